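"""End-to-end study pipeline and report rendering.

``run_full_study`` reproduces the canonical analysis order of an X-STR
population survey: stratified allele frequencies -> HWE / LD / sex-Fst
testing battery -> per-locus forensic parameters -> linkage-group haplotype
parameters -> combined powers.  Outputs are a bundle of delimited tables
rounded to 4 decimals (half away from zero) plus a machine-readable JSON at
full precision; a rerun with the same config and seed is byte-identical.

``compare_populations`` runs the inter-population machinery (Nei distances,
PCA, MDS, neighbor-joining tree) over a focal frequency table and a
directory of reference tables.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as xio
from .core import (
    AlleleFrequencyTable,
    DEFAULT_LINKAGE_GROUPS,
    GenotypeTable,
    LinkageGroupDef,
    OVERLAP_11,
)
from .exact_tests import (
    McmcConfig,
    PermConfig,
    bonferroni_threshold,
    fst_gender,
    hwe_exact_test,
    ld_em_permutation_test,
    ld_exact_test_haploid,
)
from .forensic import (
    CombinedPower,
    ForensicSummary,
    combined_power,
    observed_expected_het,
    round_half_up,
)
from .frequencies import allele_frequencies, haplotype_frequencies, singleton_fraction

__all__ = ["RunConfig", "run_full_study", "compare_populations", "OVERLAP_11"]


@dataclass
class RunConfig:
    """Configuration of a full study run.

    ``ld_scope`` chooses which locus pairs get the (costly) female EM
    permutation test: "all" pairs, or "within_group" only; the male exact
    test always covers all pairs.  The seed feeds every stochastic stage
    through independent derived seeds.
    """

    out_dir: str
    genotypes: str | GenotypeTable = ""
    linkage_groups: tuple[LinkageGroupDef, ...] = DEFAULT_LINKAGE_GROUPS
    hwe_mcmc: McmcConfig = field(default_factory=McmcConfig)
    male_ld_mcmc: McmcConfig = field(
        default_factory=lambda: McmcConfig(chain_length=10_000, dememorization=1_000))
    ld_perm: PermConfig = field(default_factory=PermConfig)
    fst_permutations: int = 10_000
    alpha: float = 0.05
    ld_scope: str = "all"
    seed: int = 0


_SUMMARY_COLS = [
    "unit", "n_units", "ho", "he", "hwe_p", "gd", "mp", "pic", "pd_m", "pd_f",
    "mec_kruger", "mec_kishida", "mec_desmarais", "mec_desmarais_duo", "n_obs",
]


def _summary_frame(rows: list[ForensicSummary]) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {c: getattr(r, c) for c in _SUMMARY_COLS}
        recs.append(rec)
    return pd.DataFrame(recs, columns=_SUMMARY_COLS)


def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype == float:
            out[c] = out[c].map(lambda x: "" if pd.isna(x) else f"{round_half_up(x):.4f}")
    return out


def _derived_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_full_study(cfg: RunConfig) -> dict:
    """Run the whole single-population study; returns the result bundle and
    writes it under ``cfg.out_dir``."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    log_lines = [f"config: seed={cfg.seed} alpha={cfg.alpha} ld_scope={cfg.ld_scope}",
                 f"hwe_mcmc: chain={cfg.hwe_mcmc.chain_length} burn={cfg.hwe_mcmc.dememorization}",
                 f"male_ld_mcmc: chain={cfg.male_ld_mcmc.chain_length} "
                 f"burn={cfg.male_ld_mcmc.dememorization}",
                 f"ld_perm: permutations={cfg.ld_perm.permutations} "
                 f"em_starts={cfg.ld_perm.em_initial_conditions}",
                 f"fst_permutations={cfg.fst_permutations}"]

    g = cfg.genotypes
    if isinstance(g, str):
        g = xio.read_genotypes(g)
    loci = g.loci
    log_lines.append(f"samples: {len(g.females)} females, {len(g.males)} males; "
                     f"{len(loci)} loci")

    # --- frequencies per stratum
    freqs = {stratum: allele_frequencies(g, stratum)
             for stratum in ("female", "male", "pooled")}
    for stratum, table in freqs.items():
        xio.write_frequency_table(table, os.path.join(cfg.out_dir,
                                                      f"allele_freqs_{stratum}.csv"))

    seeds = _derived_seeds(cfg.seed, 4)

    # --- HWE in females
    hwe_results = {}
    hwe_seeds = _derived_seeds(seeds[0], len(loci))
    for locus, s in zip(loci, hwe_seeds):
        counts: dict[tuple[str, str], int] = {}
        for smp in g.females:
            call = smp.call(locus)
            if call is None:
                continue
            key = tuple(sorted(call))
            counts[key] = counts.get(key, 0) + 1
        cfg_l = McmcConfig(cfg.hwe_mcmc.chain_length, cfg.hwe_mcmc.dememorization, s)
        hwe_results[locus] = hwe_exact_test(counts, cfg_l)

    # --- gender differentiation Fst
    fst_results = {}
    fst_seeds = _derived_seeds(seeds[1], len(loci))
    for locus, s in zip(loci, fst_seeds):
        fm = freqs["male"]
        ff = freqs["female"]
        if locus not in fm or locus not in ff:
            continue
        fst_results[locus] = fst_gender(
            fm[locus].as_dict(), ff[locus].as_dict(), fm[locus].n, ff[locus].n,
            permutations=cfg.fst_permutations, seed=s)

    # --- LD battery over locus pairs
    pairs = list(itertools.combinations(loci, 2))
    within = set()
    for lg in cfg.linkage_groups:
        within |= {tuple(sorted(p)) for p in itertools.combinations(lg.loci, 2)}
    if cfg.ld_scope == "within_group":
        female_pairs = [p for p in pairs if tuple(sorted(p)) in within]
    else:
        female_pairs = pairs

    ld_female = {}
    f_seeds = _derived_seeds(seeds[2], len(female_pairs) + len(pairs))
    for (la, lb), s in zip(female_pairs, f_seeds):
        obs = [(tuple(sorted(smp.call(la))), tuple(sorted(smp.call(lb))))
               for smp in g.females
               if smp.call(la) is not None and smp.call(lb) is not None]
        pc = PermConfig(cfg.ld_perm.permutations, cfg.ld_perm.em_initial_conditions, s)
        ld_female[(la, lb)] = ld_em_permutation_test(obs, pc)

    ld_male = {}
    for (la, lb), s in zip(pairs, f_seeds[len(female_pairs):]):
        rows = sorted({smp.call(la)[0] for smp in g.males
                       if smp.call(la) and smp.call(lb)})
        cols = sorted({smp.call(lb)[0] for smp in g.males
                       if smp.call(la) and smp.call(lb)})
        ri = {a: i for i, a in enumerate(rows)}
        ci = {b: i for i, b in enumerate(cols)}
        tab = np.zeros((len(rows), len(cols)), dtype=np.int64)
        for smp in g.males:
            ca, cb = smp.call(la), smp.call(lb)
            if ca and cb:
                tab[ri[ca[0]], ci[cb[0]]] += 1
        mc = McmcConfig(cfg.male_ld_mcmc.chain_length, cfg.male_ld_mcmc.dememorization, s)
        ld_male[(la, lb)] = ld_exact_test_haploid(tab, mc)

    n_tests = len(pairs)
    bonf = bonferroni_threshold(cfg.alpha, n_tests)
    log_lines.append(f"bonferroni: alpha={cfg.alpha} m={n_tests} threshold={bonf:.6g}")

    # p-value matrix: upper triangle females, lower triangle males
    ld_matrix = pd.DataFrame("", index=loci, columns=loci, dtype=object)
    for (la, lb), res in ld_female.items():
        i, j = loci.index(la), loci.index(lb)
        ld_matrix.iloc[min(i, j), max(i, j)] = f"{round_half_up(res.p_value):.4f}"
    for (la, lb), res in ld_male.items():
        i, j = loci.index(la), loci.index(lb)
        ld_matrix.iloc[max(i, j), min(i, j)] = f"{round_half_up(res.p_value):.4f}"

    # --- per-locus forensic summaries (pooled frequencies)
    locus_rows = []
    for locus in loci:
        lf = freqs["pooled"][locus]
        ho, he = observed_expected_het(g, locus)
        locus_rows.append(ForensicSummary.from_frequencies(
            locus, lf.freqs, lf.n, ho=ho, he=he, hwe_p=hwe_results[locus].p_value))

    # --- linkage-group haplotype summaries (males)
    haplos = haplotype_frequencies(g, cfg.linkage_groups)
    group_rows = []
    group_extra = {}
    for lg in cfg.linkage_groups:
        gh = haplos[lg.name]
        fv = gh.frequency_vector()
        group_rows.append(ForensicSummary.from_frequencies(lg.name, fv.freqs, fv.n))
        group_extra[lg.name] = {
            "n_haplotypes": gh.n_distinct,
            "n_singletons": gh.n_singletons,
            "fraction_unique": singleton_fraction(haplos, lg.name),
            "n_males": gh.n_males,
        }

    # --- combined powers
    combined = {
        "per_locus": {
            "pd_m": combined_power([r.pd_m for r in locus_rows]),
            "pd_f": combined_power([r.pd_f for r in locus_rows]),
            "mec_kruger": combined_power([r.mec_kruger for r in locus_rows]),
            "mec_kishida": combined_power([r.mec_kishida for r in locus_rows]),
            "mec_desmarais": combined_power([r.mec_desmarais for r in locus_rows]),
            "mec_desmarais_duo": combined_power([r.mec_desmarais_duo for r in locus_rows]),
        },
        "per_group": {
            "pd_m": combined_power([r.pd_m for r in group_rows]),
            "pd_f": combined_power([r.pd_f for r in group_rows]),
            "mec_kruger": combined_power([r.mec_kruger for r in group_rows]),
            "mec_kishida": combined_power([r.mec_kishida for r in group_rows]),
            "mec_desmarais": combined_power([r.mec_desmarais for r in group_rows]),
            "mec_desmarais_duo": combined_power([r.mec_desmarais_duo for r in group_rows]),
        },
    }

    # --- write bundle
    t1 = _summary_frame(locus_rows)
    _rounded(t1).to_csv(os.path.join(cfg.out_dir, "table1_loci.csv"), index=False)
    t2 = _summary_frame(group_rows)
    for col in ("n_haplotypes", "n_singletons", "fraction_unique", "n_males"):
        t2[col] = [group_extra[r.unit][col] for r in group_rows]
    _rounded(t2).to_csv(os.path.join(cfg.out_dir, "table2_groups.csv"), index=False)
    ld_matrix.to_csv(os.path.join(cfg.out_dir, "ld_pvalues.csv"))

    hwe_df = pd.DataFrame(
        {"locus": list(hwe_results),
         "p": [r.p_value for r in hwe_results.values()],
         "se": [r.se for r in hwe_results.values()],
         "method": [r.method for r in hwe_results.values()]})
    _rounded(hwe_df).to_csv(os.path.join(cfg.out_dir, "hwe.csv"), index=False)
    fst_df = pd.DataFrame(
        {"locus": list(fst_results),
         "fst": [r.statistic for r in fst_results.values()],
         "p": [r.p_value for r in fst_results.values()]})
    _rounded(fst_df).to_csv(os.path.join(cfg.out_dir, "fst.csv"), index=False)

    with open(os.path.join(cfg.out_dir, "combined_powers.txt"), "w") as fh:
        for level, block in combined.items():
            fh.write(f"[{level}]\n")
            for name, cp in block.items():
                fh.write(f"combined_{name} = {cp.text(24)}\n")
            fh.write("\n")

    def _res(r):
        return {"statistic": r.statistic, "p": r.p_value, "se": r.se, "method": r.method}

    bundle = {
        "loci": list(loci),
        "per_locus": [dict(zip(_SUMMARY_COLS, [getattr(r, c) for c in _SUMMARY_COLS]))
                      for r in locus_rows],
        "per_group": [dict(**{c: getattr(r, c) for c in _SUMMARY_COLS
                              if c not in ("ho", "he", "hwe_p")},
                           **group_extra[r.unit]) for r in group_rows],
        "hwe": {l: _res(r) for l, r in hwe_results.items()},
        "fst": {l: _res(r) for l, r in fst_results.items()},
        "ld_female": {f"{a}|{b}": _res(r) for (a, b), r in ld_female.items()},
        "ld_male": {f"{a}|{b}": _res(r) for (a, b), r in ld_male.items()},
        "bonferroni": {"alpha": cfg.alpha, "m": n_tests, "threshold": bonf},
        "combined": {level: {k: {"value": cp.value, "complement": cp.complement,
                                 "text": cp.text(24)}
                             for k, cp in block.items()}
                     for level, block in combined.items()},
        "significant_after_bonferroni": {
            "hwe": [l for l, r in hwe_results.items() if r.p_value <= cfg.alpha / len(loci)],
            "ld_female": [f"{a}|{b}" for (a, b), r in ld_female.items()
                          if r.p_value <= bonf],
            "ld_male": [f"{a}|{b}" for (a, b), r in ld_male.items() if r.p_value <= bonf],
        },
    }
    with open(os.path.join(cfg.out_dir, "results.json"), "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    with open(os.path.join(cfg.out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    bundle["_combined_objects"] = combined
    return bundle


def compare_populations(focal: AlleleFrequencyTable | str,
                        references: dict[str, AlleleFrequencyTable] | str,
                        out_dir: str,
                        focal_name: str = "focal",
                        loci: list[str] | None = None,
                        mds_dims: int = 2) -> dict:
    """Nei distances, PCA, MDS and NJ tree over focal + reference populations.

    ``references`` may be a directory of frequency CSV/TSV files (stem =
    population name).  ``loci`` restricts the comparison to a named subset
    (e.g. the 11-locus overlap panel).  With fewer than 3 populations only
    the distance matrix is produced.
    """
    from .popcompare import mds_from_distances, nei_distance_matrix, nj_tree, pca_frequencies

    os.makedirs(out_dir, exist_ok=True)
    if isinstance(focal, str):
        focal = xio.read_frequency_table(focal)
    if isinstance(references, str):
        refs = {}
        for fn in sorted(os.listdir(references)):
            if fn.endswith((".csv", ".tsv")):
                refs[os.path.splitext(fn)[0]] = xio.read_frequency_table(
                    os.path.join(references, fn))
        references = refs
    pops = {focal_name: focal, **references}
    if len(pops) < 3:
        import warnings
        warnings.warn("fewer than 3 populations: PCA/MDS/NJ skipped")
        dm = nei_distance_matrix(pops, loci)
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            os.path.join(out_dir, "nei_distances.csv"))
        return {"distances": dm}

    dm = nei_distance_matrix(pops, loci)
    scores, loadings, pct = pca_frequencies(pops, loci)
    coords, stress = mds_from_distances(dm, dims=mds_dims)
    tree = nj_tree(dm)

    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        os.path.join(out_dir, "nei_distances.csv"))
    scores.to_csv(os.path.join(out_dir, "pca_scores.csv"))
    pd.Series(pct, index=scores.columns, name="percent_variance").to_csv(
        os.path.join(out_dir, "pca_variance.csv"))
    coords.to_csv(os.path.join(out_dir, "mds_coordinates.csv"))
    with open(os.path.join(out_dir, "mds_stress.txt"), "w") as fh:
        fh.write(f"stress1 = {stress:.6g}\n")
    xio.write_newick(tree, os.path.join(out_dir, "nj_tree.nwk"))
    return {"distances": dm, "pca_scores": scores, "pca_variance": pct,
            "mds_coordinates": coords, "mds_stress": stress, "tree": tree}
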