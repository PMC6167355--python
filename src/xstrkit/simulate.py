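"""Synthetic X-STR genotype and frequency generators.

The generators emulate the statistical structure the downstream analyses
assume, so every stage of the pipeline is testable without real genotypes:

* diploid females / hemizygous males at named STR loci, with microvariant
  allele labels ("24.1") in realistic repeat ranges;
* optional departure from Hardy-Weinberg in females via a per-locus
  inbreeding coefficient F (two allele draws identical by descent with
  probability F);
* within-linkage-group LD via explicit group haplotype distributions: male
  haplotypes and female gametes are drawn jointly from them (random union
  of gametes, i.e. HWE at the haplotype level);
* multi-population divergence via the Balding-Nichols construction: each
  population's per-locus frequencies are Dirichlet draws around the
  ancestral vector with concentration (1 - Fst)/Fst.

Identical spec + seed reproduces identical tables byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AlleleFrequencyTable,
    DEFAULT_LINKAGE_GROUPS,
    GenotypeTable,
    LinkageGroupDef,
    LocusFrequencies,
    PANEL_19,
    Sample,
    label_sort_key,
)

__all__ = ["SyntheticSpec", "simulate_genotypes",
           "simulate_divergent_populations", "gelao_like_fixture"]


class SpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Generating parameters for a synthetic study.

    ``loci`` maps locus name to an allele-label -> frequency mapping.
    ``haplotype_freqs`` optionally maps a linkage-group name to a haplotype
    distribution (keys are allele labels joined by "-" in group locus
    order); loci covered by such a group are drawn jointly.
    ``f_inbreeding`` may be a single coefficient or a per-locus mapping.
    """

    n_females: int
    n_males: int
    loci: dict[str, dict[str, float]]
    f_inbreeding: float | dict[str, float] = 0.0
    linkage_groups: tuple[LinkageGroupDef, ...] = ()
    haplotype_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    n_populations: int = 2
    fst_divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 0 or self.n_males < 0:
            raise SpecError("sample counts must be >= 0")
        if not 0.0 <= self.fst_divergence < 1.0:
            raise SpecError("fst_divergence must be in [0, 1)")
        for locus, fv in self.loci.items():
            total = sum(fv.values())
            if abs(total - 1.0) > 1e-9:
                raise SpecError(f"locus {locus}: frequencies sum to {total}, not 1")
        groups_by_name = {g.name: g for g in self.linkage_groups}
        for gname, hv in self.haplotype_freqs.items():
            if gname not in groups_by_name:
                raise SpecError(f"haplotype frequencies for undeclared group {gname}")
            total = sum(hv.values())
            if abs(total - 1.0) > 1e-9:
                raise SpecError(f"group {gname}: haplotype frequencies sum to {total}")
            g = groups_by_name[gname]
            for locus in g.loci:
                if locus not in self.loci:
                    raise SpecError(f"group {gname} locus {locus} lacks frequencies")
            for h in hv:
                if len(h.split("-")) != len(g.loci):
                    raise SpecError(f"group {gname}: haplotype {h!r} has wrong arity")

    def f_at(self, locus: str) -> float:
        if isinstance(self.f_inbreeding, dict):
            return self.f_inbreeding.get(locus, 0.0)
        return self.f_inbreeding

    def truth(self) -> dict:
        """Generating parameters as a plain-data record (YAML/JSON safe)."""
        return {
            "n_females": self.n_females,
            "n_males": self.n_males,
            "seed": self.seed,
            "f_inbreeding": (dict(self.f_inbreeding)
                             if isinstance(self.f_inbreeding, dict)
                             else float(self.f_inbreeding)),
            "loci": {l: {a: float(f) for a, f in fv.items()}
                     for l, fv in self.loci.items()},
            "linkage_groups": {g.name: list(g.loci) for g in self.linkage_groups},
            "haplotype_freqs": {g: {h: float(f) for h, f in hv.items()}
                                for g, hv in self.haplotype_freqs.items()},
            "n_populations": self.n_populations,
            "fst_divergence": float(self.fst_divergence),
        }


def _draw(labels: list[str], probs: np.ndarray, rng: np.random.Generator) -> str:
    return labels[rng.choice(len(labels), p=probs)]


def simulate_genotypes(spec: SyntheticSpec) -> tuple[GenotypeTable, dict]:
    """Draw a genotype table from the spec; returns (table, truth record)."""
    rng = np.random.default_rng(spec.seed)
    loci = list(spec.loci)

    # loci drawn jointly (through a group haplotype distribution) vs singly
    joint: dict[str, tuple[LinkageGroupDef, list[list[str]], np.ndarray]] = {}
    for g in spec.linkage_groups:
        if g.name in spec.haplotype_freqs:
            hv = spec.haplotype_freqs[g.name]
            haps = [h.split("-") for h in hv]
            probs = np.array(list(hv.values()))
            joint[g.name] = (g, haps, probs / probs.sum())
    joint_loci = {l for g, _, _ in joint.values() for l in g.loci}

    single = {}
    for locus in loci:
        if locus in joint_loci:
            continue
        fv = spec.loci[locus]
        labels = sorted(fv, key=label_sort_key)
        probs = np.array([fv[a] for a in labels])
        single[locus] = (labels, probs / probs.sum())

    samples: list[Sample] = []

    def draw_haplotype_set() -> dict[str, str]:
        """One gamete: an allele for every locus."""
        calls: dict[str, str] = {}
        for g, haps, probs in joint.values():
            h = haps[rng.choice(len(haps), p=probs)]
            calls.update(dict(zip(g.loci, h)))
        for locus, (labels, probs) in single.items():
            calls[locus] = _draw(labels, probs, rng)
        return calls

    for i in range(spec.n_females):
        g1 = draw_haplotype_set()
        g2 = draw_haplotype_set()
        calls: dict[str, tuple[str, ...]] = {}
        for locus in loci:
            f = spec.f_at(locus)
            a1 = g1[locus]
            a2 = a1 if (f > 0 and rng.random() < f) else g2[locus]
            calls[locus] = (a1, a2)
        samples.append(Sample(f"F{i+1:04d}", "female", calls))
    for i in range(spec.n_males):
        g1 = draw_haplotype_set()
        samples.append(Sample(f"M{i+1:04d}", "male",
                              {locus: (g1[locus],) for locus in loci}))
    return GenotypeTable(loci=loci, samples=samples), spec.truth()


def simulate_divergent_populations(spec: SyntheticSpec,
                                   ) -> tuple[list[AlleleFrequencyTable], dict]:
    """Per-population frequency tables under the Balding-Nichols model.

    Each population's per-locus frequency vector is a Dirichlet draw with
    concentration p_ancestral * (1 - Fst)/Fst; Fst = 0 copies the ancestral
    vector exactly.
    """
    if spec.n_populations < 2:
        raise SpecError("need at least 2 populations")
    fst = spec.fst_divergence
    rng = np.random.default_rng(spec.seed)
    tables: list[AlleleFrequencyTable] = []
    for _ in range(spec.n_populations):
        loci: dict[str, LocusFrequencies] = {}
        for locus, fv in spec.loci.items():
            labels = sorted(fv, key=label_sort_key)
            p = np.array([fv[a] for a in labels])
            if fst == 0.0:
                q = p.copy()
            else:
                if len(labels) < 2:
                    raise SpecError(f"locus {locus}: degenerate ancestral vector with Fst > 0")
                q = rng.dirichlet(p * (1.0 - fst) / fst)
            # keep support identical to the ancestral one (floor tiny draws)
            q = np.maximum(q, 1e-9)
            q = q / q.sum()
            loci[locus] = LocusFrequencies(list(labels), q)
        tables.append(AlleleFrequencyTable(loci))
    truth = spec.truth()
    return tables, truth


# ---------------------------------------------------------------------------
# A study-sized fixture

#: Distinct-allele richness configured per panel locus (observed span of a
#: 19-locus Chinese population survey: 5 at DXS7423 up to 26 at DXS10135).
_RICHNESS = {
    "DXS8378": 9, "DXS7423": 5, "DXS10148": 22, "DXS10159": 10,
    "DXS10134": 21, "DXS7424": 9, "DXS10164": 10, "DXS10162": 13,
    "DXS7132": 8, "DXS10079": 10, "DXS6789": 12, "DXS101": 14,
    "DXS10103": 10, "DXS10101": 20, "HPRTB": 7, "DXS6809": 10,
    "DXS10075": 14, "DXS10074": 12, "DXS10135": 26,
}

#: Smallest common repeat number per locus, to place labels in realistic ranges.
_BASE_REPEAT = {
    "DXS8378": 8, "DXS7423": 13, "DXS10148": 13, "DXS10159": 28,
    "DXS10134": 28, "DXS7424": 9, "DXS10164": 16, "DXS10162": 14,
    "DXS7132": 11, "DXS10079": 14, "DXS6789": 14, "DXS101": 15,
    "DXS10103": 15, "DXS10101": 24, "HPRTB": 9, "DXS6809": 28,
    "DXS10075": 9, "DXS10074": 4, "DXS10135": 13,
}

#: Loci whose ladders are rich in partial-repeat (".1") microvariants.
_MICROVARIANT_LOCI = ("DXS10148", "DXS10135", "DXS10101")


def _locus_labels(locus: str, k: int) -> list[str]:
    base = _BASE_REPEAT[locus]
    if locus in _MICROVARIANT_LOCI:
        # interleave integer and ".1" labels along the ladder
        labels = []
        r = base
        while len(labels) < k:
            labels.append(str(r))
            if len(labels) < k:
                labels.append(f"{r}.1")
            r += 1
        return labels[:k]
    return [str(base + i) for i in range(k)]


def _unimodal_freqs(k: int, rng: np.random.Generator) -> np.ndarray:
    """A realistic unimodal STR frequency shape with rare tail alleles."""
    center = rng.uniform(0.3, 0.7) * (k - 1)
    scale = rng.uniform(0.12, 0.25) * max(k, 2)
    shape = np.exp(-((np.arange(k) - center) ** 2) / (2 * scale**2))
    conc = 60.0 * shape / shape.sum() + 0.15
    p = rng.dirichlet(conc)
    p = np.maximum(p, 1e-4)
    return p / p.sum()


def gelao_like_spec(seed: int = 0, n_females: int = 265, n_males: int = 248,
                    ld_weight: float = 0.6, n_core_haplotypes: int = 40,
                    ) -> SyntheticSpec:
    """A study-sized spec: the 19-locus panel at its observed allele
    richness, the seven default linkage groups, and within-group LD.

    Within-group LD is induced by a mixture haplotype distribution: weight
    ``ld_weight`` on a drawn set of core haplotypes, the rest on the product
    of the single-locus frequencies.
    """
    rng = np.random.default_rng(seed)
    loci: dict[str, dict[str, float]] = {}
    for locus in PANEL_19:
        k = _RICHNESS[locus]
        labels = _locus_labels(locus, k)
        loci[locus] = dict(zip(labels, _unimodal_freqs(k, rng).tolist()))

    hap_freqs: dict[str, dict[str, float]] = {}
    for g in DEFAULT_LINKAGE_GROUPS:
        per_locus = []
        for locus in g.loci:
            fv = loci[locus]
            labels = sorted(fv, key=label_sort_key)
            per_locus.append((labels, np.array([fv[a] for a in labels])))
        core: dict[str, float] = {}
        w = rng.dirichlet(np.ones(n_core_haplotypes))
        for wi in w:
            h = "-".join(_draw(labels, probs / probs.sum(), rng)
                         for labels, probs in per_locus)
            core[h] = core.get(h, 0.0) + float(wi) * ld_weight
        # the independent-background part of the mixture, enumerated lazily:
        # instead of enumerating the full product space, draw a large sample
        # of product haplotypes to carry the (1 - ld_weight) mass
        n_bg = 400
        for _ in range(n_bg):
            h = "-".join(_draw(labels, probs / probs.sum(), rng)
                         for labels, probs in per_locus)
            core[h] = core.get(h, 0.0) + (1.0 - ld_weight) / n_bg
        total = sum(core.values())
        hap_freqs[g.name] = {h: f / total for h, f in core.items()}

    return SyntheticSpec(
        n_females=n_females, n_males=n_males, loci=loci,
        linkage_groups=DEFAULT_LINKAGE_GROUPS, haplotype_freqs=hap_freqs,
        seed=seed,
    )


def gelao_like_fixture(seed: int = 0) -> GenotypeTable:
    """A 265-female + 248-male genotype table at the 19-locus panel with
    within-group haplotype LD; deterministic in the seed."""
    table, _ = simulate_genotypes(gelao_like_spec(seed))
    return table
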