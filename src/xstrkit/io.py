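"""Reading and writing of on-disk artifacts.

Formats are all plain text:

* genotype tables — CSV/TSV (delimiter autodetected from the extension),
  one row per sample with ``sample_id, sex`` followed by either two columns
  per locus (``<locus>_1, <locus>_2``, the second blank for males) or one
  slash-separated column per locus (``15/16``; ``15`` for males);
* allele-frequency tables — allele labels as rows, loci as columns, blank
  cells for unobserved alleles, an optional ``N`` row of chromosome counts;
* linkage-group definitions — YAML or JSON mapping group name to locus list;
* trees — Newick with branch lengths.

Missing genotype calls are encoded as empty cells or ``NA``.
"""

from __future__ import annotations

import json
import math
import os

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .core import (
    ALLELE_LABEL_RE,
    AlleleFrequencyTable,
    AlleleLabelError,
    ConsistencyError,
    GenotypeTable,
    LinkageGroupDef,
    LocusFrequencies,
    PloidyError,
    Sample,
    allele_sort_key,
)

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_frequency_table", "write_frequency_table",
    "read_linkage_groups", "write_linkage_groups",
    "read_newick", "write_newick",
]

_MISSING = {"", "na", "nan", "none"}


def _delimiter(path: str, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".txt") else ","


def _is_missing(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    return str(cell).strip().lower() in _MISSING


def _clean_label(cell, row: str, locus: str) -> str:
    label = str(cell).strip()
    if not ALLELE_LABEL_RE.match(label):
        raise AlleleLabelError(f"row {row!r}, locus {locus}: malformed allele label {label!r}")
    return label


def read_genotypes(path: str, dialect: str | None = None) -> GenotypeTable:
    """Read a genotype table; both the two-column and the ``15/16`` compact
    per-locus layouts are accepted (and may be mixed across loci)."""
    df = pd.read_csv(path, sep=_delimiter(path, dialect), dtype=str,
                     keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "sex":
        raise ConsistencyError(
            f"{path}: header must start with sample_id, sex; got {cols[:2]}")

    # map locus -> ("pair", (col1, col2)) or ("compact", col)
    layout: dict[str, tuple[str, tuple]] = {}
    i = 2
    while i < len(cols):
        c = cols[i]
        if c.endswith("_1"):
            locus = c[:-2]
            if i + 1 >= len(cols) or cols[i + 1] != f"{locus}_2":
                raise ConsistencyError(f"{path}: column {c} lacks its {locus}_2 partner")
            layout[locus] = ("pair", (c, cols[i + 1]))
            i += 2
        else:
            layout[c] = ("compact", (c,))
            i += 1
    loci = list(layout)

    samples = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        sex = str(row["sex"]).strip().lower()
        if sex in ("m", "male"):
            sex = "male"
        elif sex in ("f", "female"):
            sex = "female"
        else:
            raise ValueError(f"{path}: sample {sid!r}: unrecognized sex {row['sex']!r}")
        calls: dict[str, tuple[str, ...] | None] = {}
        for locus, (kind, lcols) in layout.items():
            if kind == "pair":
                c1, c2 = row[lcols[0]], row[lcols[1]]
                parts = [c for c in (c1, c2) if not _is_missing(c)]
            else:
                cell = row[lcols[0]]
                parts = [] if _is_missing(cell) else str(cell).strip().split("/")
            if not parts:
                calls[locus] = None
                continue
            labels = tuple(_clean_label(p, sid, locus) for p in parts)
            if sex == "male":
                if len(labels) == 2:
                    if labels[0] != labels[1]:
                        raise PloidyError(
                            f"{path}: male {sid!r} has two distinct alleles "
                            f"{labels} at {locus}")
                    # duplicated hemizygous call, a common typing-software
                    # artifact: collapse to a single allele
                    labels = (labels[0],)
                elif len(labels) != 1:
                    raise PloidyError(f"{path}: male {sid!r} has {len(labels)} alleles at {locus}")
            else:
                if len(labels) != 2:
                    raise PloidyError(
                        f"{path}: female {sid!r} has {len(labels)} allele(s) at {locus}")
            calls[locus] = labels
        samples.append(Sample(sid, sex, calls))
    return GenotypeTable(loci=loci, samples=samples)


def write_genotypes(table: GenotypeTable, path: str, dialect: str | None = None) -> None:
    """Write a genotype table in the two-column-per-locus layout."""
    sep = _delimiter(path, dialect)
    rows = []
    for s in table.samples:
        row = {"sample_id": s.sample_id, "sex": s.sex}
        for locus in table.loci:
            call = s.call(locus)
            row[f"{locus}_1"] = call[0] if call else ""
            row[f"{locus}_2"] = call[1] if call and len(call) > 1 else ""
        rows.append(row)
    cols = ["sample_id", "sex"]
    for locus in table.loci:
        cols += [f"{locus}_1", f"{locus}_2"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def read_frequency_table(path: str, dialect: str | None = None) -> AlleleFrequencyTable:
    """Read a locus x allele frequency matrix.

    Rows are allele labels, columns loci, cells relative frequencies (blank
    for alleles absent at a locus).  An optional ``N`` row carries the
    chromosome counts.  Per-locus sums within 0.01 of 1 are renormalized to
    exactly 1; anything further off raises :class:`ConsistencyError`.
    """
    df = pd.read_csv(path, sep=_delimiter(path, dialect), dtype=str,
                     keep_default_na=False)
    # first column holds the allele labels; keep them as verbatim text
    df = df.set_index(df.columns[0])
    index = [str(i).strip() for i in df.index]
    n_row = None
    if "N" in index:
        n_row = df.iloc[index.index("N")]
        keep = [i for i, lab in enumerate(index) if lab != "N"]
        df = df.iloc[keep]
        index = [index[i] for i in keep]

    loci: dict[str, LocusFrequencies] = {}
    for locus in df.columns:
        labels, freqs = [], []
        for lab, cell in zip(index, df[locus]):
            if _is_missing(cell):
                continue
            f = float(cell)
            if f < 0:
                raise ConsistencyError(f"{path}: negative frequency {f} at {locus}/{lab}")
            if f == 0:
                continue
            labels.append(_clean_label(lab, lab, locus))
            freqs.append(f)
        if not labels:
            continue
        total = float(np.sum(freqs))
        if abs(total - 1.0) > 0.01:
            raise ConsistencyError(
                f"{path}: locus {locus} frequencies sum to {total:.4f}, outside [0.99, 1.01]")
        freqs = np.asarray(freqs) / total
        n = None
        if n_row is not None and not _is_missing(n_row[locus]):
            n = int(float(n_row[locus]))
        loci[locus] = LocusFrequencies(labels, freqs, n)
    if not loci:
        raise ConsistencyError(f"{path}: no usable loci")
    return AlleleFrequencyTable(loci)


def write_frequency_table(table: AlleleFrequencyTable, path: str,
                          dialect: str | None = None) -> None:
    """Write the locus x allele matrix at full float precision (17 significant
    digits), so that a read-back reproduces the values exactly."""
    sep = _delimiter(path, dialect)
    all_alleles = sorted(
        {a for lf in table.loci.values() for a in lf.alleles}, key=allele_sort_key)
    data: dict[str, dict[str, str]] = {}
    for locus, lf in table.loci.items():
        col = {a: "" for a in all_alleles}
        for a, f in zip(lf.alleles, lf.freqs):
            col[a] = repr(float(f))
        data[locus] = col
    df = pd.DataFrame(data, index=all_alleles)
    if any(lf.n is not None for lf in table.loci.values()):
        df.loc["N"] = {loc: ("" if lf.n is None else str(lf.n))
                       for loc, lf in table.loci.items()}
    df.to_csv(path, sep=sep)


def read_linkage_groups(path: str) -> tuple[LinkageGroupDef, ...]:
    with open(path) as fh:
        data = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return tuple(LinkageGroupDef(name, tuple(loci)) for name, loci in data.items())


def write_linkage_groups(groups: tuple[LinkageGroupDef, ...], path: str) -> None:
    data = {g.name: list(g.loci) for g in groups}
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def write_newick(tree: TreeNode, path: str) -> None:
    """Serialize a tree (e.g. a neighbor-joining tree over populations) as
    Newick with branch lengths."""
    tips = [t.name for t in tree.tips()]
    if not tips:
        raise ValueError("cannot serialize an empty tree")
    if len(set(tips)) != len(tips):
        raise ValueError(f"duplicate leaf names: {sorted(tips)}")
    tree.write(path, format="newick")


def read_newick(path: str) -> TreeNode:
    return TreeNode.read(path, format="newick")
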