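"""Core domain types for X-STR panel analysis.

An X-STR panel is typed in diploid females (two allele calls per locus) and
hemizygous males (one call per locus).  Allele labels follow standard STR
nomenclature: the repeat number, optionally with a partial-repeat suffix
("15", "24.1").  Labels are kept as categorical text throughout so that
microvariants such as "24.1" survive round-trips exactly; numeric ordering
uses the (integer, fractional) sort key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALLELE_LABEL_RE",
    "PANEL_19",
    "OVERLAP_11",
    "DEFAULT_LINKAGE_GROUPS",
    "allele_sort_key",
    "Sample",
    "GenotypeTable",
    "LocusFrequencies",
    "AlleleFrequencyTable",
    "LinkageGroupDef",
    "PloidyError",
    "AlleleLabelError",
    "ConsistencyError",
]

ALLELE_LABEL_RE = re.compile(r"^\d+(\.\d+)?$")

#: The 19-locus X-STR panel, in the customary reporting order.
PANEL_19 = (
    "DXS8378", "DXS7423", "DXS10148", "DXS10159", "DXS10134", "DXS7424",
    "DXS10164", "DXS10162", "DXS7132", "DXS10079", "DXS6789", "DXS101",
    "DXS10103", "DXS10101", "HPRTB", "DXS6809", "DXS10075", "DXS10074",
    "DXS10135",
)

#: The 11 loci shared between this panel and the 12-locus commercial kits,
#: used when comparing against populations typed on the smaller panel.
OVERLAP_11 = (
    "DXS7132", "DXS10079", "DXS10074", "DXS10103", "HPRTB", "DXS10101",
    "DXS10134", "DXS10148", "DXS10135", "DXS8378", "DXS7423",
)


class PloidyError(ValueError):
    """A sample's call count is inconsistent with its sex (X hemizygosity)."""


class AlleleLabelError(ValueError):
    """An allele label does not match STR nomenclature."""


class ConsistencyError(ValueError):
    """A frequency table fails its sum/positivity checks."""


def allele_sort_key(label: str) -> tuple[int, int]:
    """Numeric sort key for an STR allele label: (repeat count, partial repeat).

    >>> sorted(["24.1", "9", "24"], key=allele_sort_key)
    ['9', '24', '24.1']
    """
    if not ALLELE_LABEL_RE.match(label):
        raise AlleleLabelError(f"not an STR allele label: {label!r}")
    if "." in label:
        whole, frac = label.split(".")
        return (int(whole), int(frac))
    return (int(label), 0)


def label_sort_key(label: str):
    """Like :func:`allele_sort_key` but tolerant of non-STR labels (e.g.
    haplotype strings), which sort lexicographically after numeric ones."""
    if ALLELE_LABEL_RE.match(label):
        return (0,) + allele_sort_key(label)
    return (1, label)


@dataclass
class Sample:
    """One typed individual.

    ``calls`` maps locus name to a tuple of allele labels: length 2 for
    females, length 1 for males.  A missing locus is simply absent from the
    mapping (or mapped to ``None``).
    """

    sample_id: str
    sex: str  # "male" | "female"
    calls: dict[str, tuple[str, ...] | None] = field(default_factory=dict)

    def call(self, locus: str) -> tuple[str, ...] | None:
        c = self.calls.get(locus)
        return c if c else None


@dataclass
class GenotypeTable:
    """Per-sample, per-locus allele calls with sex."""

    loci: list[str]
    samples: list[Sample]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ConsistencyError("duplicate locus names")
        locusset = set(self.loci)
        seen_ids = set()
        for s in self.samples:
            if s.sample_id in seen_ids:
                raise ConsistencyError(f"duplicate sample id {s.sample_id!r}")
            seen_ids.add(s.sample_id)
            if s.sex not in ("male", "female"):
                raise ValueError(f"sample {s.sample_id!r}: sex must be male/female, got {s.sex!r}")
            for locus, call in s.calls.items():
                if locus not in locusset:
                    raise ConsistencyError(
                        f"sample {s.sample_id!r} has call at undeclared locus {locus!r}")
                if call is None:
                    continue
                for a in call:
                    if not ALLELE_LABEL_RE.match(a):
                        raise AlleleLabelError(
                            f"sample {s.sample_id!r}, locus {locus}: bad allele label {a!r}")
                expected = 2 if s.sex == "female" else 1
                if len(call) != expected:
                    raise PloidyError(
                        f"sample {s.sample_id!r} ({s.sex}) has {len(call)} alleles "
                        f"at {locus}, expected {expected}")

    @property
    def females(self) -> list[Sample]:
        return [s for s in self.samples if s.sex == "female"]

    @property
    def males(self) -> list[Sample]:
        return [s for s in self.samples if s.sex == "male"]

    def n_typed(self, locus: str, sex: str | None = None) -> int:
        """Number of samples (optionally restricted by sex) typed at locus."""
        return sum(
            1 for s in self.samples
            if (sex is None or s.sex == sex) and s.call(locus) is not None
        )


@dataclass
class LocusFrequencies:
    """Relative allele frequencies at one locus.

    ``n`` is the number of X chromosomes the counts came from (2 per typed
    female + 1 per typed male); it may be ``None`` for published reference
    tables that do not report sample sizes.
    """

    alleles: list[str]
    freqs: np.ndarray
    n: int | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.alleles) != len(self.freqs):
            raise ConsistencyError("allele labels and frequencies differ in length")
        if len(self.alleles) == 0:
            raise ConsistencyError("empty locus frequency vector")
        if np.any(self.freqs <= 0):
            raise ConsistencyError("frequencies must be strictly positive")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ConsistencyError(f"frequencies sum to {self.freqs.sum()!r}, not 1")
        if self.n is not None and self.n < 1:
            raise ConsistencyError("observation count must be >= 1")
        # STR labels sort numerically; anything else (e.g. haplotype labels)
        # falls back to lexicographic order
        if all(ALLELE_LABEL_RE.match(a) for a in self.alleles):
            key = lambda i: allele_sort_key(self.alleles[i])  # noqa: E731
        else:
            key = lambda i: self.alleles[i]  # noqa: E731
        order = sorted(range(len(self.alleles)), key=key)
        self.alleles = [self.alleles[i] for i in order]
        self.freqs = self.freqs[order]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.alleles, self.freqs.tolist()))


@dataclass
class AlleleFrequencyTable:
    """Locus -> allele frequency vectors; the currency of every downstream formula."""

    loci: dict[str, LocusFrequencies]

    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)

    def __getitem__(self, locus: str) -> LocusFrequencies:
        return self.loci[locus]

    def __contains__(self, locus: str) -> bool:
        return locus in self.loci


@dataclass(frozen=True)
class LinkageGroupDef:
    """A named group of physically clustered loci, in map order."""

    name: str
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ConsistencyError(f"group {self.name}: duplicate loci")


#: The seven linkage groups of the 19-locus panel.  Tightly linked loci are
#: inherited as units, so haplotype statistics replace per-locus statistics
#: within each group.
DEFAULT_LINKAGE_GROUPS = (
    LinkageGroupDef("LG1", ("DXS10148", "DXS10135", "DXS8378")),
    LinkageGroupDef("LG2", ("DXS10159", "DXS10162", "DXS10164")),
    LinkageGroupDef("LG3", ("DXS7132", "DXS10079", "DXS10074", "DXS10075")),
    LinkageGroupDef("LG4", ("DXS6809", "DXS6789")),
    LinkageGroupDef("LG5", ("DXS7424", "DXS101")),
    LinkageGroupDef("LG6", ("DXS10103", "HPRTB", "DXS10101")),
    LinkageGroupDef("LG7", ("DXS10134", "DXS7423")),
)


def validate_linkage_groups(groups: tuple[LinkageGroupDef, ...],
                            panel: tuple[str, ...] | list[str] = PANEL_19) -> None:
    """Check that every panel locus appears in exactly one group."""
    seen: dict[str, str] = {}
    for g in groups:
        for locus in g.loci:
            if locus in seen:
                raise ConsistencyError(f"locus {locus} in both {seen[locus]} and {g.name}")
            seen[locus] = g.name
    missing = set(panel) - set(seen)
    if missing:
        raise ConsistencyError(f"panel loci not covered by any group: {sorted(missing)}")
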