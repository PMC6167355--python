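"""Allele and haplotype frequency estimation from genotype tables.

Allele frequencies are plain counting: each typed female contributes two
X chromosomes per locus, each typed male one, so the pooled observation
count at a fully typed locus is ``2 * n_females + n_males``.

Haplotypes are counted in males only.  A hemizygous male genotype is a
directly observed, fully phased haplotype, so linkage-group haplotype
frequencies come from direct counting with no inference; females are never
used here because their gametic phase is unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    AlleleFrequencyTable,
    GenotypeTable,
    LinkageGroupDef,
    LocusFrequencies,
    allele_sort_key,
)

__all__ = ["allele_frequencies", "haplotype_frequencies", "singleton_fraction",
           "GroupHaplotypes", "HaplotypeTable"]

log = logging.getLogger(__name__)

#: Separator joining allele labels into a haplotype label, in group locus order.
HAPLOTYPE_SEP = "-"


def allele_counts(g: GenotypeTable, stratum: str = "pooled") -> dict[str, dict[str, int]]:
    """Raw per-locus allele counts for a stratum ('female', 'male', 'pooled')."""
    if stratum not in ("female", "male", "pooled"):
        raise ValueError(f"unknown stratum {stratum!r}")
    sexes = ("female", "male") if stratum == "pooled" else (stratum,)
    counts: dict[str, dict[str, int]] = {locus: {} for locus in g.loci}
    for s in g.samples:
        if s.sex not in sexes:
            continue
        for locus in g.loci:
            call = s.call(locus)
            if call is None:
                continue
            c = counts[locus]
            for a in call:
                c[a] = c.get(a, 0) + 1
    return counts


def allele_frequencies(g: GenotypeTable, stratum: str = "pooled") -> AlleleFrequencyTable:
    """Estimate per-locus allele frequencies for one stratum.

    Loci with no typed sample in the stratum are omitted from the result
    (flagged absent) rather than zero-filled.
    """
    counts = allele_counts(g, stratum)
    loci: dict[str, LocusFrequencies] = {}
    for locus, c in counts.items():
        if not c:
            log.warning("locus %s: no typed %s samples; omitted", locus, stratum)
            continue
        labels = sorted(c, key=allele_sort_key)
        n = sum(c.values())
        freqs = np.array([c[a] for a in labels], dtype=float) / n
        loci[locus] = LocusFrequencies(labels, freqs, n)
    return AlleleFrequencyTable(loci)


@dataclass
class GroupHaplotypes:
    """Male haplotype counts for one linkage group."""

    group: LinkageGroupDef
    counts: dict[str, int]  # haplotype label -> number of males carrying it
    n_males: int            # males typed at every locus of the group

    @property
    def frequencies(self) -> dict[str, float]:
        return {h: c / self.n_males for h, c in self.counts.items()}

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)

    def frequency_vector(self) -> LocusFrequencies:
        """The haplotype distribution as a frequency vector (for the forensic
        formulas, which are agnostic to whether units are alleles or
        haplotypes).  Labels keep the joined haplotype string."""
        labels = sorted(self.counts)
        freqs = np.array([self.counts[h] for h in labels], dtype=float) / self.n_males
        lf = LocusFrequencies.__new__(LocusFrequencies)
        lf.alleles = labels  # haplotype labels do not obey allele nomenclature
        lf.freqs = freqs
        lf.n = self.n_males
        return lf


@dataclass
class HaplotypeTable:
    """Per-linkage-group male haplotype counts and frequencies."""

    groups: dict[str, GroupHaplotypes]

    def __getitem__(self, name: str) -> GroupHaplotypes:
        if name not in self.groups:
            raise KeyError(f"unknown linkage group {name!r}")
        return self.groups[name]


def haplotype_frequencies(g: GenotypeTable,
                          lgs: tuple[LinkageGroupDef, ...]) -> HaplotypeTable:
    """Count male haplotypes per linkage group by direct counting.

    A male enters a group's count only if typed at every locus of the group;
    females are excluded (phase unknown).
    """
    n_females = len(g.females)
    if n_females:
        log.info("haplotype counting: %d female samples excluded (phase unknown)",
                 n_females)
    groups: dict[str, GroupHaplotypes] = {}
    for lg in lgs:
        counts: dict[str, int] = {}
        n_males = 0
        for s in g.males:
            calls = [s.call(locus) for locus in lg.loci]
            if any(c is None for c in calls):
                continue
            n_males += 1
            label = HAPLOTYPE_SEP.join(c[0] for c in calls)
            counts[label] = counts.get(label, 0) + 1
        groups[lg.name] = GroupHaplotypes(lg, counts, n_males)
    return HaplotypeTable(groups)


def singleton_fraction(h: HaplotypeTable, group: str) -> float:
    """Fraction of distinct haplotypes observed exactly once in a group."""
    gh = h[group]
    if gh.n_distinct == 0:
        raise ValueError(f"group {group}: no haplotypes")
    return gh.n_singletons / gh.n_distinct
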