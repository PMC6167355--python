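"""Forensic parameter suite for X-STR loci and linkage-group haplotypes.

Everything is a polynomial in the power sums of the frequency vector
``p`` (allele or haplotype frequencies): ``s2 = sum p_i^2``,
``s3 = sum p_i^3``, ``s4 = sum p_i^4``.

* gene / haplotype diversity  GD = N/(N-1) * (1 - s2)   (bias-corrected)
* match probability           MP = s2
* power of discrimination     PD_m = 1 - s2 (hemizygous males),
                              PD_f = 1 - 2*s2^2 + s4 (diploid female genotypes)
* polymorphism information content  PIC = 1 - s2 - s2^2 + s4
* mean exclusion chance (MEC), the probability that a random unrelated man
  is excluded from paternity:
    - Krueger: autosomal-style trio (mother, child, alleged father diploid)
    - trio with a daughter on X (the father passes his single X):
      the Desmarais form equals the PIC identically; the Kishida form is
      evaluated here through its case decomposition over mother/daughter
      configurations, which reduces to the same polynomial
    - Desmarais duo: father/daughter (or mother/son) duos, 1 - 2*s2 + s3

Each closed form is guarded in the test suite by an independent exhaustive
enumeration over genotype configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, getcontext, ROUND_HALF_UP

import numpy as np

from .core import GenotypeTable

__all__ = [
    "PowerSums", "power_sums", "diversity", "match_probability",
    "pd_male", "pd_female", "pic", "mec_kruger", "mec_trio_x", "mec_duo",
    "observed_expected_het", "combined_power", "CombinedPower",
    "ForensicSummary", "round_half_up",
]


@dataclass(frozen=True)
class PowerSums:
    """Power sums s2, s3, s4 of a frequency vector."""

    s2: float
    s3: float
    s4: float

    def __post_init__(self) -> None:
        if not (1.0 + 1e-12 >= self.s2 >= self.s3 >= self.s4 > 0.0):
            raise ValueError(f"inadmissible power sums {self}")


def _as_freqs(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(p <= 0):
        raise ValueError("frequencies must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()!r}, not 1")
    return p


def power_sums(freqs) -> PowerSums:
    """Exact partial power sums, accumulated in descending-frequency order so
    the summation order (hence the float result) is deterministic."""
    p = np.sort(_as_freqs(freqs))[::-1]
    return PowerSums(float(np.sum(p**2)), float(np.sum(p**3)), float(np.sum(p**4)))


def diversity(ps: PowerSums, n: int) -> float:
    """Bias-corrected gene (or haplotype) diversity, N/(N-1) * (1 - s2)."""
    if n < 2:
        raise ValueError("diversity needs at least 2 observed chromosomes")
    return n / (n - 1) * (1.0 - ps.s2)


def match_probability(ps: PowerSums) -> float:
    return ps.s2


def pd_male(ps: PowerSums) -> float:
    """Probability two random X chromosomes (male genotypes) differ."""
    return 1.0 - ps.s2


def pd_female(ps: PowerSums) -> float:
    """Probability two random diploid HWE genotypes differ: 1 - 2*s2^2 + s4."""
    return 1.0 - 2.0 * ps.s2**2 + ps.s4


def pic(ps: PowerSums) -> float:
    """Polymorphism information content, 1 - s2 - s2^2 + s4."""
    return 1.0 - ps.s2 - ps.s2**2 + ps.s4


def mec_kruger(freqs) -> float:
    """Mean exclusion chance for an autosomal-style trio (diploid alleged
    father): sum p(1-p)^2 - sum_{i<j} (p_i p_j)^2 (4 - 3(p_i + p_j))."""
    p = _as_freqs(freqs)
    single = float(np.sum(p * (1.0 - p) ** 2))
    pp = np.outer(p, p)
    ss = np.add.outer(p, p)
    pair = (pp**2) * (4.0 - 3.0 * ss)
    cross = float(np.sum(np.triu(pair, k=1)))
    return single - cross


def mec_trio_x(freqs, variant: str = "desmarais") -> float:
    """Mean exclusion chance for an X trio with a daughter.

    The alleged father contributes a single X allele; he is excluded when his
    allele cannot be the daughter's paternal allele given the mother.

    ``desmarais`` evaluates the PIC identity 1 - s2 - s2^2 + s4 directly.
    ``kishida`` evaluates the case decomposition over mother/daughter
    configurations (homozygous daughter; heterozygous daughter with an
    unambiguous paternal allele; double-heterozygote ambiguity), which sums
    to the same quantity.
    """
    ps = power_sums(freqs)
    if variant == "desmarais":
        return pic(ps)
    if variant == "kishida":
        s2, s3, s4 = ps.s2, ps.s3, ps.s4
        hom_daughter = s2 - s3                        # daughter (x,x): exclude unless AF carries x
        het_unambig = 1.0 - 3.0 * s2 + 3.0 * s3 - s4  # paternal allele identified
        het_ambig = s2 - s2**2 - 2.0 * s3 + 2.0 * s4  # mother and daughter same heterozygote
        return hom_daughter + het_unambig + het_ambig
    raise ValueError(f"unknown trio MEC variant {variant!r}")


def mec_duo(freqs) -> float:
    """Mean exclusion chance for a father/daughter (or mother/son) duo:
    1 - 2*s2 + s3."""
    ps = power_sums(freqs)
    return 1.0 - 2.0 * ps.s2 + ps.s3


def observed_expected_het(g: GenotypeTable, locus: str) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity among typed females.

    He uses the small-sample correction 2n/(2n-1) * (1 - sum p_hat^2) with
    p_hat the female-only allele frequencies and n the number of typed
    females.
    """
    counts: dict[str, int] = {}
    n_f = 0
    n_het = 0
    for s in g.females:
        call = s.call(locus)
        if call is None:
            continue
        n_f += 1
        if call[0] != call[1]:
            n_het += 1
        for a in call:
            counts[a] = counts.get(a, 0) + 1
    if n_f == 0:
        raise ValueError(f"locus {locus}: no typed females")
    ho = n_het / n_f
    p = np.array(list(counts.values()), dtype=float) / (2 * n_f)
    if n_f < 2:
        raise ValueError(f"locus {locus}: expected heterozygosity needs >= 2 females")
    he = 2 * n_f / (2 * n_f - 1) * (1.0 - float(np.sum(p**2)))
    return ho, he


@dataclass(frozen=True)
class CombinedPower:
    """Combined (cumulative) power 1 - prod(1 - x_i), held as the complement
    product so values indistinguishable from 1 in binary floating point keep
    their full run of nines in text form."""

    complement: float          # prod(1 - x_i), in [0, 1]
    log_complement: float      # sum log(1 - x_i), -inf if any x_i == 1

    @property
    def value(self) -> float:
        """Float value; rounds to 1.0 when the complement is below ~1e-16."""
        return 1.0 - self.complement

    def text(self, digits: int = 30) -> str:
        """Full-precision decimal string, e.g. '0.999999999997106...'."""
        getcontext().prec = 60
        d = Decimal(1) - Decimal(self.complement)
        return str(+d.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))

    def __str__(self) -> str:  # trimmed of trailing zeros
        return self.text().rstrip("0")


def combined_power(values) -> CombinedPower:
    """Combine per-unit probabilities multiplicatively: 1 - prod(1 - x)."""
    values = list(values)
    if not values:
        raise ValueError("no values to combine")
    comp = 1.0
    logc = 0.0
    for x in values:
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"probability out of [0,1]: {x}")
        comp *= 1.0 - x
        logc += np.log1p(-x) if x < 1.0 else -np.inf
    return CombinedPower(comp, float(logc))


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ForensicSummary:
    """One row of a per-locus or per-linkage-group forensic report.

    All parameter fields are unitless probabilities in [0, 1].  ``ho``,
    ``he`` and ``hwe_p`` are female-genotype quantities and are ``None`` for
    haplotype (linkage-group) rows built from male data.
    """

    unit: str                 # locus or group name
    n_units: int              # number of distinct alleles or haplotypes
    gd: float                 # gene/haplotype diversity
    mp: float
    pic: float
    pd_m: float
    pd_f: float
    mec_kruger: float
    mec_kishida: float
    mec_desmarais: float
    mec_desmarais_duo: float
    n_obs: int                # chromosomes (or male haplotypes) observed
    ho: float | None = None
    he: float | None = None
    hwe_p: float | None = None

    @classmethod
    def from_frequencies(cls, unit: str, freqs, n_obs: int, **kw) -> "ForensicSummary":
        ps = power_sums(freqs)
        return cls(
            unit=unit,
            n_units=len(np.atleast_1d(freqs)),
            gd=diversity(ps, n_obs),
            mp=match_probability(ps),
            pic=pic(ps),
            pd_m=pd_male(ps),
            pd_f=pd_female(ps),
            mec_kruger=mec_kruger(freqs),
            mec_kishida=mec_trio_x(freqs, "kishida"),
            mec_desmarais=mec_trio_x(freqs, "desmarais"),
            mec_desmarais_duo=mec_duo(freqs),
            n_obs=n_obs,
            **kw,
        )
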