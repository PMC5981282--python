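"""Single-marker population genetics and two-locus linkage disequilibrium.

Statistics for one biallelic marker genotyped in one breed: allele and
genotype frequencies, expected heterozygosity (HE), polymorphic information
content (PIC), effective number of alleles (NE), and a chi-square test for
deviation from Hardy-Weinberg equilibrium. Two-locus LD (D, D', r^2) is
estimated from unphased genotypes by an EM algorithm over haplotype
frequencies.

All frequencies are computed from unrounded allele counts; :func:`round2`
reproduces the round-half-away-from-zero convention used when comparing
against published two-decimal tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "AlleleSummary",
    "HWEResult",
    "LDResult",
    "allele_frequencies",
    "marker_summary",
    "hwe_test",
    "ld_em",
    "round2",
]


def round2(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed genetics tables).

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    how published tables are typically rounded at exact .xx5 boundaries.
    """
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic marker in one sample of individuals.

    ``n_hom_ref`` counts reference-allele homozygotes, ``n_het``
    heterozygotes and ``n_hom_alt`` alternate-allele homozygotes.
    """

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for name in ("n_hom_ref", "n_het", "n_hom_alt"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_total < 1:
            raise ValueError("genotype counts must total at least one individual")

    @property
    def n_total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    def swapped(self) -> "GenotypeCounts":
        """Counts with the allele labels exchanged."""
        return GenotypeCounts(self.n_hom_alt, self.n_het, self.n_hom_ref)


@dataclass(frozen=True)
class AlleleSummary:
    """Allele frequencies and marker informativeness at a biallelic locus.

    HE = 1 - p^2 - q^2 is the expected heterozygosity under random mating,
    PIC = HE - 2 p^2 q^2 the polymorphic information content, and
    NE = 1 / (p^2 + q^2) the effective number of alleles.
    """

    p: float
    q: float
    he: float
    pic: float
    ne: float


@dataclass(frozen=True)
class HWEResult:
    """Chi-square goodness-of-fit test against Hardy-Weinberg proportions."""

    chi2: float
    df: int
    p_value: float
    testable: bool = True


@dataclass(frozen=True)
class LDResult:
    """Two-locus linkage disequilibrium from EM haplotype frequencies.

    ``haplotype_freqs`` is (f_AB, f_Ab, f_aB, f_ab) with A/B the reference
    alleles at loci 1 and 2. D = f_AB - p1 p2, D' = |D| / D_max and
    r2 = D^2 / (p1 q1 p2 q2).
    """

    haplotype_freqs: tuple[float, float, float, float]
    d: float
    d_prime: float
    r2: float
    n_iter: int
    converged: bool
    defined: bool = True
    log_likelihoods: tuple[float, ...] = field(default=(), repr=False)


def allele_frequencies(g: GenotypeCounts) -> tuple[float, float]:
    """Reference (p) and alternate (q) allele frequencies by gene counting."""
    n2 = 2 * g.n_total
    p = (2 * g.n_hom_ref + g.n_het) / n2
    return p, 1.0 - p


def marker_summary(g: GenotypeCounts) -> AlleleSummary:
    """HE, PIC and NE at one marker, computed from unrounded frequencies."""
    p, q = allele_frequencies(g)
    he = 1.0 - p * p - q * q
    pic = he - 2.0 * p * p * q * q
    ne = 1.0 / (p * p + q * q)
    return AlleleSummary(p=p, q=q, he=he, pic=pic, ne=ne)


def hwe_test(g: GenotypeCounts) -> HWEResult:
    """Chi-square test for departure from Hardy-Weinberg proportions.

    Expected counts are (N p^2, 2 N p q, N q^2) with p estimated from the
    observed genotypes, giving one degree of freedom (three classes minus one
    minus one estimated parameter). No continuity correction is applied. A
    monomorphic marker is not testable and is returned flagged rather than
    raising.
    """
    p, q = allele_frequencies(g)
    if p == 0.0 or p == 1.0:
        return HWEResult(chi2=float("nan"), df=1, p_value=float("nan"), testable=False)
    n = g.n_total
    expected = np.array([n * p * p, 2.0 * n * p * q, n * q * q])
    observed = np.array([g.n_hom_ref, g.n_het, g.n_hom_alt], dtype=float)
    if expected.min() < 5.0:
        warnings.warn(
            "expected genotype count below 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(chi2=chi2, df=1, p_value=float(stats.chi2.sf(chi2, 1)), testable=True)


def _genotype_class_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype counts, genotypes coded 0/1/2 ref alleles."""
    tab = np.zeros((3, 3), dtype=float)
    for a, b in zip(g1, g2):
        tab[a, b] += 1
    return tab


def _ld_loglik(tab: np.ndarray, f: np.ndarray) -> float:
    fab, fAb, faB, fAB = f[3], f[1], f[2], f[0]  # noqa: N806 - haplotype labels
    probs = np.array(
        [
            [fab * fab, 2 * faB * fab, faB * faB],
            [2 * fAb * fab, 2 * fAB * fab + 2 * fAb * faB, 2 * fAB * faB],
            [fAb * fAb, 2 * fAB * fAb, fAB * fAB],
        ]
    )
    mask = tab > 0
    with np.errstate(divide="ignore"):
        return float((tab[mask] * np.log(probs[mask])).sum())


def ld_em(
    genotypes_locus1,
    genotypes_locus2,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LDResult:
    """Estimate two-locus haplotype frequencies and LD by EM.

    Parameters
    ----------
    genotypes_locus1, genotypes_locus2
        Per-individual genotypes at the two loci, coded as the number of
        reference alleles (0, 1 or 2); negative or NaN entries are treated as
        missing and the individual is dropped pairwise.
    tol
        Convergence threshold on the maximum absolute change of any haplotype
        frequency between iterations.
    max_iter
        Iteration cap; non-convergence warns and returns the last iterate.

    Only double heterozygotes carry phase ambiguity; the E-step splits them
    between the AB/ab and Ab/aB configurations in proportion to the current
    haplotype-frequency products. Frequencies are initialised at linkage
    equilibrium. The observed-data log-likelihood is recorded each iteration
    (it is non-decreasing, a property the test suite asserts).
    """
    g1 = np.asarray(genotypes_locus1, dtype=float)
    g2 = np.asarray(genotypes_locus2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    keep = np.isfinite(g1) & np.isfinite(g2) & (g1 >= 0) & (g2 >= 0)
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    if g1.size < 2:
        raise ValueError("need at least two individuals with calls at both loci")
    if np.any((g1 > 2) | (g2 > 2)):
        raise ValueError("genotypes must be coded 0/1/2 reference-allele counts")

    p1 = g1.mean() / 2.0
    p2 = g2.mean() / 2.0
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return LDResult(
            haplotype_freqs=(float("nan"),) * 4,
            d=float("nan"),
            d_prime=float("nan"),
            r2=float("nan"),
            n_iter=0,
            converged=False,
            defined=False,
        )

    tab = _genotype_class_counts(g1, g2)
    n_hap = 2.0 * g1.size
    n11 = tab[1, 1]  # double heterozygotes

    # unambiguous haplotype contributions (counted once, outside the loop)
    base = np.array(
        [
            2 * tab[2, 2] + tab[2, 1] + tab[1, 2],  # AB
            2 * tab[2, 0] + tab[2, 1] + tab[1, 0],  # Ab
            2 * tab[0, 2] + tab[0, 1] + tab[1, 2],  # aB
            2 * tab[0, 0] + tab[0, 1] + tab[1, 0],  # ab
        ],
        dtype=float,
    )

    q1, q2 = 1.0 - p1, 1.0 - p2
    f = np.array([p1 * p2, p1 * q2, q1 * p2, q1 * q2])
    lls = [_ld_loglik(tab, f)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = f[0] * f[3]  # AB/ab ("cis") weight
        trans = f[1] * f[2]
        w = 0.5 if cis + trans == 0.0 else cis / (cis + trans)
        counts = base + n11 * np.array([w, 1.0 - w, 1.0 - w, w])
        f_new = counts / n_hap
        delta = np.abs(f_new - f).max()
        f = f_new
        lls.append(_ld_loglik(tab, f))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"LD EM did not converge in {max_iter} iterations", stacklevel=2)

    p1_hat = f[0] + f[1]
    p2_hat = f[0] + f[2]
    q1_hat, q2_hat = 1.0 - p1_hat, 1.0 - p2_hat
    d = f[0] - p1_hat * p2_hat
    if d > 0:
        d_max = min(p1_hat * q2_hat, q1_hat * p2_hat)
    else:
        d_max = min(p1_hat * p2_hat, q1_hat * q2_hat)
    d_prime = 0.0 if d == 0.0 else abs(d) / d_max
    denom = p1_hat * q1_hat * p2_hat * q2_hat
    r2 = d * d / denom
    return LDResult(
        haplotype_freqs=tuple(float(x) for x in f),
        d=float(d),
        d_prime=float(d_prime),
        r2=float(r2),
        n_iter=it,
        converged=converged,
        defined=True,
        log_likelihoods=tuple(lls),
    )
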