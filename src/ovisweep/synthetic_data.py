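"""Simulators with the statistical structure the analyses assume.

Every generator is a pure function of (config, seed): the same seed yields
identical output. A single global seed fans out to per-operation child seeds
through :func:`child_seed`, which hashes the operation name into a
``numpy.random.SeedSequence`` spawn key, so any subset of a run is
reproducible in isolation.

The generators provide ground truth the real study cannot: the implanted
sweep interval, the true litter-size cell means and the true expression
shifts are returned alongside the data so downstream modules can be tested
for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import PooledSiteFrequency
from .popgen import GenotypeCounts

__all__ = [
    "SimConfig",
    "PhenoSimConfig",
    "SweepTruth",
    "PhenotypeRecord",
    "CtRecord",
    "child_seed",
    "simulate_divergent_pools",
    "simulate_genotype_counts",
    "simulate_litter_sizes",
    "simulate_ct_table",
]


def child_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Derive a named child seed from the global seed (documented fan-out)."""
    key = sum(ord(c) * 31**i for i, c in enumerate(label)) % (2**31)
    return np.random.SeedSequence(entropy=seed, spawn_key=(key,))


@dataclass(frozen=True)
class SimConfig:
    """Two pooled breed groups along one chromosome with an implanted sweep.

    Defaults mirror the scan's study conditions: 10,000 SNPs over a 5-Mb
    chromosome, background divergence F = 0.05, a 100-kb interval of strong
    divergence F = 0.5, and pool sizes of 30 vs 59 animals (the high- and
    low-fecundity pools of a multi-breed contrast).
    """

    seed: int = 0
    n_sites: int = 10_000
    chrom: str = "17"
    chrom_length: int = 5_000_000
    sweep_interval: tuple[int, int] = (2_450_001, 2_550_000)
    f_background: float = 0.05
    f_sweep: float = 0.5
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_group_a: int = 30
    n_group_b: int = 59

    def __post_init__(self) -> None:
        if not 0.0 < self.f_background < 1.0 or not 0.0 < self.f_sweep < 1.0:
            raise ValueError("divergence parameters must lie in (0, 1)")
        if self.f_sweep <= self.f_background:
            raise ValueError("f_sweep must exceed f_background")
        lo, hi = self.sweep_interval
        if not 1 <= lo < hi <= self.chrom_length:
            raise ValueError("sweep_interval must lie within the chromosome")
        a, b = self.ancestral_freq_range
        if not 0.0 < a < b < 1.0:
            raise ValueError("ancestral_freq_range must lie strictly inside (0, 1)")
        if self.n_sites > self.chrom_length:
            raise ValueError("more sites than positions")


@dataclass(frozen=True)
class SweepTruth:
    """The implanted high-divergence interval, for recovery tests."""

    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class PhenotypeRecord:
    """One ewe-parity litter-size observation."""

    ewe_id: str
    parity: int
    genotype: int
    litter_size: float


@dataclass(frozen=True)
class CtRecord:
    """One qPCR replicate: target and reference-gene threshold cycles."""

    tissue: str
    group: str
    replicate: int
    ct_target: float
    ct_reference: float


def simulate_divergent_pools(config: SimConfig) -> tuple[list[PooledSiteFrequency], SweepTruth]:
    """Pooled frequencies for two groups under a Balding-Nichols model.

    Site positions are drawn uniformly without replacement and sorted. At
    each site an ancestral frequency p is drawn uniformly from
    ``ancestral_freq_range``; each group's frequency is then an independent
    Beta draw with mean p and divergence F (shapes p(1-F)/F and
    (1-p)(1-F)/F), where F is ``f_sweep`` inside the sweep interval and
    ``f_background`` elsewhere.
    """
    rng = np.random.default_rng(child_seed(config.seed, "pools"))
    pos = np.sort(rng.choice(config.chrom_length, size=config.n_sites, replace=False)) + 1
    anc = rng.uniform(*config.ancestral_freq_range, size=config.n_sites)
    lo, hi = config.sweep_interval
    in_sweep = (pos >= lo) & (pos <= hi)
    f = np.where(in_sweep, config.f_sweep, config.f_background)
    a = anc * (1.0 - f) / f
    b = (1.0 - anc) * (1.0 - f) / f
    p_a = rng.beta(a, b)
    p_b = rng.beta(a, b)
    sites = [
        PooledSiteFrequency(
            chrom=config.chrom,
            pos=int(pos[i]),
            p_ref_a=float(p_a[i]),
            p_ref_b=float(p_b[i]),
            n_alleles_a=2 * config.n_group_a,
            n_alleles_b=2 * config.n_group_b,
        )
        for i in range(config.n_sites)
    ]
    return sites, SweepTruth(chrom=config.chrom, start=lo, end=hi)


def simulate_genotype_counts(
    n: int, p: float, d: float = 0.0, seed: int = 0
) -> GenotypeCounts:
    """Multinomial genotype counts at frequency p with HWE disequilibrium D.

    Genotype probabilities are (p^2 + D, 2pq - 2D, q^2 + D); D = 0 is
    Hardy-Weinberg equilibrium. An infeasible D raises with the feasible
    range [-min(p^2, q^2), pq].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    q = 1.0 - p
    d_lo, d_hi = -min(p * p, q * q), p * q
    if not d_lo <= d <= d_hi:
        raise ValueError(f"infeasible D={d}; feasible range is [{d_lo:.6g}, {d_hi:.6g}]")
    probs = np.array([p * p + d, 2 * p * q - 2 * d, q * q + d])
    rng = np.random.default_rng(child_seed(seed, "genotypes"))
    counts = rng.multinomial(n, probs)
    return GenotypeCounts(int(counts[0]), int(counts[1]), int(counts[2]))


@dataclass(frozen=True)
class PhenoSimConfig:
    """Litter sizes from the two-way fixed-effects model y = mu + P + G + PG + e.

    Defaults reflect a prolific-breed litter-size study: overall mean 2.3
    lambs, a strong third-parity lift, heterozygote advantage at the marker,
    and residual sd 0.75 (the scale implied by printed SEs near 0.06 at cell
    sizes around 150). Each simulated ewe keeps one genotype across all
    parities.
    """

    mu: float = 2.3
    parity_effects: tuple[float, float, float] = (-0.15, 0.0, 0.55)
    genotype_effects: tuple[float, float, float] = (-0.1, 0.2, 0.0)
    interaction_effects: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
    )
    residual_sd: float = 0.75
    n_per_cell: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if len(self.interaction_effects) != 3 or any(
            len(row) != 3 for row in self.interaction_effects
        ):
            raise ValueError("interaction_effects must be 3x3")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")

    def cell_mean(self, parity: int, genotype: int) -> float:
        """True mean of cell (parity, genotype), levels 1-based."""
        return (
            self.mu
            + self.parity_effects[parity - 1]
            + self.genotype_effects[genotype - 1]
            + self.interaction_effects[parity - 1][genotype - 1]
        )


def simulate_litter_sizes(config: PhenoSimConfig) -> list[PhenotypeRecord]:
    """Draw litter-size records; ``n_per_cell`` ewes per genotype and parity.

    Genotype is a property of the ewe: ewe ``G{j}_{k}`` carries genotype j at
    every parity. Residuals are independent Normal(0, residual_sd^2); litter
    size is simulated on the continuous scale the fixed-effects model
    assumes.
    """
    rng = np.random.default_rng(child_seed(config.seed, "phenotypes"))
    records = []
    for genotype in (1, 2, 3):
        for k in range(config.n_per_cell):
            ewe = f"G{genotype}_{k}"
            for parity in (1, 2, 3):
                y = config.cell_mean(parity, genotype) + rng.normal(0.0, config.residual_sd)
                records.append(
                    PhenotypeRecord(ewe_id=ewe, parity=parity, genotype=genotype, litter_size=float(y))
                )
    return records


def simulate_ct_table(
    tissues: Sequence[str] = ("ovary",),
    groups: Sequence[str] = ("high_fecundity", "low_fecundity"),
    delta_ct_shift: Mapping[str, float] | None = None,
    sd: float = 0.2,
    seed: int = 0,
    n_replicates: int = 3,
    baseline_delta_ct: float = 5.0,
    reference_ct_mean: float = 20.0,
) -> list[CtRecord]:
    """qPCR Ct tables with per-group expression shifts.

    The reference-gene Ct is Normal(``reference_ct_mean``, sd^2); the target
    Ct equals the reference Ct plus a baseline dCt, the group's dCt shift
    (negative = earlier amplification = higher expression) and independent
    noise. Three biological replicates per tissue and group by default.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n_replicates < 1:
        raise ValueError("need at least one replicate per tissue and group")
    shifts = dict(delta_ct_shift or {})
    rng = np.random.default_rng(child_seed(seed, "ct"))
    records = []
    for tissue in tissues:
        for group in groups:
            shift = shifts.get(group, 0.0)
            for rep in range(1, n_replicates + 1):
                ref = rng.normal(reference_ct_mean, sd)
                target = ref + baseline_delta_ct + shift + rng.normal(0.0, sd)
                records.append(
                    CtRecord(
                        tissue=tissue,
                        group=group,
                        replicate=rep,
                        ct_target=float(target),
                        ct_reference=float(ref),
                    )
                )
    return records
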