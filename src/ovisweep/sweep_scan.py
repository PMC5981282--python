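"""Genome scan for selective sweeps from pooled two-group allele frequencies.

The scan computes, along a chromosome: per-site FST between the two breed
groups, windowed FST (50-kb windows sliding by 25 kb, ratio of sums),
windowed pooled heterozygosity H = 2*sum(p)*sum(q)/(sum(p)+sum(q))^2 per
group (20-kb windows, 10-kb step), and per-site allele-frequency differences
dAF = |p_A - p_B|. Window statistics are Z-standardized as |x - mean| / sd
over all defined windows genome-wide, and runs of significant windows
(Z above a fixed threshold or a genome-wide quantile) are merged into
candidate sweep regions, which can then be annotated with overlapping genes.

FST is the Nei/Hudson-style (H_T - H_S) / H_T on pooled frequencies, with
no finite-sample correction: it is exactly 0 under equal group frequencies
and needs only the pooled proportions the input carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GeneInterval, PooledSiteFrequency

__all__ = [
    "WindowStat",
    "SweepRegion",
    "site_fst",
    "window_fst",
    "pooled_heterozygosity",
    "z_standardize",
    "delta_af",
    "delta_af_threshold",
    "call_regions",
    "annotate_regions",
]

FST_WINDOW = 50_000
FST_STEP = 25_000
H_WINDOW = 20_000
H_STEP = 10_000
MIN_SITES_FST = 3


@dataclass(frozen=True)
class WindowStat:
    """One sliding window and its raw (x) and standardized (z) statistic.

    Coordinates are 1-based inclusive. ``x`` is None for windows with fewer
    than the minimum number of sites; such windows are excluded from
    standardization and region calling. ``partial`` flags a terminal window
    extending past the last site.
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    x: float | None = None
    z: float | None = None
    partial: bool = False


@dataclass(frozen=True)
class SweepRegion:
    """A merged run of significant windows."""

    chrom: str
    start: int
    end: int
    peak_z: float
    n_windows: int
    genes: tuple[str, ...] = ()


def _fst_components(p_a: float, p_b: float) -> tuple[float, float]:
    """(H_T - H_S, H_T) for one site."""
    p_bar = 0.5 * (p_a + p_b)
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    h_s = p_a * (1.0 - p_a) + p_b * (1.0 - p_b)  # mean of 2p(1-p) per group
    return h_t - h_s, h_t


def site_fst(site: PooledSiteFrequency) -> float:
    """Per-site FST (H_T - H_S)/H_T; 0 when the site is monomorphic overall."""
    num, den = _fst_components(site.p_ref_a, site.p_ref_b)
    return 0.0 if den == 0.0 else num / den


def delta_af(site: PooledSiteFrequency) -> float:
    """Absolute reference-allele frequency difference between the groups."""
    return abs(site.p_ref_a - site.p_ref_b)


def delta_af_threshold(sites: Sequence[PooledSiteFrequency], quantile: float = 0.05) -> float:
    """Genome-wide top-``quantile`` threshold for per-site dAF."""
    vals = np.array([delta_af(s) for s in sites])
    if vals.size == 0:
        raise ValueError("no sites")
    return float(np.quantile(vals, 1.0 - quantile))


def _iter_chrom_blocks(sites: Sequence[PooledSiteFrequency]):
    start = 0
    for i in range(1, len(sites) + 1):
        if i == len(sites) or sites[i].chrom != sites[start].chrom:
            yield sites[start].chrom, sites[start:i]
            start = i


def _windowed_ratio_of_sums(
    sites: Sequence[PooledSiteFrequency],
    numden,
    window_size: int,
    step: int,
    min_sites: int,
) -> list[WindowStat]:
    """Shared sliding-window machinery: x = sum(num)/sum(den) per window.

    ``numden(block)`` maps a chromosome block of sites to per-site (num, den)
    arrays; the reduction within each window is a ratio of sums.
    """
    if window_size % step != 0:
        raise ValueError("window_size must be a multiple of step")
    out: list[WindowStat] = []
    for chrom, block in _iter_chrom_blocks(sites):
        pos = np.array([s.pos for s in block])
        num, den = numden(block)
        cnum = np.concatenate([[0.0], np.cumsum(num)])
        cden = np.concatenate([[0.0], np.cumsum(den)])
        max_pos = int(pos[-1])
        for w_start in range(1, max_pos + 1, step):
            w_end = w_start + window_size - 1
            i0 = int(np.searchsorted(pos, w_start, side="left"))
            i1 = int(np.searchsorted(pos, w_end, side="right"))
            n = i1 - i0
            if n >= min_sites:
                dsum = cden[i1] - cden[i0]
                x = 0.0 if dsum == 0.0 else float((cnum[i1] - cnum[i0]) / dsum)
            else:
                x = None
            out.append(
                WindowStat(
                    chrom=chrom,
                    start=w_start,
                    end=w_end,
                    n_sites=n,
                    x=x,
                    partial=w_end > max_pos,
                )
            )
    return out


def window_fst(
    sites: Sequence[PooledSiteFrequency],
    window_size: int = FST_WINDOW,
    step: int = FST_STEP,
    min_sites: int = MIN_SITES_FST,
) -> list[WindowStat]:
    """Windowed FST as a ratio of sums, sum(H_T - H_S) / sum(H_T).

    Windows slide in ``step`` increments from position 1 to the last site of
    each chromosome; windows with fewer than ``min_sites`` SNPs are kept but
    carry ``x=None`` (sparse windows make the Z-scan unstable). Sites must be
    sorted by (chrom, pos).
    """

    def numden(block):
        comps = np.array([_fst_components(s.p_ref_a, s.p_ref_b) for s in block])
        return comps[:, 0], comps[:, 1]

    return _windowed_ratio_of_sums(sites, numden, window_size, step, min_sites)


def pooled_heterozygosity(
    sites: Sequence[PooledSiteFrequency],
    group: str = "a",
    window_size: int = H_WINDOW,
    step: int = H_STEP,
    min_sites: int = 1,
) -> list[WindowStat]:
    """Windowed pooled heterozygosity H = 2*Sp*Sq/(Sp+Sq)^2 for one group.

    Sp and Sq are the sums of per-site major- and minor-allele frequencies
    over the SNPs in the window, with major/minor assigned per site within
    the group. ``group`` is "a", "b", or "pooled" (allele-count-weighted
    average of the two groups).
    """
    if group not in ("a", "b", "pooled"):
        raise ValueError(f"group must be 'a', 'b' or 'pooled', got {group!r}")

    def numden(block):
        if group == "a":
            p = np.array([s.p_ref_a for s in block])
        elif group == "b":
            p = np.array([s.p_ref_b for s in block])
        else:
            p = np.array(
                [
                    (s.p_ref_a * s.n_alleles_a + s.p_ref_b * s.n_alleles_b)
                    / (s.n_alleles_a + s.n_alleles_b)
                    for s in block
                ]
            )
        major = np.maximum(p, 1.0 - p)
        return major, np.ones_like(major)

    # H is not a plain ratio of sums, so aggregate Sp and site counts via the
    # shared windower and finish the formula here: with n sites per window,
    # Sp + Sq = n, hence H = 2*Sp*(n - Sp)/n^2 and Sp = x*n (x = mean major).
    stats = _windowed_ratio_of_sums(sites, numden, window_size, step, min_sites)
    out = []
    for w in stats:
        if w.x is None:
            out.append(w)
            continue
        sp = w.x * w.n_sites
        sq = w.n_sites - sp
        h = 2.0 * sp * sq / (sp + sq) ** 2
        out.append(replace(w, x=float(h)))
    return out


def z_standardize(windows: Iterable[WindowStat]) -> list[WindowStat]:
    """Fill z = |x - mean(x)| / sd(x) over all defined windows genome-wide.

    The standard deviation uses the population (n) denominator. A degenerate
    scan with sd = 0 sets every z to 0 and warns.
    """
    windows = list(windows)
    xs = np.array([w.x for w in windows if w.x is not None])
    if xs.size < 2:
        raise ValueError("need at least two defined windows to standardize")
    mu = float(xs.mean())
    sd = float(xs.std(ddof=0))
    # identical x values can leave a rounding-level residual sd; treat any
    # spread below machine precision relative to the mean as degenerate
    if sd <= 1e-12 * max(1.0, abs(mu)):
        sd = 0.0
        warnings.warn("all window statistics identical; z set to 0", stacklevel=2)
    out = []
    for w in windows:
        if w.x is None:
            out.append(w)
        else:
            z = 0.0 if sd == 0.0 else abs(w.x - mu) / sd
            out.append(replace(w, z=float(z)))
    return out


def call_regions(
    windows: Sequence[WindowStat],
    z_threshold: float | None = 5.0,
    quantile: float | None = None,
    require_above_mean: bool = True,
) -> list[SweepRegion]:
    """Merge significant windows into candidate sweep regions.

    A window is significant when its z exceeds ``z_threshold``, or lies in
    the top ``quantile`` of z genome-wide when ``quantile`` is given (the
    quantile mode overrides the fixed threshold). Because z is an absolute
    deviation it also flags unusually *low* windows; ``require_above_mean``
    (default) restricts calling to windows with x above the genome-wide mean,
    i.e. elevated divergence. Overlapping or abutting significant windows on
    one chromosome merge into a single region spanning their union;
    ``peak_z`` is the maximum member z.
    """
    defined = [w for w in windows if w.x is not None and w.z is not None]
    if not defined:
        return []
    zs = np.array([w.z for w in defined])
    if quantile is not None:
        cut = float(np.quantile(zs, 1.0 - quantile))
        sig = [w for w in defined if w.z >= cut]
    else:
        if z_threshold is None:
            raise ValueError("either z_threshold or quantile must be given")
        sig = [w for w in defined if w.z > z_threshold]
    if require_above_mean:
        mu = float(np.mean([w.x for w in defined]))
        sig = [w for w in sig if w.x > mu]
    sig.sort(key=lambda w: (w.chrom, w.start))

    regions: list[SweepRegion] = []
    cur: list[WindowStat] = []
    for w in sig:
        if cur and w.chrom == cur[-1].chrom and w.start <= max(c.end for c in cur) + 1:
            cur.append(w)
        else:
            if cur:
                regions.append(_finish_region(cur))
            cur = [w]
    if cur:
        regions.append(_finish_region(cur))
    return regions


def _finish_region(members: list[WindowStat]) -> SweepRegion:
    return SweepRegion(
        chrom=members[0].chrom,
        start=min(w.start for w in members),
        end=max(w.end for w in members),
        peak_z=max(w.z for w in members),
        n_windows=len(members),
    )


def annotate_regions(
    regions: Sequence[SweepRegion], genes: Sequence[GeneInterval]
) -> list[SweepRegion]:
    """Attach the names of genes overlapping each region by >= 1 bp."""
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    out = []
    for r in regions:
        cand = by_chrom.get(r.chrom, [])
        starts = np.array([g.start for g in cand])
        # genes starting after the region end cannot overlap
        hi = int(np.searchsorted(starts, r.end, side="right"))
        names = tuple(g.name for g in cand[:hi] if g.end >= r.start)
        out.append(replace(r, genes=names))
    return out
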