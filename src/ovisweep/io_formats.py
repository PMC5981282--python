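"""Readers and writers for the formats the pipeline touches.

VCF is read with cyvcf2 into pooled per-group allele frequencies; genotype
count tables, site-frequency tables and window statistics travel as
tab-separated files with declared headers; sweep regions are written as BED6.
Coordinates are 1-based inclusive everywhere inside the package (the VCF
convention); only BED output/input converts to and from 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .popgen import GenotypeCounts

__all__ = [
    "PooledSiteFrequency",
    "GeneInterval",
    "VcfReadResult",
    "read_pooled_vcf",
    "read_site_frequency_tsv",
    "write_site_frequency_tsv",
    "read_genotype_table",
    "write_genotype_table",
    "write_regions_bed",
    "read_regions_bed",
    "read_gene_bed",
    "read_gene_gff",
]

GENOTYPE_TABLE_COLUMNS = ["breed", "locus", "n_AA", "n_Aa", "n_aa"]
SITE_FREQ_COLUMNS = ["chrom", "pos", "p_ref_a", "p_ref_b", "n_alleles_a", "n_alleles_b"]


@dataclass(frozen=True)
class PooledSiteFrequency:
    """Reference-allele frequency of one biallelic SNP in two breed groups.

    ``pos`` is 1-based. ``p_ref_a``/``p_ref_b`` are the pooled
    reference-allele proportions in groups A and B; ``n_alleles_a``/``_b``
    the called allele totals behind them.
    """

    chrom: str
    pos: int
    p_ref_a: float
    p_ref_b: float
    n_alleles_a: int
    n_alleles_b: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("p_ref_a", "p_ref_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_alleles_a", "n_alleles_b"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic span, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} for {self.name}"
            )


class VcfReadResult(NamedTuple):
    sites: list[PooledSiteFrequency]
    n_skipped: int


def _check_sorted_unique(sites: Sequence[PooledSiteFrequency], source: str) -> None:
    seen_chroms: set[str] = set()
    prev_chrom, prev_pos = None, -1
    for s in sites:
        if s.chrom != prev_chrom:
            if s.chrom in seen_chroms:
                raise ValueError(f"{source}: chromosome {s.chrom} occurs in two blocks (unsorted)")
            seen_chroms.add(s.chrom)
            prev_chrom, prev_pos = s.chrom, s.pos
        else:
            if s.pos <= prev_pos:
                raise ValueError(
                    f"{source}: positions not strictly increasing at {s.chrom}:{s.pos}"
                )
            prev_pos = s.pos


def _group_ref_fraction(gts: list, idx: Sequence[int]) -> tuple[int, int]:
    """(# REF alleles, # called alleles) among the samples at ``idx``."""
    n_ref = n_called = 0
    for i in idx:
        for allele in gts[i][:-1]:  # last entry is the phased flag
            if allele < 0:  # missing call
                continue
            n_called += 1
            if allele == 0:
                n_ref += 1
    return n_ref, n_called


def read_pooled_vcf(
    path,
    group_a_samples: Sequence,
    group_b_samples: Sequence,
    mode: str = "pooled",
) -> VcfReadResult:
    """Pooled per-group reference-allele frequencies from a VCF.

    Only biallelic SNP records are used; multiallelic records, indels and
    sites without at least one called allele in each group are skipped and
    counted in ``n_skipped``. Missing genotypes are excluded from allele
    totals, never imputed.

    ``mode="pooled"`` (default) counts alleles over all samples of a group;
    ``mode="breed_mean"`` expects each group as a sequence of per-breed
    sample lists and averages the per-breed frequencies, which matches a
    breed-balanced rather than sample-pooled contrast.
    """
    if mode not in ("pooled", "breed_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "pooled":
        breeds_a = [list(group_a_samples)]
        breeds_b = [list(group_b_samples)]
    else:
        breeds_a = [list(b) for b in group_a_samples]
        breeds_b = [list(b) for b in group_b_samples]

    vcf = VCF(str(path))
    sample_idx = {name: i for i, name in enumerate(vcf.samples)}
    for name in [s for grp in breeds_a + breeds_b for s in grp]:
        if name not in sample_idx:
            raise ValueError(f"sample {name!r} not present in {path}")
    idx_a = [[sample_idx[s] for s in breed] for breed in breeds_a]
    idx_b = [[sample_idx[s] for s in breed] for breed in breeds_b]

    sites: list[PooledSiteFrequency] = []
    n_skipped = 0
    prev_chrom, prev_pos = None, -1
    seen_chroms: set[str] = set()
    for v in vcf:
        if v.CHROM != prev_chrom:
            if v.CHROM in seen_chroms:
                raise ValueError(f"{path}: unsorted VCF (chromosome {v.CHROM} revisited)")
            seen_chroms.add(v.CHROM)
            prev_chrom, prev_pos = v.CHROM, -1
        if v.POS < prev_pos:
            raise ValueError(f"{path}: unsorted VCF at {v.CHROM}:{v.POS}")
        prev_pos = v.POS
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        gts = v.genotypes

        def group_freq(breed_idx: list[list[int]]) -> tuple[float, int] | None:
            fracs, total_called = [], 0
            for idx in breed_idx:
                n_ref, n_called = _group_ref_fraction(gts, idx)
                total_called += n_called
                if n_called > 0:
                    fracs.append(n_ref / n_called)
            if not fracs or total_called == 0:
                return None
            return float(np.mean(fracs)), total_called

        fa = group_freq(idx_a)
        fb = group_freq(idx_b)
        if fa is None or fb is None or fa[1] < 2 or fb[1] < 2:
            n_skipped += 1
            continue
        sites.append(
            PooledSiteFrequency(
                chrom=v.CHROM,
                pos=v.POS,
                p_ref_a=fa[0],
                p_ref_b=fb[0],
                n_alleles_a=fa[1],
                n_alleles_b=fb[1],
            )
        )
    return VcfReadResult(sites=sites, n_skipped=n_skipped)


def read_site_frequency_tsv(path) -> list[PooledSiteFrequency]:
    """Read a site-frequency table (columns chrom, pos, p_ref_a, p_ref_b,
    n_alleles_a, n_alleles_b); sites must be sorted with unique positions."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    missing = [c for c in SITE_FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sites = [
        PooledSiteFrequency(
            chrom=str(r.chrom),
            pos=int(r.pos),
            p_ref_a=float(r.p_ref_a),
            p_ref_b=float(r.p_ref_b),
            n_alleles_a=int(r.n_alleles_a),
            n_alleles_b=int(r.n_alleles_b),
        )
        for r in df.itertuples()
    ]
    _check_sorted_unique(sites, str(path))
    return sites


def write_site_frequency_tsv(sites: Iterable[PooledSiteFrequency], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SITE_FREQ_COLUMNS)
        for s in sites:
            w.writerow(
                [s.chrom, s.pos, repr(s.p_ref_a), repr(s.p_ref_b), s.n_alleles_a, s.n_alleles_b]
            )


def read_genotype_table(path) -> list[tuple[str, str, GenotypeCounts]]:
    """Read a genotype-count table: breed, locus, n_AA, n_Aa, n_aa.

    Counts are homozygote-ref, heterozygote, homozygote-alt. Negative,
    non-integer or all-zero rows are fatal, reported with their row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"breed": str, "locus": str})
    missing = [c for c in GENOTYPE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: list[tuple[str, str, GenotypeCounts]] = []
    for i, r in enumerate(df.itertuples(), start=2):  # row 1 is the header
        counts = (r.n_AA, r.n_Aa, r.n_aa)
        for v in counts:
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{path} row {i}: counts must be non-negative integers, got {v}")
        if sum(counts) < 1:
            raise ValueError(f"{path} row {i}: all genotype counts are zero")
        out.append((str(r.breed), str(r.locus), GenotypeCounts(*(int(v) for v in counts))))
    return out


def write_genotype_table(entries: Iterable[tuple[str, str, GenotypeCounts]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENOTYPE_TABLE_COLUMNS)
        for breed, locus, g in entries:
            w.writerow([breed, locus, g.n_hom_ref, g.n_het, g.n_hom_alt])


def write_regions_bed(regions, path) -> None:
    """Write sweep regions as BED6 (0-based half-open, score = peak Z to 2 dp).

    Regions are expected to be merged upstream: overlapping regions on one
    chromosome are a contract violation and raise.
    """
    regs = sorted(regions, key=lambda r: (r.chrom, r.start))
    for prev, cur in zip(regs, regs[1:]):
        if cur.chrom == prev.chrom and cur.start <= prev.end:
            raise ValueError(
                f"overlapping regions {prev.chrom}:{prev.start}-{prev.end} and "
                f"{cur.chrom}:{cur.start}-{cur.end}; merging contract violated upstream"
            )
    with open(path, "w", newline="") as fh:
        for i, r in enumerate(regs, start=1):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i}\t{r.peak_z:.2f}\t.\n")


def read_regions_bed(path) -> list[tuple[str, int, int, float]]:
    """Parse a BED6 region file back to (chrom, start, end, score) with
    1-based inclusive coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2]), float(parts[4])))
    return out


def read_gene_bed(path) -> list[GeneInterval]:
    """Gene intervals from BED (>= 4 columns: chrom, start, end, name)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: gene BED needs at least 4 columns")
            genes.append(
                GeneInterval(chrom=parts[0], start=int(parts[1]) + 1, end=int(parts[2]), name=parts[3])
            )
    return genes


def read_gene_gff(path, feature_types: Sequence[str] = ("gene",)) -> list[GeneInterval]:
    """Gene intervals from GFF3/GTF; name taken from Name/gene_name/gene_id/ID."""
    from gffutils.iterators import DataIterator

    genes = []
    for feat in DataIterator(str(Path(path))):
        if feature_types and feat.featuretype not in feature_types:
            continue
        name = None
        for key in ("Name", "gene_name", "gene_id", "ID"):
            if key in feat.attributes:
                name = feat.attributes[key][0]
                break
        genes.append(
            GeneInterval(chrom=feat.seqid, start=int(feat.start), end=int(feat.end), name=name or ".")
        )
    return genes
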