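"""Shared fixtures: in-memory VCF construction and deterministic hypothesis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ovisweep",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ovisweep")

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=17,length=100000000>\n'
    '##contig=<ID=18,length=100000000>\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def make_vcf(path, samples, records):
    """Write a minimal VCF.

    ``records`` are (chrom, pos, ref, alt_field, genotype_strings); the alt
    field may contain commas (multiallelic) or multi-base alleles (indels).
    """
    lines = [VCF_HEADER.rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for chrom, pos, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def vcf_factory(tmp_path):
    def factory(samples, records, name="test.vcf"):
        return make_vcf(tmp_path / name, samples, records)

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(20180504)
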