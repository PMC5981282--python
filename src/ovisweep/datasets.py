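"""Bundled reference inputs.

The genotype counts below are the published counts for the two HIRA-region
SNPs (g.71874104G>A, upstream of the transcription start site, and
g.71833755T>C, a missense variant) genotyped across six sheep breeds in a
litter-size candidate-gene study. They are inputs to the marker-statistics
module, used by the worked examples and the reproduction checks.
"""

from __future__ import annotations

import pandas as pd

from .popgen import GenotypeCounts

__all__ = ["hira_genotype_counts", "HIRA_GENOTYPE_COUNTS"]

# breed, locus, n homozygote-ref, n heterozygote, n homozygote-alt
HIRA_GENOTYPE_COUNTS: tuple[tuple[str, str, int, int, int], ...] = (
    ("Small Tail Han", "g.71874104G>A", 42, 167, 166),
    ("Tan", "g.71874104G>A", 13, 37, 30),
    ("Sunite", "g.71874104G>A", 6, 36, 57),
    ("Suffolk", "g.71874104G>A", 4, 13, 21),
    ("Dorper", "g.71874104G>A", 5, 9, 14),
    ("Prairie Tibetan", "g.71874104G>A", 13, 48, 69),
    ("Small Tail Han", "g.71833755T>C", 215, 126, 32),
    ("Tan", "g.71833755T>C", 51, 22, 7),
    ("Sunite", "g.71833755T>C", 69, 21, 6),
    ("Suffolk", "g.71833755T>C", 36, 3, 0),
    ("Dorper", "g.71833755T>C", 30, 0, 0),
    ("Prairie Tibetan", "g.71833755T>C", 95, 22, 12),
)


def hira_genotype_counts(as_frame: bool = False):
    """The six-breed genotype-count table for the two HIRA SNPs.

    Returns a list of ``(breed, locus, GenotypeCounts)`` tuples, or a
    DataFrame with the genotype-table columns when ``as_frame=True``.
    """
    if as_frame:
        return pd.DataFrame(
            HIRA_GENOTYPE_COUNTS, columns=["breed", "locus", "n_AA", "n_Aa", "n_aa"]
        )
    return [
        (breed, locus, GenotypeCounts(a, b, c))
        for breed, locus, a, b, c in HIRA_GENOTYPE_COUNTS
    ]
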