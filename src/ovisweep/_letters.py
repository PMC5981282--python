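"""Compact letter displays by the insert-and-absorb algorithm.

Given a set of levels, their means and the set of significantly different
pairs, produce per-level letter strings such that two levels share a letter
exactly when their difference is NOT significant.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping

__all__ = ["compact_letter_display"]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def compact_letter_display(
    levels: Iterable[Hashable],
    means: Mapping[Hashable, float],
    significant_pairs: Iterable[tuple[Hashable, Hashable]],
    uppercase: bool = False,
) -> dict[Hashable, str]:
    """Assign letters so shared letter <=> non-significant pair.

    Starts from one group holding every level; for each significant pair any
    group containing both is split in two (one without each member), then
    groups that became subsets of others are absorbed. Groups are lettered in
    order of their best (largest) mean, so 'a' marks the top group.
    """
    levels = list(levels)
    sig = {frozenset(p) for p in significant_pairs if p[0] != p[1]}
    columns: list[set] = [set(levels)]
    for pair in sig:
        i, j = tuple(pair)
        new_columns: list[set] = []
        for col in columns:
            if i in col and j in col:
                new_columns.append(col - {i})
                new_columns.append(col - {j})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = []
        for col in new_columns:
            if any(col < other for other in new_columns) or col in columns:
                continue
            columns.append(col)
    columns.sort(key=lambda col: -max(means[l] for l in col))
    alphabet = _ALPHABET.upper() if uppercase else _ALPHABET
    out = {l: "" for l in levels}
    for letter, col in zip(alphabet, columns):
        for l in col:
            out[l] += letter
    return {l: "".join(sorted(s)) for l, s in out.items()}
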