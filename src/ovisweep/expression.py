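"""Relative qPCR expression by the 2^-ddCt method and group comparison.

Each replicate's dCt = Ct(target) - Ct(reference gene) removes the loading
difference; ddCt = dCt - mean dCt of the calibrator cell expresses the
replicate relative to the calibrator, and 2^-ddCt converts to fold units
(assuming perfect doubling per cycle). Group differences per tissue are
tested with two-sided two-sample t-tests — on dCt by default, the scale on
which qPCR noise is closest to Gaussian — and summarized as significance
letters at two levels (lowercase 0.05, uppercase 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._letters import compact_letter_display
from .synthetic_data import CtRecord

__all__ = [
    "RelativeExpression",
    "TissueComparison",
    "relative_expression",
    "compare_expression",
    "group_fold_ratio",
]


@dataclass(frozen=True)
class RelativeExpression:
    tissue: str
    group: str
    replicate: int
    delta_ct: float
    ddct: float
    rel_expr: float


@dataclass(frozen=True)
class TissueComparison:
    """Per-tissue group letters at the two significance levels."""

    tissue: str
    letters_005: dict[str, str]
    letters_001: dict[str, str]
    p_values: dict[tuple[str, str], float]
    testable: bool = True


def relative_expression(
    records: Sequence[CtRecord],
    calibrator_group: str | None = None,
    calibrator: tuple[str, str] | None = None,
) -> list[RelativeExpression]:
    """2^-ddCt per replicate.

    The calibrator is either ``calibrator_group`` — each tissue is
    calibrated against that group's mean dCt *within the same tissue*, so
    per-tissue group contrasts do not depend on a global anchor — or an
    explicit global ``calibrator=(tissue, group)`` cell. Exactly one must be
    given; a calibrator cell with no records is fatal.
    """
    if (calibrator_group is None) == (calibrator is None):
        raise ValueError("give exactly one of calibrator_group or calibrator")
    dct = {id(r): r.ct_target - r.ct_reference for r in records}

    def cal_mean(tissue: str) -> float:
        if calibrator is not None:
            sel = [r for r in records if (r.tissue, r.group) == calibrator]
            label = f"{calibrator[0]}/{calibrator[1]}"
        else:
            sel = [r for r in records if r.tissue == tissue and r.group == calibrator_group]
            label = f"{tissue}/{calibrator_group}"
        if not sel:
            raise ValueError(f"calibrator cell {label} has no records")
        return float(np.mean([dct[id(r)] for r in sel]))

    out = []
    for r in records:
        base = cal_mean(r.tissue)
        ddct = dct[id(r)] - base
        out.append(
            RelativeExpression(
                tissue=r.tissue,
                group=r.group,
                replicate=r.replicate,
                delta_ct=dct[id(r)],
                ddct=ddct,
                rel_expr=float(2.0 ** (-ddct)),
            )
        )
    return out


def group_fold_ratio(rel: Sequence[RelativeExpression], tissue: str, group: str) -> float:
    """Geometric-mean fold of ``group`` in ``tissue`` (2^-mean ddCt)."""
    dd = [r.ddct for r in rel if r.tissue == tissue and r.group == group]
    if not dd:
        raise ValueError(f"no replicates for {tissue}/{group}")
    return float(2.0 ** (-np.mean(dd)))


def compare_expression(
    rel: Sequence[RelativeExpression],
    on: str = "delta_ct",
    alpha_levels: tuple[float, float] = (0.05, 0.01),
) -> list[TissueComparison]:
    """Pairwise group t-tests per tissue with two-level letter summaries.

    ``on`` selects the tested scale: "delta_ct" (default; equivalent to
    testing log2 expression) or "rel_expr". Tissues where any group has
    fewer than two replicates are returned flagged untestable.
    """
    if on not in ("delta_ct", "rel_expr"):
        raise ValueError("on must be 'delta_ct' or 'rel_expr'")
    df = pd.DataFrame(
        {
            "tissue": [r.tissue for r in rel],
            "group": [r.group for r in rel],
            "value": [getattr(r, on) for r in rel],
            "fold": [r.rel_expr for r in rel],
        }
    )
    out = []
    for tissue, sub in df.groupby("tissue", sort=False):
        groups = list(dict.fromkeys(sub["group"]))
        values = {g: sub.loc[sub["group"] == g, "value"].to_numpy() for g in groups}
        if len(groups) < 2 or min(len(v) for v in values.values()) < 2:
            out.append(
                TissueComparison(
                    tissue=tissue, letters_005={}, letters_001={}, p_values={}, testable=False
                )
            )
            continue
        # order letters by mean fold so 'a'/'A' marks the most expressed group
        fold_means = {g: float(sub.loc[sub["group"] == g, "fold"].mean()) for g in groups}
        pvals = {}
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1 :]:
                t_res = stats.ttest_ind(values[g1], values[g2], equal_var=True)
                pvals[(g1, g2)] = float(t_res.pvalue)
        letters = {}
        for alpha, upper in zip(alpha_levels, (False, True)):
            sig = [pair for pair, p in pvals.items() if p < alpha]
            letters[alpha] = compact_letter_display(groups, fold_means, sig, uppercase=upper)
        out.append(
            TissueComparison(
                tissue=tissue,
                letters_005=letters[alpha_levels[0]],
                letters_001=letters[alpha_levels[1]],
                p_values=pvals,
                testable=True,
            )
        )
    return out
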