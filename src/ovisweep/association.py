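"""Litter-size association: the two-way fixed-effects model and its tables.

The model is y_ijn = mu + P_i + G_j + (PG)_ij + e_ijn with parity i and
marker genotype j as fixed factors and an i.i.d. Gaussian residual. It is
fitted by ordinary least squares under the saturated cell-means
parameterization (one coefficient per non-empty parity-by-genotype cell,
equivalent to the interaction model with estimable contrasts). Downstream
tables report least-squares means with standard errors from the pooled
residual mean square, and pairwise genotype comparisons by the least
significant difference (LSD) test at alpha = 0.05 with no multiplicity
adjustment, summarized as superscript letters.

Records from the same ewe at different parities are treated as independent
observations; the model carries no ewe random effect (a documented
limitation of this model class).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._letters import compact_letter_display
from .synthetic_data import PhenotypeRecord

__all__ = [
    "ModelFit",
    "LSMean",
    "LSMeanTable",
    "fit_model",
    "ls_means",
    "lsd_letters",
    "association_table",
]


@dataclass(frozen=True)
class ModelFit:
    """OLS fit of the saturated parity-by-genotype cell-means model."""

    cells: tuple[tuple[int, int], ...]  # (parity, genotype), non-empty only
    coef: tuple[float, ...]  # cell means, aligned with ``cells``
    cell_n: dict[tuple[int, int], int]
    mse: float
    df_resid: int
    sse: float
    parities: tuple[int, ...]
    genotypes: tuple[int, ...]

    def cell_mean(self, parity: int, genotype: int) -> float:
        return self.coef[self.cells.index((parity, genotype))]


@dataclass(frozen=True)
class LSMean:
    """One least-squares mean: a cell (parity, genotype) or a genotype average.

    ``var_coef`` is the factor c such that Var(estimate) = MSE * c; it feeds
    the LSD pairwise tests. ``parity`` is None for genotype averages.
    """

    parity: int | None
    genotype: int
    estimate: float
    se: float
    n: int
    var_coef: float
    letter: str = ""
    incomplete: bool = False


@dataclass(frozen=True)
class LSMeanTable:
    scope: str  # "per_parity" or "genotype_average"
    rows: tuple[LSMean, ...]
    alpha: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parity": r.parity,
                    "genotype": r.genotype,
                    "ls_mean": r.estimate,
                    "se": r.se,
                    "n": r.n,
                    "letters": r.letter,
                }
                for r in self.rows
            ]
        )


def fit_model(records: Sequence[PhenotypeRecord]) -> ModelFit:
    """Fit the interaction model by OLS on the cell-means design.

    Empty cells are allowed (recorded by their absence from ``cells``);
    residual df = N - (#non-empty cells) and must be positive.
    """
    if not records:
        raise ValueError("no records")
    cells = sorted({(r.parity, r.genotype) for r in records})
    if len(cells) < 2:
        raise ValueError("need at least two non-empty cells")
    idx = {c: k for k, c in enumerate(cells)}
    y = np.array([r.litter_size for r in records], dtype=float)
    x = np.zeros((len(records), len(cells)))
    for i, r in enumerate(records):
        x[i, idx[(r.parity, r.genotype)]] = 1.0
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sse = float(resid @ resid)
    df = len(records) - len(cells)
    if df <= 0:
        raise ValueError("zero residual degrees of freedom; cannot estimate MSE")
    cell_n = {c: 0 for c in cells}
    for r in records:
        cell_n[(r.parity, r.genotype)] += 1
    return ModelFit(
        cells=tuple(cells),
        coef=tuple(float(b) for b in beta),
        cell_n=cell_n,
        mse=sse / df,
        df_resid=df,
        sse=sse,
        parities=tuple(sorted({p for p, _ in cells})),
        genotypes=tuple(sorted({g for _, g in cells})),
    )


def ls_means(fit: ModelFit, scope: str = "per_parity") -> LSMeanTable:
    """Least-squares means per (parity, genotype) cell or per genotype average.

    Per-parity LS means are the cell means with SE = sqrt(MSE / n_ij). The
    genotype average weights the genotype's parity cells equally:
    estimate = mean of cell means, SE = sqrt(MSE * sum(1/n_ij)) / k over the
    k non-empty parity cells (flagged incomplete when k is short of the full
    parity set). ``n`` reports the total records behind the estimate.
    """
    rows: list[LSMean] = []
    if scope == "per_parity":
        for parity, genotype in fit.cells:
            n = fit.cell_n[(parity, genotype)]
            c = 1.0 / n
            rows.append(
                LSMean(
                    parity=parity,
                    genotype=genotype,
                    estimate=fit.cell_mean(parity, genotype),
                    se=float(np.sqrt(fit.mse * c)),
                    n=n,
                    var_coef=c,
                )
            )
    elif scope == "genotype_average":
        import warnings

        for genotype in fit.genotypes:
            present = [p for p in fit.parities if (p, genotype) in fit.cell_n]
            k = len(present)
            est = float(np.mean([fit.cell_mean(p, genotype) for p in present]))
            c = float(sum(1.0 / fit.cell_n[(p, genotype)] for p in present)) / k**2
            incomplete = k < len(fit.parities)
            if incomplete:
                warnings.warn(
                    f"genotype {genotype}: average over {k} of {len(fit.parities)} parities "
                    "(empty cells excluded)",
                    stacklevel=2,
                )
            rows.append(
                LSMean(
                    parity=None,
                    genotype=genotype,
                    estimate=est,
                    se=float(np.sqrt(fit.mse * c)),
                    n=sum(fit.cell_n[(p, genotype)] for p in present),
                    var_coef=c,
                    incomplete=incomplete,
                )
            )
    else:
        raise ValueError("scope must be 'per_parity' or 'genotype_average'")
    return LSMeanTable(scope=scope, rows=tuple(rows))


def _pairwise_p(a: LSMean, b: LSMean, fit: ModelFit) -> float:
    se_diff = np.sqrt(fit.mse * (a.var_coef + b.var_coef))
    t = (a.estimate - b.estimate) / se_diff
    return float(2.0 * stats.t.sf(abs(t), fit.df_resid))


def lsd_letters(table: LSMeanTable, fit: ModelFit, alpha: float = 0.05) -> LSMeanTable:
    """Attach LSD significance letters to an LS-mean table.

    Genotypes are compared within each parity (or within the average column)
    by t-tests on the LS-mean differences against the residual-df t
    distribution, unadjusted for multiplicity. Two genotypes share a letter
    exactly when their difference is not significant at ``alpha``; 'a' marks
    the group containing the largest mean.
    """
    families: dict[int | None, list[LSMean]] = {}
    for row in table.rows:
        families.setdefault(row.parity, []).append(row)
    new_rows = []
    for rows in families.values():
        if len(rows) < 2:
            new_rows.extend(rows)
            continue
        means = {r.genotype: r.estimate for r in rows}
        sig = [
            (a.genotype, b.genotype)
            for i, a in enumerate(rows)
            for b in rows[i + 1 :]
            if _pairwise_p(a, b, fit) < alpha
        ]
        letters = compact_letter_display(means, means, sig)
        new_rows.extend(replace(r, letter=letters[r.genotype]) for r in rows)
    new_rows.sort(key=lambda r: (r.parity is None, r.parity or 0, r.genotype))
    return LSMeanTable(scope=table.scope, rows=tuple(new_rows), alpha=alpha)


def association_table(
    records: Sequence[PhenotypeRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """One-call litter-size table: per-parity and average LS means with letters.

    Rows are genotypes; columns hold, for each parity and for the equally
    weighted three-parity average, the LS mean, its SE, the record count and
    the LSD letter group.
    """
    fit = fit_model(records)
    frames = []
    for scope in ("per_parity", "genotype_average"):
        tab = lsd_letters(ls_means(fit, scope), fit, alpha=alpha)
        df = tab.to_frame()
        df["column"] = df["parity"].map(
            lambda p: "average" if pd.isna(p) else f"parity_{int(p)}"
        )
        frames.append(df.drop(columns="parity"))
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot_table(
        index="genotype",
        columns="column",
        values=["ls_mean", "se", "n", "letters"],
        aggfunc="first",
    )
    wide.columns = [f"{col}_{stat}" for stat, col in wide.columns]
    return wide.sort_index(axis=1)
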