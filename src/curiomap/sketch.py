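"""Sketch-map scoring: composites, inter-rater reliability, internal consistency.

Each sketch map (one participant x room) is scored by two raters on four
dimensions — Object Presence (OP), Spatial Distortion and Rotation of
features (SD), Relative Positioning (RP), Spatial Proportion (SP) — on a
1-to-5 scale in 0.5 steps.  The composite precision score averages the two
raters within each dimension and then the four dimension means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DIMENSIONS = ["OP", "SD", "RP", "SP"]

__all__ = [
    "DIMENSIONS",
    "composite",
    "composite_table",
    "inter_rater_reliability",
    "ReliabilityResult",
    "cronbach_alpha",
    "AlphaResult",
]


def composite(scores: pd.DataFrame) -> float:
    """Composite score of one participant x room from its two rater rows.

    ``scores`` holds exactly two rows (one per rater) with the four dimension
    columns; the result is the mean over dimensions of the rater means, which
    is invariant to rater and dimension order.
    """
    if len(scores) != 2:
        raise ValueError(f"expected exactly two rater rows, got {len(scores)}")
    missing = [d for d in DIMENSIONS if d not in scores.columns or scores[d].isna().any()]
    if missing:
        raise ValueError(f"missing dimension scores: {missing}")
    dim_means = scores[DIMENSIONS].mean(axis=0)
    return float(dim_means.mean())


def composite_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per participant x room composites from a long two-rater score table."""
    rows = []
    for (pid, rid), grp in scores.groupby(["participant_id", "room_id"], sort=True):
        rows.append(
            {"participant_id": pid, "room_id": rid, "composite": composite(grp)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReliabilityResult:
    """Agreement between the two raters on one dimension."""

    dimension: str
    pearson: float
    icc: float  # two-way mixed, consistency, single rater (ICC3)
    n_units: int


def inter_rater_reliability(scores: pd.DataFrame, dimension: str) -> ReliabilityResult:
    """Two-rater reliability of one dimension across participant x room units.

    Returns both the Pearson correlation of the two raters' scores and the
    two-way consistency intraclass coefficient (single rater); the intraclass
    form is the default to report.  Requires >= 3 units scored by both raters
    and nonzero variance in each rater's scores.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    wide = scores.pivot_table(
        index=["participant_id", "room_id"], columns="rater_id", values=dimension
    ).dropna()
    if wide.shape[1] != 2:
        raise ValueError(f"expected exactly two raters, found {wide.shape[1]}")
    if len(wide) < 3:
        raise ValueError("need at least 3 participant x room units scored by both raters")
    a, b = wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy()
    if np.isclose(a.var(), 0) or np.isclose(b.var(), 0):
        raise ValueError("zero variance in a rater's scores; reliability undefined")
    pearson = float(stats.pearsonr(a, b).statistic)

    import pingouin as pg

    long = wide.reset_index()
    long["unit"] = np.arange(len(long))
    long = long.melt(id_vars="unit", value_vars=list(wide.columns),
                     var_name="rater", value_name="score")
    icc_tab = pg.intraclass_corr(long, targets="unit", raters="rater", ratings="score")
    # two-way consistency, single rater; label differs across pingouin versions
    mask = icc_tab["Type"].isin(["ICC3", "ICC(C,1)"])
    icc3 = float(icc_tab.loc[mask, "ICC"].iloc[0])
    return ReliabilityResult(dimension, pearson, icc3, len(wide))


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    ci_low: float
    ci_high: float
    level: float
    n_units: int


def cronbach_alpha(
    matrix: np.ndarray | pd.DataFrame,
    *,
    level: float = 0.93,
    n_boot: int = 2000,
    seed: int | None = None,
) -> AlphaResult:
    """Cronbach's alpha of a units x items matrix with a bootstrap interval.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance of row totals)``
    with sample variances (ddof=1).  The uncertainty interval is a
    nonparametric bootstrap over units at the given level (percentile form).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need a units x items matrix with >= 3 units and >= 2 items")

    def _alpha(m: np.ndarray) -> float:
        k = m.shape[1]
        total_var = m.sum(axis=1).var(ddof=1)
        if np.isclose(total_var, 0):
            raise ValueError("zero total variance; alpha undefined")
        item_var = m.var(axis=0, ddof=1).sum()
        return k / (k - 1) * (1.0 - item_var / total_var)

    point = _alpha(X)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        m = X[idx]
        if np.isclose(m.sum(axis=1).var(ddof=1), 0):
            boots[i] = np.nan
            continue
        boots[i] = _alpha(m)
    boots = boots[~np.isnan(boots)]
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [tail, 1.0 - tail])
    return AlphaResult(float(point), float(lo), float(hi), level, n)
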