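"""Evaluation statistics for genomic predictions.

Reliability is the squared Pearson correlation between predictions and true
breeding values; unbiasedness is the OLS regression of TBV on (G)EBV.
Because EBV response variables are regressed toward the mean, GEBVs trained
on them are deflated roughly in proportion to the mean EBV reliability, so
a rescaled slope ``b_c = b * rbar2`` (equivalently, regressing on
GEBV / rbar2) is also reported.  Differences between two dependent
validation correlations that share the TBV are tested with Williams'
modified t (the Hotelling-Williams test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class StatisticError(ValueError):
    pass


def _check_pair(a, b, min_n=3):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatisticError("inputs must be equal-length vectors")
    if a.size < min_n:
        raise StatisticError(f"need at least {min_n} pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise StatisticError("constant input vector; statistic undefined")
    return a, b


def reliability(estimates, truths) -> float:
    """Squared Pearson correlation between predictions and truths."""
    a, b = _check_pair(estimates, truths)
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def regression_tbv_on_gebv(truths, estimates) -> tuple[float, float]:
    """OLS of TBV (response) on GEBV (predictor): (intercept, slope).

    A slope of 1 means unbiased predictions; slopes above 1 indicate
    deflated (over-shrunk) predictions.
    """
    y, x = _check_pair(truths, estimates)
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope)


def rescale_gebv(gebv, mean_reliability: float) -> np.ndarray:
    """Put GEBVs back on the TBV scale by dividing by the mean reliability
    of the EBV response variables; the regression slope transforms as
    ``b_c = b * mean_reliability``."""
    if mean_reliability <= 0:
        raise StatisticError("mean reliability must be positive")
    return np.asarray(gebv, dtype=float) / mean_reliability


def hotelling_williams_t(
    r_1t: float, r_2t: float, r_12: float, n: int
) -> tuple[float, int]:
    """Williams' t for the difference of two correlations sharing variable T.

    Here r_1t and r_2t are the validation correlations of two competing
    predictors with the TBV, and r_12 the correlation between the
    predictors.  Returns (t, df) with df = n - 3.
    """
    for r in (r_1t, r_2t, r_12):
        if not -1.0 <= r <= 1.0:
            raise StatisticError("correlations must lie in [-1, 1]")
    n = int(n)
    if n < 4:
        raise StatisticError("need n >= 4")
    det = 1.0 - r_1t**2 - r_2t**2 - r_12**2 + 2.0 * r_1t * r_2t * r_12
    if det < -1e-10:
        raise StatisticError("inconsistent (non-PSD) correlation triple")
    det = max(det, 0.0)
    rbar = 0.5 * (r_1t + r_2t)
    denom = 2.0 * ((n - 1) / (n - 3)) * det + rbar**2 * (1.0 - r_12) ** 3
    if denom <= 0:
        raise StatisticError("degenerate correlation configuration")
    t = (r_1t - r_2t) * math.sqrt((n - 1) * (1.0 + r_12) / denom)
    return float(t), n - 3


def williams_p_value(t: float, df: int) -> float:
    """Two-sided p from Student's t with df = n - 3."""
    return float(2.0 * stats.t.sf(abs(t), df))


def significance_mark(p: float) -> str:
    return "**" if p < 0.01 else ""


CELL_KEYS = ["table", "trait", "scenario", "model", "response", "statistic"]


@dataclass
class EvaluationReport:
    """Long-format table of evaluation cells.

    ``cells`` has the key columns (table, trait, scenario, model, response,
    statistic) plus either ``value`` (single replicate) or
    ``mean``/``sd``/``n_replicates`` (aggregated).
    """

    cells: pd.DataFrame

    @property
    def aggregated(self) -> bool:
        return "mean" in self.cells.columns

    def lookup(self, **keys) -> pd.DataFrame:
        df = self.cells
        for k, v in keys.items():
            df = df[df[k] == v]
        return df

    def value(self, **keys) -> float:
        df = self.lookup(**keys)
        if len(df) != 1:
            raise KeyError(f"{keys} matched {len(df)} cells")
        col = "mean" if self.aggregated else "value"
        return float(df[col].iloc[0])

    def to_tables(self) -> dict[str, pd.DataFrame]:
        """Pivot into the four wide report tables (one per table label)."""
        out = {}
        val = "mean" if self.aggregated else "value"
        for name, df in self.cells.groupby("table"):
            cols = ["model", "response", "statistic"]
            wide = df.pivot_table(
                index=["trait", "scenario"], columns=cols, values=val
            )
            if self.aggregated:
                sd = df.pivot_table(
                    index=["trait", "scenario"], columns=cols, values="sd"
                )
                sd.columns = pd.MultiIndex.from_tuples(
                    [(*c[:-1], c[-1] + "_sd") for c in sd.columns]
                )
                wide = pd.concat([wide, sd], axis=1).sort_index(axis=1)
            out[name] = wide
        return out


def aggregate_replicates(reports: list[EvaluationReport]) -> EvaluationReport:
    """Per-cell mean and sample SD (n-1 denominator) over replicates.

    A single replicate yields SD 0 and ``n_replicates`` 1 so the flag is
    visible downstream.  All replicates must share the same cell structure.
    """
    if len(reports) < 1:
        raise StatisticError("need at least one replicate")
    frames = []
    ref_keys = None
    for i, rep in enumerate(reports):
        df = rep.cells if isinstance(rep, EvaluationReport) else rep
        keys = df[CELL_KEYS].sort_values(CELL_KEYS).reset_index(drop=True)
        if ref_keys is None:
            ref_keys = keys
        elif not keys.equals(ref_keys):
            raise StatisticError(f"replicate {i} has a different cell structure")
        frames.append(df.assign(replicate=i))
    allcells = pd.concat(frames, ignore_index=True)
    grp = allcells.groupby(CELL_KEYS, dropna=False, sort=True)["value"]
    agg = grp.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_replicates="count")
    agg["sd"] = agg["sd"].fillna(0.0)
    return EvaluationReport(cells=agg.reset_index())
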