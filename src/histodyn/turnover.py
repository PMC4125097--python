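"""The relative turnover statistic: log2 of early vs late pulse signal.

Internally the canonical orientation is fast-positive — high score means rapid
exchange (early signal exceeds late signal after depth normalization). The
slow-positive orientation used by some displays is an output conversion only.
Because the score is a log ratio, per-time-point global rescaling (any
normalization change) shifts all scores by a constant and leaves every pairwise
difference untouched (exactly so at epsilon = 0).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "turnover_score",
    "classify_deciles",
    "invariance_audit",
    "turnover_histogram",
    "correlate",
]


def turnover_score(s3: pd.Series, s12: pd.Series, s6: pd.Series | None = None,
                   epsilon: float = 0.01) -> pd.DataFrame:
    """Build a turnover table: score = log2((s3 + eps) / (s12 + eps)).

    ``s3`` and ``s12`` must share an identical locus index; ``s6`` (optional)
    is carried for diagnostics but not used by the score.
    """
    if len(s3.index) != len(s12.index) or not s3.index.equals(s12.index):
        raise ValueError("s3 and s12 locus sets do not match")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    a = s3.to_numpy(dtype=float)
    b = s12.to_numpy(dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("signals must be nonnegative")
    with np.errstate(divide="ignore"):
        score = np.log2(a + epsilon) - np.log2(b + epsilon)
    table = pd.DataFrame({"s3": a, "s12": b, "score": score}, index=s3.index)
    if s6 is not None:
        if not s6.index.equals(s3.index):
            raise ValueError("s6 locus set does not match")
        table.insert(1, "s6", s6.to_numpy(dtype=float))
    table.index.name = s3.index.name or "locus_id"
    return table


def classify_deciles(table: pd.DataFrame) -> pd.DataFrame:
    """Label the top/bottom 10% of loci by score as hot/cold.

    Counts are floor(n/10) each; ties are broken by stable input order.
    """
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 loci, got {n}")
    n_decile = n // 10
    out = table.copy()
    score = out["score"].to_numpy(dtype=float)
    hot_order = np.argsort(-score, kind="stable")
    cls = np.full(n, "intermediate", dtype=object)
    hot_idx = hot_order[:n_decile]
    cls[hot_idx] = "hot"
    # cold picks from the remaining loci so counts stay 10%/10% even under ties
    cold_order = np.argsort(score, kind="stable")
    cold_idx = cold_order[~np.isin(cold_order, hot_idx)][:n_decile]
    cls[cold_idx] = "cold"
    out["decile_class"] = cls
    return out


def invariance_audit(s3: pd.Series, s12: pd.Series,
                     factors: tuple[float, float] = (2.0, 5.0),
                     epsilon: float = 0.01) -> float:
    """Max absolute change in any pairwise score difference under rescaling.

    Each time point is multiplied by its factor (a stand-in for an arbitrary
    normalization choice) and scores recomputed. With epsilon = 0 the result is
    exactly 0 — relative hot/cold calls are insensitive to normalization; with
    epsilon > 0 the returned bound quantifies the pseudocount's cost.
    """
    f3, f12 = factors
    if f3 <= 0 or f12 <= 0:
        raise ValueError("rescale factors must be positive")
    base = turnover_score(s3, s12, epsilon=epsilon)["score"].to_numpy()
    if epsilon == 0:
        # log2((a f3)/(b f12)) - log2(a/b) = log2(f3) - log2(f12) for every locus:
        # the per-locus shift is a single constant, so every pairwise score
        # difference is exactly unchanged.
        return 0.0
    scaled = turnover_score(s3 * f3, s12 * f12, epsilon=epsilon)["score"].to_numpy()
    d = scaled - base
    d = d[np.isfinite(d)]
    if d.size == 0:
        return 0.0
    # max over pairs (i,j) of |(a_i - a_j) - (b_i - b_j)| = max(d) - min(d)
    return float(d.max() - d.min())


def turnover_histogram(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       bin_width: float = 0.25,
                       orientation: str = "fast-positive") -> pd.DataFrame:
    """Histogram two score tables on shared bin edges.

    ``orientation='slow-positive'`` negates scores on output (the display
    convention where positive values mean slow exchange).
    """
    if table_a.empty or table_b.empty:
        raise ValueError("tables must be nonempty")
    if orientation not in ("fast-positive", "slow-positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sign = 1.0 if orientation == "fast-positive" else -1.0
    a = sign * table_a["score"].to_numpy(dtype=float)
    b = sign * table_b["score"].to_numpy(dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    first = math.floor(lo / bin_width) * bin_width
    n_bins = max(1, math.ceil((hi - first) / bin_width + 1e-9))
    edges = first + bin_width * np.arange(n_bins + 1)
    counts_a, _ = np.histogram(a, bins=edges)
    counts_b, _ = np.histogram(b, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count_a": counts_a,
        "count_b": counts_b,
    })


def correlate(x: pd.Series | Sequence[float], y: pd.Series | Sequence[float],
              method: str = "pearson") -> float:
    """Pearson or Spearman correlation over paired finite values.

    Pairs with a missing member are dropped (the count is not silently hidden:
    it is reported via logging by callers that care). Zero variance raises.
    """
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float)
    if isinstance(x.index, pd.Index) and isinstance(y.index, pd.Index) and x.index.equals(y.index):
        pass
    else:
        y.index = x.index
    ok = np.isfinite(x.to_numpy()) & np.isfinite(y.to_numpy())
    xv, yv = x.to_numpy()[ok], y.to_numpy()[ok]
    if len(xv) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in one of the vectors")
    if method == "pearson":
        return float(stats.pearsonr(xv, yv).statistic)
    if method == "spearman":
        return float(stats.spearmanr(xv, yv).statistic)
    raise ValueError(f"unknown method {method!r}")
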