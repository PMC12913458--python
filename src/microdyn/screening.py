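"""Between-group feature screening: Mann-Whitney U, Cohen's d, Cliff's delta.

All tests are two-sided.  The sign convention throughout is group A minus
group B with A as the case (e.g. ASD) group: positive d or delta means the
feature runs higher in the cases.  No multiple-testing correction is
applied by default (a Benjamini-Hochberg column is available on request);
the conventional effect-size cutoffs are attached as annotations only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._types import ConfigError

__all__ = ["mann_whitney_u", "cohens_d", "cliffs_delta", "feature_screen",
           "FeatureScreenResult"]

logger = logging.getLogger(__name__)

# interpretive cutoffs (reporting annotations only)
D_CUTOFFS = (0.2, 0.5, 0.8)
DELTA_CUTOFFS = (0.147, 0.33, 0.474)


def _magnitude(value: float, cutoffs: tuple[float, float, float]) -> str:
    v = abs(value)
    if np.isnan(v):
        return "undefined"
    small, medium, large = cutoffs
    if v < small:
        return "negligible"
    if v < medium:
        return "small"
    if v < large:
        return "medium"
    return "large"


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (min(U1, U2), p).

    Mid-ranks handle ties.  The p-value uses exact enumeration when
    n1*n2 <= 400 and the data are tie-free, otherwise the normal
    approximation with tie correction.  Two identical single-valued samples
    give U = n1*n2/2 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return n1 * n2 / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    return u, float(res.pvalue)


def cohens_d(x, y) -> float:
    """Standardized mean difference (x minus y) with pooled variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ConfigError("Cohen's d needs at least 2 observations per group")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        logger.warning("zero pooled variance: Cohen's d undefined (NaN)")
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def cliffs_delta(x, y) -> float:
    """Dominance effect size: P(x > y) - P(x < y) over all pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / diff.size)


@dataclass
class FeatureScreenResult:
    feature: str
    u_statistic: float
    p_value: float
    cohens_d: float
    cliffs_delta: float
    median_case: float
    median_control: float
    n_case: int
    n_control: int
    d_magnitude: str = ""
    delta_magnitude: str = ""


def feature_screen(table: pd.DataFrame, groups, case_group=None,
                   bh_correction: bool = False) -> pd.DataFrame:
    """Screen every feature column between two groups.

    ``groups`` aligns with the rows of ``table``; ``case_group`` names the
    positive/case level (default: the first level in sorted order is the
    control, so with labels {"A", "B"}, pass ``case_group="B"`` for a
    B-minus-A sign convention — the default takes the *first* distinct
    label as the case).  NaN feature values are dropped pairwise, with a
    logged count.  Returns one row per feature, sortable by any statistic.
    """
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups.tolist()))
    if len(levels) != 2:
        raise ConfigError(f"need exactly 2 groups, got {levels}")
    case = levels[0] if case_group is None else case_group
    control = [g for g in levels if g != case][0]
    rows = []
    for name in table.columns:
        col = np.asarray(table[name], dtype=float)
        x = col[groups == case]
        y = col[groups == control]
        nan_x, nan_y = np.isnan(x), np.isnan(y)
        if nan_x.any() or nan_y.any():
            logger.info("feature %s: dropping %d NaN values", name,
                        nan_x.sum() + nan_y.sum())
            x, y = x[~nan_x], y[~nan_y]
        if x.size < 2 or y.size < 2:
            raise ConfigError(
                f"feature {name}: a group has fewer than 2 observations"
            )
        u, p = mann_whitney_u(x, y)
        d = cohens_d(x, y)
        delta = cliffs_delta(x, y)
        rows.append(FeatureScreenResult(
            feature=name, u_statistic=u, p_value=p, cohens_d=d,
            cliffs_delta=delta, median_case=float(np.median(x)),
            median_control=float(np.median(y)), n_case=x.size,
            n_control=y.size, d_magnitude=_magnitude(d, D_CUTOFFS),
            delta_magnitude=_magnitude(delta, DELTA_CUTOFFS),
        ))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("feature")
    if bh_correction:
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(ranked)
        q[order] = np.clip(ranked, 0, 1)
        out["q_value"] = q
    return out
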