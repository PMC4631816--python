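"""Small statistical helpers shared by the evoked and source modules."""

from __future__ import annotations

import numpy as np
from scipy import stats


def one_way_anova(*groups: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One-way fixed-effects ANOVA F and p, vectorized along ``axis``.

    Thin wrapper over :func:`scipy.stats.f_oneway` that maps the degenerate
    all-groups-identical case (zero between- and within-group variance,
    where scipy returns NaN) to F = 0, p = 1: no evidence of a group
    difference rather than an undefined statistic.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*groups, axis=axis)
    f = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    grand = np.concatenate([np.asarray(g, dtype=float) for g in groups], axis=axis)
    flat = np.all(grand == np.take(grand, [0], axis=axis), axis=axis)
    bad = ~np.isfinite(f)
    f = np.where(bad & flat, 0.0, f)
    p = np.where(bad & flat, 1.0, p)
    if f.ndim == 0:
        return float(f), float(p)
    return f, p
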