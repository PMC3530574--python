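"""Multiple-testing control: Bonferroni and Benjamini-Hochberg step-up.

Both are written out explicitly because their exact arithmetic is part of
the analysis contract: Bonferroni is ``p_corr = min(1, p * m)`` and the
step-up FDR is ``p_corr(i) = (m / i) * p(i)`` over ascending ranks ``i``,
followed by a monotonicity pass that replaces any value with the smallest
adjusted value among higher ranks. ``m`` is the number of tests retained
after group-size filtering, and is recorded alongside every corrected
table.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "bonferroni_adjust",
    "bonferroni_threshold",
    "bh_adjust",
    "add_corrections",
]


def _check_p(p: np.ndarray) -> None:
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")


def bonferroni_adjust(p, m: int):
    """Family-wise adjusted p-value ``min(1, p * m)``."""
    if m < 1:
        raise ValueError("m must be at least 1")
    p = np.asarray(p, float)
    _check_p(p)
    out = np.minimum(p * m, 1.0)
    return out.item() if out.ndim == 0 else out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test cutoff ``alpha / m`` controlling the FWER at ``alpha``."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Ties receive identical adjusted values (the running-minimum pass from
    the largest rank downward guarantees it); the result is invariant to
    permutation of the input.
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    _check_p(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    raw = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def add_corrections(records: pd.DataFrame, m: int | None = None) -> pd.DataFrame:
    """Append ``p_bonf`` and ``p_fdr`` columns to an association table.

    ``m`` defaults to the number of rows with a defined p-value (the
    post-filter test count); it is stored in ``records.attrs["m"]``.
    Degenerate rows (NaN p) stay NaN in both corrected columns and do not
    count toward ``m`` unless an explicit ``m`` is given.
    """
    out = records.copy()
    finite = np.isfinite(out["p"].to_numpy(float))
    if m is None:
        m = int(finite.sum())
    if m < 1:
        out["p_bonf"] = np.nan
        out["p_fdr"] = np.nan
        out.attrs["m"] = 0
        return out
    p = out["p"].to_numpy(float)
    p_bonf = np.full(p.shape, np.nan)
    p_bonf[finite] = bonferroni_adjust(p[finite], m)
    p_fdr = np.full(p.shape, np.nan)
    # step-up over the finite subset, scaled by the declared m
    sub = p[finite]
    adj = bh_adjust(sub)
    if m != sub.size:
        adj = np.minimum(adj * m / sub.size, 1.0)
    p_fdr[finite] = adj
    out["p_bonf"] = p_bonf
    out["p_fdr"] = p_fdr
    out.attrs["m"] = m
    return out
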