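"""Supervised comparison against a designated reference method.

Every method is summarized by the bias ``beta`` (mean of method-minus-
reference differences over subjects), its standard deviation ``s`` (sample
SD, n-1) and the limits of agreement ``beta +- 1.96 s``, which contain about
95% of the differences under normality.  A second analysis correlates the
bias of each fused candidate with the sum of the biases of the methods it
was built from.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["bias_report", "within_limits", "combination_bias_correlation", "pick_reference"]


def bias_report(matrix: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Per-method bias/spread/limits with respect to ``reference``.

    Returns a DataFrame indexed by method with columns ``bias``, ``s``,
    ``lo``, ``hi`` (= bias -+ 1.96 s) and ``n``.  The reference compared to
    itself gives bias 0 and s 0.
    """
    matrix = pd.DataFrame(matrix)
    if reference not in matrix.columns:
        raise KeyError(f"reference method {reference!r} not in matrix")
    ref = matrix[reference]
    if ref.isna().any():
        raise ValueError("reference column must be complete")
    rows = {}
    for m in matrix.columns:
        d = (matrix[m] - ref).dropna()
        n = len(d)
        beta = float(d.mean()) if n else math.nan
        s = float(d.std(ddof=1)) if n >= 2 else (0.0 if m == reference else math.nan)
        if m == reference:
            beta, s = 0.0, 0.0
        rows[m] = {"bias": beta, "s": s, "lo": beta - 1.96 * s, "hi": beta + 1.96 * s, "n": n}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "method"
    return out


def within_limits(report: pd.DataFrame, method: str, envelope_method: str) -> bool:
    """True iff ``method``'s bias lies within the limits of agreement
    [beta - 1.96 s, beta + 1.96 s] computed for ``envelope_method``."""
    lo = report.loc[envelope_method, "lo"]
    hi = report.loc[envelope_method, "hi"]
    b = report.loc[method, "bias"]
    return bool(lo <= b <= hi)


def combination_bias_correlation(
    candidate_biases: np.ndarray, component_bias_sums: np.ndarray
) -> float:
    """Pearson r between fused-candidate biases and the summed biases of
    their component methods.  Returns NaN when either vector is constant."""
    x = np.asarray(candidate_biases, dtype=float)
    y = np.asarray(component_bias_sums, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two matched vectors of length >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def pick_reference(fom: pd.Series) -> str:
    """Optional heuristic: the method with the smallest figure of merit."""
    return str(pd.Series(fom).idxmin())
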