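"""Shared statistical primitives.

Conventions used throughout the package:

* missing data are removed pairwise (complete pairs / triples only) and the
  ``n`` actually used is reported on every result;
* ties receive midranks;
* all p-values are two-sided;
* z-scores use the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientDataError, ValidationError

__all__ = [
    "CorrelationResult",
    "RankSumResult",
    "correlate",
    "partial_correlate",
    "correlate_many",
    "bh_adjust",
    "rank_sum_test",
    "zscore",
]

_METHODS = ("pearson", "spearman")

# Relative residual-variance thresholds for near- vs exact collinearity of
# the control with x or y in a partial correlation.
_EXACT_COLLINEAR_TOL = 1e-24
_NEAR_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation estimate with its two-sided p-value.

    Attributes
    ----------
    estimate : float
        Correlation coefficient in [-1, 1].
    p_value : float
        Two-sided p-value from the t approximation.
    n : int
        Number of complete paired observations actually used (>= 3).
    method : str
        One of ``pearson``, ``spearman``, ``partial_pearson``,
        ``partial_spearman``.
    metadata : dict
        Free-form annotations (e.g. ``degenerate`` flag, convention notes).
    """

    estimate: float
    p_value: float
    n: int
    method: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (abs(self.estimate) <= 1 + 1e-12 or np.isnan(self.estimate)):
            raise ValidationError(f"estimate {self.estimate} outside [-1, 1]")
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U test result (U reported for the first sample)."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    metadata: dict = field(default_factory=dict)


def _as_float_array(v, name):
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size == 0:
        raise InsufficientDataError(f"{name} is empty")
    return arr


def _complete(*vectors):
    """Row mask keeping only positions finite in every vector."""
    mask = np.ones(vectors[0].shape[0], dtype=bool)
    for v in vectors:
        mask &= np.isfinite(v)
    return mask


def _check_variation(v, name):
    if np.min(v) == np.max(v):
        raise DegenerateInputError(f"{name} is constant after pairwise deletion")


def _t_pvalue(r, df):
    """Two-sided p for a correlation coefficient via the t approximation."""
    r = float(np.clip(r, -1.0, 1.0))
    if df <= 0:
        return float("nan")
    denom = 1.0 - r * r
    if denom <= 0.0:
        return 0.0
    t = r * np.sqrt(df / denom)
    return float(2.0 * sps.t.sf(abs(t), df))


def _pearson(x, y):
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise DegenerateInputError("zero variance in correlation input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlate(x, y, method="pearson"):
    """Correlate two vectors after pairwise deletion of missing entries.

    Pearson is the standard product-moment coefficient; Spearman is Pearson
    applied to midranks. The two-sided p-value comes from the t
    approximation with ``n - 2`` degrees of freedom.

    Raises
    ------
    DegenerateInputError
        If either vector is constant on the complete pairs.
    InsufficientDataError
        If fewer than 3 complete pairs remain.
    """
    if method not in _METHODS:
        raise ValidationError(f"unknown correlation method {method!r}")
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    if x.shape[0] != y.shape[0]:
        raise ValidationError("x and y must have equal length")
    mask = _complete(x, y)
    x, y = x[mask], y[mask]
    n = x.shape[0]
    if n < 3:
        raise InsufficientDataError(f"only {n} complete pairs (need >= 3)")
    _check_variation(x, "x")
    _check_variation(y, "y")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    r = _pearson(x, y)
    return CorrelationResult(r, _t_pvalue(r, n - 2), n, method)


def partial_correlate(x, y, control, method="pearson"):
    """Correlation of x and y with a single control variable removed.

    Residual definition: regress x on control (with intercept), regress y on
    control, then correlate the residuals. For the Spearman variant all
    three vectors are midrank-transformed first and the same residual
    definition is applied (convention recorded in ``metadata``). The p-value
    degrees of freedom are reduced by one for the control (df = n - 3).

    If the control is exactly collinear with x or y the residuals vanish and
    ``DegenerateInputError`` is raised; near-collinearity yields an estimate
    of 0.0 with ``metadata['degenerate'] = True`` rather than NaN.
    """
    if method not in _METHODS:
        raise ValidationError(f"unknown correlation method {method!r}")
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    c = _as_float_array(control, "control")
    if not (x.shape[0] == y.shape[0] == c.shape[0]):
        raise ValidationError("x, y, control must have equal length")
    mask = _complete(x, y, c)
    x, y, c = x[mask], y[mask], c[mask]
    n = x.shape[0]
    if n < 4:
        raise InsufficientDataError(f"only {n} complete triples (need >= 4)")
    _check_variation(x, "x")
    _check_variation(y, "y")
    if np.min(c) == np.max(c):
        raise DegenerateInputError("control is constant after pairwise deletion")
    if method == "spearman":
        x, y, c = sps.rankdata(x), sps.rankdata(y), sps.rankdata(c)

    cc = np.column_stack([np.ones(n), c])
    rx = x - cc @ np.linalg.lstsq(cc, x, rcond=None)[0]
    ry = y - cc @ np.linalg.lstsq(cc, y, rcond=None)[0]

    meta = {"convention": "residual", "df": n - 3}
    var_x = float(np.var(x))
    var_y = float(np.var(y))
    rel_x = float(np.var(rx)) / var_x if var_x > 0 else 0.0
    rel_y = float(np.var(ry)) / var_y if var_y > 0 else 0.0
    if rel_x <= _EXACT_COLLINEAR_TOL or rel_y <= _EXACT_COLLINEAR_TOL:
        raise DegenerateInputError("control is collinear with x or y")
    if rel_x <= _NEAR_COLLINEAR_TOL or rel_y <= _NEAR_COLLINEAR_TOL:
        meta["degenerate"] = True
        return CorrelationResult(0.0, 1.0, n, f"partial_{method}", meta)
    r = _pearson(rx, ry)
    return CorrelationResult(r, _t_pvalue(r, n - 3), n, f"partial_{method}", meta)


def correlate_many(matrix, y, method="pearson"):
    """Correlate every row of ``matrix`` with ``y`` (no missing values).

    Vectorized helper for genome-scale screens. Rows with zero variance are
    flagged invalid instead of raising.

    Parameters
    ----------
    matrix : (m, n) array
        One variable per row; must be fully observed.
    y : (n,) array
        Fully observed vector.

    Returns
    -------
    estimates, p_values : (m,) arrays
        NaN where a row is degenerate.
    valid : (m,) boolean array
    """
    matrix = np.asarray(matrix, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if matrix.ndim != 2 or matrix.shape[1] != y.shape[0]:
        raise ValidationError("matrix columns must match y length")
    if not (np.isfinite(matrix).all() and np.isfinite(y).all()):
        raise ValidationError("correlate_many requires fully observed input")
    n = y.shape[0]
    if n < 3:
        raise InsufficientDataError(f"only {n} observations (need >= 3)")
    if method == "spearman":
        matrix = sps.rankdata(matrix, axis=1)
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    yc = y - y.mean()
    y_norm = np.sqrt(yc @ yc)
    mc = matrix - matrix.mean(axis=1, keepdims=True)
    row_norm = np.sqrt(np.einsum("ij,ij->i", mc, mc))
    valid = (row_norm > 0) & (y_norm > 0)
    est = np.full(matrix.shape[0], np.nan)
    if y_norm > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            est = np.where(valid, np.clip((mc @ yc) / (row_norm * y_norm), -1, 1), np.nan)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = 1.0 - est * est
        t = np.where(denom > 0, np.abs(est) * np.sqrt(df / np.maximum(denom, 1e-300)), np.inf)
    pvals = np.where(np.isnan(est), np.nan, 2.0 * sps.t.sf(t, df))
    return est, pvals, valid


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted q-values.

    Missing entries are excluded from the family and returned missing.
    Output satisfies ``q >= p`` elementwise and ``max(q) <= 1``; the
    procedure is idempotent.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[finite] = adj
    return q


def rank_sum_test(a, b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Midranks for ties; normal approximation with tie-corrected variance and
    continuity correction (recorded in metadata). The statistic is U for
    sample ``a`` (number of (a_i > b_j) pairs plus half the ties).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return RankSumResult(
        float(res.statistic), float(res.pvalue), int(a.size), int(b.size),
        metadata={"approximation": "normal", "tie_corrected": True,
                  "continuity_correction": True},
    )


def zscore(v):
    """Standardize a vector: (v - mean) / sd with the sample (n-1) sd.

    NaNs are preserved in place; mean/sd use the observed entries only.
    """
    v = np.asarray(v, dtype=float).ravel()
    obs = v[np.isfinite(v)]
    if obs.size < 2:
        raise InsufficientDataError("need at least 2 observations to z-score")
    if np.min(obs) == np.max(obs):
        raise DegenerateInputError("cannot z-score a constant vector")
    return (v - obs.mean()) / obs.std(ddof=1)
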