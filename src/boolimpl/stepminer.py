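"""StepMiner: one-step fits to sorted expression and ternary discretization.

For each gene the values are sorted ascending and a rising step function is
fitted: samples ``1..k`` take the mean of the lowest ``k`` values, samples
``k+1..n`` the mean of the rest.  The step position minimizing the residual
sum of squares is selected (for a fixed model dimension this is the same
ordering as maximizing the F-statistic, which is reported as a diagnostic).
The gene's high/low threshold is the midpoint of the two fitted levels.

Discretization then assigns each sample a ternary state relative to the
threshold ``t`` with a noise margin (default 0.5, a two-fold change on the
log2 scale): LOW (< t - margin), HIGH (> t + margin), else INTERMEDIATE.
States are encoded as integers -1 / 0 / +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "StepFit",
    "fit_step",
    "threshold_matrix",
    "discretize",
    "StepMinerDiscretizer",
    "LOW",
    "INTERMEDIATE",
    "HIGH",
    "DEFAULT_MARGIN",
]

LOW, INTERMEDIATE, HIGH = -1, 0, 1
DEFAULT_MARGIN = 0.5
_TIE_TOL = 1e-12  # SSE ties resolved toward the smallest step index


@dataclass(frozen=True)
class StepFit:
    """A fitted one-step function for a single gene.

    ``step_index`` is the number of sorted samples on the low side (1-based
    position of the transition); ``m`` is the model dimension used in the
    F-statistic (two level means plus the step position).
    """

    step_index: int
    mu_low: float
    mu_high: float
    threshold: float
    f_stat: float
    sse: float
    m: int = 3
    degenerate: bool = False


def _sse_profile(sorted_values: np.ndarray) -> np.ndarray:
    """Residual SSE of the two-level fit for every step position k=1..n-1.

    Rows are independent series (2D input), columns the candidate k.
    Uses running sums; algebraically SSE(k) = SS_left(k) + SS_right(k).
    """
    x = np.atleast_2d(sorted_values)
    n = x.shape[1]
    cs = np.cumsum(x, axis=1)
    css = np.cumsum(x * x, axis=1)
    k = np.arange(1, n, dtype=float)
    left = css[:, :-1] - cs[:, :-1] ** 2 / k
    right = (css[:, -1:] - css[:, :-1]) - (cs[:, -1:] - cs[:, :-1]) ** 2 / (n - k)
    return left + right


def _pick_k(sse: np.ndarray) -> np.ndarray:
    """First (smallest) k whose SSE is within the tie tolerance of the min."""
    best = sse.min(axis=1, keepdims=True)
    return np.argmax(sse <= best + _TIE_TOL, axis=1) + 1


def fit_step(values, m: int = 3) -> StepFit:
    """Fit a rising one-step function to one gene's expression values.

    Values are sorted ascending internally.  Requires n >= 4 finite values.
    A constant vector has no step: it is returned with ``degenerate=True``,
    threshold equal to the constant, and F = 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise ValueError(f"need at least 4 values to fit a step, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    x = np.sort(x, kind="stable")
    n = x.size
    if x[0] == x[-1]:
        c = float(x[0])
        return StepFit(0, c, c, c, 0.0, 0.0, m, degenerate=True)
    sse = _sse_profile(x)[0]
    k = int(_pick_k(sse[None, :])[0])
    mu_low = float(x[:k].mean())
    mu_high = float(x[k:].mean())
    rss = float(sse[k - 1])
    rss = max(rss, 0.0)
    # between-levels SS: sum over i of (fitted_i - grand mean)^2
    grand = x.mean()
    between = k * (mu_low - grand) ** 2 + (n - k) * (mu_high - grand) ** 2
    if rss <= 0.0:
        f = np.inf
    else:
        f = (between / (m - 1)) / (rss / (n - m))
    return StepFit(k, mu_low, mu_high, (mu_low + mu_high) / 2.0, float(f), rss, m)


def _fit_matrix(values: np.ndarray):
    """Vectorized step fits for rows of a genes x samples array.

    Returns (thresholds, mu_low, mu_high, step_index, sse, degenerate).
    Constant rows get threshold = the constant and a degenerate flag.
    """
    x = np.sort(np.asarray(values, dtype=float), axis=1, kind="stable")
    n = x.shape[1]
    if n < 4:
        raise ValueError(f"need at least 4 samples to fit steps, got {n}")
    degenerate = x[:, 0] == x[:, -1]
    sse = _sse_profile(x)
    k = _pick_k(sse)
    cs = np.cumsum(x, axis=1)
    rows = np.arange(x.shape[0])
    low_sum = cs[rows, k - 1]
    mu_low = low_sum / k
    mu_high = (cs[:, -1] - low_sum) / (n - k)
    thresholds = (mu_low + mu_high) / 2.0
    rss = np.maximum(sse[rows, k - 1], 0.0)
    thresholds = np.where(degenerate, x[:, 0], thresholds)
    mu_low = np.where(degenerate, x[:, 0], mu_low)
    mu_high = np.where(degenerate, x[:, 0], mu_high)
    k = np.where(degenerate, 0, k)
    rss = np.where(degenerate, 0.0, rss)
    return thresholds, mu_low, mu_high, k, rss, degenerate


def threshold_matrix(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene StepMiner thresholds for a genes x samples matrix."""
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = matrix.index[np.argwhere(~np.isfinite(values))[0][0]]
        raise ValueError(f"non-finite values for gene {bad!r}")
    thresholds, *_ = _fit_matrix(values)
    return pd.Series(thresholds, index=matrix.index, name="threshold")


def discretize(
    matrix: pd.DataFrame,
    thresholds: pd.Series,
    margin: float = DEFAULT_MARGIN,
) -> pd.DataFrame:
    """Ternary-state matrix (-1 LOW / 0 INTERMEDIATE / +1 HIGH).

    ``thresholds`` must cover every gene in ``matrix``.
    """
    missing = matrix.index.difference(thresholds.index)
    if len(missing) > 0:
        raise ValueError(f"no threshold for gene(s): {list(missing)}")
    t = thresholds.loc[matrix.index].to_numpy(dtype=float)[:, None]
    x = matrix.to_numpy(dtype=float)
    states = np.zeros(x.shape, dtype=np.int8)
    states[x < t - margin] = LOW
    states[x > t + margin] = HIGH
    return pd.DataFrame(states, index=matrix.index, columns=matrix.columns)


class StepMinerDiscretizer(TransformerMixin, BaseEstimator):
    """Threshold-based ternary discretizer for expression profiles.

    Follows the scikit-learn convention: ``X`` is samples x features
    (features = genes).  ``fit`` learns a per-gene threshold from the
    one-step fit; ``transform`` maps values to {-1, 0, +1} states using
    the noise margin around each threshold.

    Parameters
    ----------
    margin : float, default 0.5
        Half-width of the intermediate zone around the threshold, on the
        same (log2) scale as the data; 0.5 corresponds to a two-fold change.

    Attributes
    ----------
    thresholds_ : ndarray of shape (n_features,)
    mu_low_, mu_high_ : ndarray of shape (n_features,)
        Fitted step levels per gene.
    degenerate_ : ndarray of bool
        Genes whose values are constant (no step exists).
    """

    def __init__(self, margin: float = DEFAULT_MARGIN):
        self.margin = margin

    def fit(self, X, y=None):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        X = check_array(X, dtype=float, ensure_min_samples=4)
        t, mu_lo, mu_hi, k, sse, degen = _fit_matrix(X.T)
        self.n_features_in_ = X.shape[1]
        self.thresholds_ = t
        self.mu_low_ = mu_lo
        self.mu_high_ = mu_hi
        self.step_index_ = k
        self.sse_ = sse
        self.degenerate_ = degen
        return self

    def transform(self, X):
        check_is_fitted(self, "thresholds_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        t = self.thresholds_[None, :]
        states = np.zeros(X.shape, dtype=np.int8)
        states[X < t - self.margin] = LOW
        states[X > t + self.margin] = HIGH
        return states
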