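"""Linear encoding model of the photometry signal.

Each behavioral variable contributes a block of time-lagged indicator
columns (or a single analog column) to a design matrix; ridge regression
of the signal on that matrix yields a time-averaged kernel per variable.
Explained variance is estimated by 10-fold cross-validation with
*contiguous* time blocks as folds — random folds leak slow drift between
train and test and flatter the model. Each variable's importance is
summarized two ways: the CV R² of a model containing only that variable
(single-variable R²) and the loss in full-model CV R² when the variable is
omitted (unique contribution, ΔR²). Both are normalized by the variable's
window size in samples and by the full-model CV R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from engage.types import AlignedMatrix

#: Default kernel windows (start_s, end_s) relative to each event.
DEFAULT_WINDOWS = {
    "trial_onset": (0.0, 2.0),
    "cue_onset": (0.0, 2.0),
    "lick_onset": (-0.5, 2.0),
    "run_onset": (-1.0, 3.0),
}

DEFAULT_LAMBDA_GRID = np.logspace(-2, 4, 7)


@dataclass
class DesignSpec:
    """One variable's regressor specification.

    ``kind="impulse"`` expands the event train into one lagged indicator
    column per sample of the window; ``kind="analog"`` inserts the supplied
    samples as a single unexpanded column.
    """

    name: str
    window: tuple[float, float] = (0.0, 2.0)
    kind: str = "impulse"

    def __post_init__(self) -> None:
        if self.kind == "impulse" and not self.window[1] > self.window[0]:
            raise ValueError("kernel window must have positive length")

    def n_columns(self, rate: float) -> int:
        if self.kind == "analog":
            return 1
        return int(round((self.window[1] - self.window[0]) * rate))


@dataclass
class KernelSet:
    """Fitted kernels and model metrics."""

    coefficients: dict = field(default_factory=dict)  # var -> array per lag
    lags_s: dict = field(default_factory=dict)
    lam: float = 0.0
    cvr2_full: float = np.nan
    r2_single: dict = field(default_factory=dict)
    delta_r2: dict = field(default_factory=dict)
    normalization: dict = field(default_factory=dict)


def build_design_matrix(events: dict, specs: list[DesignSpec], rate: float,
                        n_samples: int) -> tuple[np.ndarray, list]:
    """Time-expand event trains into a design matrix.

    ``events[name]`` is an array of event times (s) for impulse variables
    or an analog signal of length ``n_samples``. Returns (X, column_map)
    where ``column_map[j] = (variable, lag_s)`` inverts each column.
    Duplicate events at the same sample collapse into a single indicator
    count with a warning; variables with no events contribute no columns
    and are flagged with a warning.
    """
    cols, colmap = [], []
    for spec in specs:
        data = np.asarray(events.get(spec.name, ()), dtype=float)
        if spec.kind == "analog":
            if data.size != n_samples:
                raise ValueError(
                    f"analog regressor {spec.name!r} must match signal length")
            cols.append(data)
            colmap.append((spec.name, 0.0))
            continue
        if data.size == 0:
            warnings.warn(f"variable {spec.name!r} has no events; "
                          "contributing zero columns")
            continue
        if data.min() < 0 or data.max() * rate > n_samples:
            raise ValueError(f"events for {spec.name!r} outside signal span")
        idx = np.round(data * rate).astype(int)
        if np.unique(idx).size < idx.size:
            warnings.warn(f"duplicate events for {spec.name!r} collapsed")
        train = np.zeros(n_samples)
        np.add.at(train, np.clip(idx, 0, n_samples - 1), 1.0)
        lag0 = int(round(spec.window[0] * rate))
        lag1 = int(round(spec.window[1] * rate))
        for lag in range(lag0, lag1):
            col = np.zeros(n_samples)
            if lag >= 0:
                col[lag:] = train[:n_samples - lag]
            else:
                col[:lag] = train[-lag:]
            cols.append(col)
            colmap.append((spec.name, lag / rate))
    X = np.column_stack(cols) if cols else np.zeros((n_samples, 0))
    return X, colmap


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """argmin ‖y − Xβ‖² + λ‖β‖² (no intercept; closed form)."""
    p = X.shape[1]
    gram = X.T @ X + lam * np.eye(p)
    if lam == 0.0:
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise np.linalg.LinAlgError(
                "design matrix is rank deficient at λ=0; use λ>0")
    return np.linalg.solve(gram, X.T @ y)


def _contiguous_folds(n: int, folds: int) -> list[np.ndarray]:
    """Split 0..n-1 into contiguous, nearly equal blocks."""
    edges = np.linspace(0, n, folds + 1).astype(int)
    return [np.arange(edges[k], edges[k + 1]) for k in range(folds)]


def cv_r2(X: np.ndarray, y: np.ndarray, lam: float, folds: int = 10) -> float:
    """Pooled cross-validated R² with contiguous time-block folds.

    Held-out predictions from all folds are pooled before computing
    1 − SS_res/SS_tot; the value may be negative on held-out data.
    """
    n = y.size
    yhat = np.zeros(n)
    for test in _contiguous_folds(n, folds):
        train = np.setdiff1d(np.arange(n), test, assume_unique=True)
        beta = _ridge_solve(X[train], y[train], lam)
        yhat[test] = X[test] @ beta
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def select_lambda(X: np.ndarray, y: np.ndarray,
                  grid=DEFAULT_LAMBDA_GRID, folds: int = 10) -> float:
    """Pick the λ maximizing contiguous-CV R² on a log grid.

    A single λ is selected once on the full design and shared by the full,
    single-variable and omission models, keeping ΔR² comparable.
    """
    scores = [cv_r2(X, y, lam, folds) for lam in grid]
    return float(np.asarray(grid)[int(np.argmax(scores))])


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float,
              colmap: list | None = None, folds: int = 10,
              seed: int = 0) -> KernelSet:
    """Fit the full ridge model and its contiguous-CV explained variance."""
    if X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    beta = _ridge_solve(X, y, lam)
    ks = KernelSet(lam=float(lam), cvr2_full=cv_r2(X, y, lam, folds))
    if colmap is not None:
        for var in dict.fromkeys(v for v, _ in colmap):
            sel = [j for j, (v, _) in enumerate(colmap) if v == var]
            ks.coefficients[var] = beta[sel]
            ks.lags_s[var] = np.array([colmap[j][1] for j in sel])
    else:
        ks.coefficients["all"] = beta
    return ks


def variable_contributions(X: np.ndarray, y: np.ndarray, colmap: list,
                           lam: float, folds: int = 10,
                           seed: int = 0) -> KernelSet:
    """Single-variable R² and unique contribution ΔR² per variable.

    ΔR² = CVR²(full) − CVR²(without the variable's columns). Both metrics
    are divided by the variable's column count and by the full-model CVR²
    (with the full CVR² clipped at a small positive floor for
    normalization only — reported values are never clipped). When the
    full-model CVR² is nonpositive, raw values are returned and
    ``normalization["applied"]`` is False.
    """
    ks = fit_ridge(X, y, lam, colmap, folds, seed)
    variables = list(dict.fromkeys(v for v, _ in colmap))
    raw_single, raw_delta, n_cols = {}, {}, {}
    for var in variables:
        sel = np.array([v == var for v, _ in colmap])
        n_cols[var] = int(sel.sum())
        raw_single[var] = cv_r2(X[:, sel], y, lam, folds)
        raw_delta[var] = ks.cvr2_full - cv_r2(X[:, ~sel], y, lam, folds)
    applied = ks.cvr2_full > 0
    if not applied:
        warnings.warn("full-model CVR² ≤ 0; returning unnormalized values")
        ks.r2_single, ks.delta_r2 = raw_single, raw_delta
    else:
        ks.r2_single = {v: raw_single[v] / n_cols[v] / ks.cvr2_full
                        for v in variables}
        ks.delta_r2 = {v: raw_delta[v] / n_cols[v] / ks.cvr2_full
                       for v in variables}
    ks.normalization = {"applied": bool(applied), "window_samples": n_cols,
                        "raw_r2_single": raw_single, "raw_delta_r2": raw_delta}
    return ks


def evoked_event_response(aligned: AlignedMatrix
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean ± s.e.m. over included trials of an aligned matrix."""
    rows = aligned.included()
    if rows.shape[0] == 0:
        raise ValueError("all trials excluded")
    mean = rows.mean(axis=0)
    sem = (rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0])
           if rows.shape[0] > 1 else np.zeros_like(mean))
    return mean, sem
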