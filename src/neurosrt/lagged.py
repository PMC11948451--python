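"""Lagged linear (TRF-style) ridge regression: decoder and encoder core.

Both the backward model (decoder: predict the stimulus envelope from
multichannel EEG) and the forward model (encoder: predict each EEG channel
from the envelope, yielding a temporal response function per channel) are
ridge regressions on a time-lagged design matrix.  This module provides
the lag-matrix construction, the ridge solver, prediction, the Pearson
accuracy metric, and leave-one-trial-out selection of the regularization
strength.

Regularization convention
-------------------------
``ridge_fit`` solves ``(X'X + lam * mbar * I) w = X'y`` on mean-centered
columns, where ``mbar = trace(X'X) / (n_rows * n_cols)`` is the mean
per-sample power of the design.  This makes ``lam`` invariant to the
amplitude units of the data (microvolts vs. normalized) while matching the
behavior of common TRF toolboxes on unit-variance inputs, where a fixed
``lam`` of 100 is a mild penalty for minute-long trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = [
    "LagWindow",
    "LaggedLinearModel",
    "build_lag_matrix",
    "ridge_fit",
    "pearson_accuracy",
    "loo_lambda_search",
    "DEFAULT_LAMBDA_GRID",
]

#: Decade-spaced grid 1e-4 .. 1e10 searched for the decoder penalty.
DEFAULT_LAMBDA_GRID = tuple(float(10.0**k) for k in range(-4, 11))


@dataclass(frozen=True)
class LagWindow:
    """A stimulus-response lag window in milliseconds at a given rate.

    Lags are realized as integer sample offsets from
    ``round(tau_min_ms / 1000 * rate)`` with
    ``round((tau_max_ms - tau_min_ms) / 1000 * rate) + 1`` consecutive
    steps.  Positive lags mean the response follows the stimulus (causal);
    a negative ``tau_min_ms`` provides an acausal margin.
    """

    tau_min_ms: float
    tau_max_ms: float
    rate: float = 64.0

    def __post_init__(self) -> None:
        if not self.tau_min_ms < self.tau_max_ms:
            raise ValueError("tau_min_ms must be below tau_max_ms")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_lags(self) -> int:
        return round((self.tau_max_ms - self.tau_min_ms) / 1000.0 * self.rate) + 1

    @property
    def lags(self) -> np.ndarray:
        """Integer sample offsets covered by the window."""
        start = round(self.tau_min_ms / 1000.0 * self.rate)
        return start + np.arange(self.n_lags)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lags / self.rate * 1000.0


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    """x shifted so that out[t] = x[t + k], zero-padded at the edges."""
    out = np.zeros_like(x)
    if k == 0:
        out[:] = x
    elif k > 0:
        out[:-k] = x[k:]
    else:
        out[-k:] = x[:k]
    return out


def build_lag_matrix(
    signal: np.ndarray, window: LagWindow, direction: str = "backward"
) -> np.ndarray:
    """Time-lagged design matrix, one row per time sample.

    ``signal`` is (channels, samples) or 1-D.  For the backward model row
    ``t`` contains ``signal[ch, t + tau]`` for every channel and lag tau
    (EEG relative to the envelope sample being predicted); the forward
    model uses ``signal[ch, t - tau]`` (stimulus history).  Samples
    falling outside the trial are zero-padded; trials are never
    concatenated across the lag boundary.
    """
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    n_ch, n_samp = sig.shape
    lags = window.lags
    if window.n_lags >= n_samp:
        raise ValueError(
            f"lag window ({window.n_lags} lags) is as long as the signal ({n_samp} samples)"
        )
    if direction not in ("backward", "forward"):
        raise ValueError(f"direction must be 'backward' or 'forward', got {direction!r}")
    sign = 1 if direction == "backward" else -1
    cols = np.empty((n_ch * len(lags), n_samp))
    for c in range(n_ch):
        for i, lag in enumerate(lags):
            cols[c * len(lags) + i] = _shift(sig[c], sign * int(lag))
    return cols.T


@dataclass
class LaggedLinearModel:
    """Fitted lagged ridge model (decoder or encoder).

    ``weights`` has shape (n_features, n_targets): n_features =
    channels x lags for the decoder (one target, the envelope) and
    lags for the encoder (one target per EEG channel).  ``intercept``
    restores the target mean(s).
    """

    weights: np.ndarray
    intercept: np.ndarray
    lam: float
    window: LagWindow
    direction: str
    n_channels: int
    meta: dict | None = None

    def predict(self, signal: np.ndarray) -> np.ndarray:
        """Apply the model to a (channels, samples) or 1-D signal.

        Returns the reconstructed envelope (backward) or the predicted
        EEG, shape (n_channels_out, n_samples) or 1-D for one target.
        """
        sig = np.atleast_2d(np.asarray(signal, dtype=float))
        if self.direction == "backward" and sig.shape[0] != self.n_channels:
            raise ValueError(
                f"decoder expects {self.n_channels} channels, got {sig.shape[0]}"
            )
        if self.direction == "forward" and sig.shape[0] != 1:
            raise ValueError("encoder expects a single-channel stimulus")
        X = build_lag_matrix(sig, self.window, self.direction)
        pred = X @ self.weights + self.intercept
        return pred[:, 0] if pred.shape[1] == 1 else pred.T

    def kernels(self) -> np.ndarray:
        """Weights reshaped per channel.

        Backward: (n_channels, n_lags).  Forward: (n_targets, n_lags) —
        one temporal response function per EEG channel.
        """
        if self.direction == "backward":
            return self.weights[:, 0].reshape(self.n_channels, self.window.n_lags)
        return self.weights.T.copy()

    def save(self, path_stem: str) -> None:
        """Serialize to ``<stem>.json`` (metadata) + ``<stem>.npz`` (arrays)."""
        meta = {
            "lam": self.lam,
            "direction": self.direction,
            "n_channels": self.n_channels,
            "window": {
                "tau_min_ms": self.window.tau_min_ms,
                "tau_max_ms": self.window.tau_max_ms,
                "rate": self.window.rate,
            },
            "meta": self.meta or {},
        }
        with open(path_stem + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)
        np.savez(path_stem + ".npz", weights=self.weights, intercept=self.intercept)

    @classmethod
    def load(cls, path_stem: str) -> "LaggedLinearModel":
        with open(path_stem + ".json") as fh:
            meta = json.load(fh)
        arrays = np.load(path_stem + ".npz")
        return cls(
            weights=arrays["weights"],
            intercept=arrays["intercept"],
            lam=meta["lam"],
            window=LagWindow(**meta["window"]),
            direction=meta["direction"],
            n_channels=meta["n_channels"],
            meta=meta.get("meta") or None,
        )


def _centered_normal_eqs(X: np.ndarray, Y: np.ndarray):
    """Centered Gram matrix, cross product, and means for ridge."""
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    A = Xc.T @ Xc
    B = Xc.T @ (Y - y_mean)
    return A, B, x_mean, y_mean


def ridge_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    window: LagWindow | None = None,
    direction: str = "backward",
    n_channels: int | None = None,
) -> LaggedLinearModel:
    """Ridge solution on mean-centered columns with scale-free ``lam``.

    Solves ``(Xc'Xc + lam * mbar * I) w = Xc'yc`` with ``mbar`` the mean
    per-sample power of the centered design; the intercept restores the
    target mean.  ``lam = 0`` requires a non-singular Gram matrix.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    A, B, x_mean, y_mean = _centered_normal_eqs(X, Y)
    mbar = np.trace(A) / (X.shape[0] * X.shape[1])
    K = A + lam * mbar * np.eye(A.shape[0])
    try:
        w = sla.cho_factor(K)
        W = sla.cho_solve(w, B)
    except sla.LinAlgError as exc:
        if lam == 0:
            raise np.linalg.LinAlgError(
                "X'X is singular with lambda = 0; use lambda > 0"
            ) from exc
        raise
    intercept = y_mean - x_mean @ W
    if window is None:
        window = LagWindow(0.0, (X.shape[1] - 1) * 1000.0, 1000.0)
    if n_channels is None:
        n_channels = X.shape[1] // window.n_lags
    return LaggedLinearModel(W, intercept, float(lam), window, direction, n_channels)


def pearson_accuracy(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two equal-length series.

    Raises on zero-variance input rather than silently returning 0 — a
    constant reconstruction is a degenerate model output, not chance-level
    performance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance input: Pearson correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


class _TrialStats:
    """Per-trial sufficient statistics for pooled/LOO ridge fits.

    Targets may be 1-D (decoder) or (n_samples, n_targets) (encoder).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        y = np.asarray(y, dtype=float)
        self.y = y[:, None] if y.ndim == 1 else y
        self.n = X.shape[0]
        self.A = X.T @ X
        self.b = X.T @ self.y
        self.sx = X.sum(axis=0)
        self.sy = self.y.sum(axis=0)


def _fold_solve_multi(stats: list["_TrialStats"], lam_grid) -> dict[float, np.ndarray]:
    """Centered ridge weights for every lambda from pooled trial stats.

    One eigendecomposition of the pooled centered Gram matrix serves all
    penalties on the grid.
    """
    n = sum(s.n for s in stats)
    A = sum(s.A for s in stats)
    b = sum(s.b for s in stats)
    sx = sum(s.sx for s in stats)
    sy = sum(s.sy for s in stats)
    Ac = A - np.outer(sx, sx) / n
    bc = b - np.outer(sx, sy / n)
    mbar = np.trace(Ac) / (n * Ac.shape[0])
    if len(lam_grid) == 1:
        lam = lam_grid[0]
        w = np.linalg.solve(Ac + lam * mbar * np.eye(Ac.shape[0]), bc)
        return {lam: w}
    evals, vecs = np.linalg.eigh(Ac)
    evals = np.clip(evals, 0.0, None)  # guard tiny negative eigenvalues (rank-deficient data)
    proj = vecs.T @ bc
    out = {}
    for lam in lam_grid:
        out[lam] = vecs @ (proj / (evals + lam * mbar)[:, None])
    return out


def loo_lambda_search(
    trials: list[tuple[np.ndarray, np.ndarray]],
    grid=DEFAULT_LAMBDA_GRID,
    return_details: bool = False,
):
    """Leave-one-trial-out selection of the ridge penalty.

    For every lambda on ``grid``, each trial is held out in turn, the
    model is fitted on the pooled rows of the remaining trials, and the
    Pearson correlation between prediction and held-out target is
    averaged across folds.  Returns the lambda maximizing the mean
    correlation; exact ties break toward the larger (more regularized)
    value.  With ``return_details`` also returns the per-fold correlation
    matrix (n_trials x n_lambdas) and the grid.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    if len(trials) < 2:
        raise ValueError("leave-one-out needs at least 2 trials")
    stats = [_TrialStats(X, y) for X, y in trials]
    fold_r = np.empty((len(trials), len(grid)))
    for i in range(len(trials)):
        rest = [s for j, s in enumerate(stats) if j != i]
        w_by_lam = _fold_solve_multi(rest, grid)
        held = stats[i]
        for k, lam in enumerate(grid):
            pred = held.X @ w_by_lam[lam]
            fold_r[i, k] = pearson_accuracy(pred, held.y)
    mean_r = fold_r.mean(axis=0)
    best = max(range(len(grid)), key=lambda k: (mean_r[k], grid[k]))
    if return_details:
        return grid[best], fold_r, np.asarray(grid)
    return grid[best]


def pooled_ridge_fit(
    trials: list[tuple[np.ndarray, np.ndarray]],
    lam: float,
    window: LagWindow | None = None,
    direction: str = "backward",
    n_channels: int | None = None,
) -> LaggedLinearModel:
    """Ridge fit pooling the rows of several trials (no cross-boundary lags)."""
    stats = [_TrialStats(X, y) for X, y in trials]
    W = _fold_solve_multi(stats, [lam])[lam]
    n = sum(s.n for s in stats)
    x_mean = sum(s.sx for s in stats) / n
    y_mean = sum(s.sy for s in stats) / n
    intercept = np.atleast_1d(y_mean - x_mean @ W)
    n_feat = trials[0][0].shape[1]
    if window is None:
        window = LagWindow(0.0, (n_feat - 1) * 1000.0, 1000.0)
    if n_channels is None:
        n_channels = n_feat // window.n_lags
    return LaggedLinearModel(W, intercept, float(lam), window, direction, n_channels)
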