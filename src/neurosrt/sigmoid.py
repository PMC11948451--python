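"""Psychometric-style sigmoid model of reconstruction accuracy vs. SNR.

The accuracy-versus-SNR relationship is modeled by a four-parameter
logistic with fixed asymptotes,

    S(SNR) = (p - b) / (1 + exp(4 s / (p - b) * (m - SNR))) + b,

where ``p`` is the mean clean-speech reconstruction accuracy (upper
asymptote, fixed), ``b`` the mismatched-envelope noise-floor mean (lower
asymptote, fixed), ``s`` the slope at the midpoint and ``m`` the midpoint
SNR in dB.  The fitted midpoint is the EEG-based speech reception
threshold (SRT_neuro).

Only (s, m) are estimated, by trial-level least squares with multiple
random restarts of the midpoint: ``s`` starts at 0 and ``m`` uniformly
within +/-10 dB of -2.52 dB (the normative behavioral SRT of the Danish
HINT for normal-hearing listeners).  The final estimate averages the
parameters of the 10 restarts with the highest R^2, which guards against
local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = ["SigmoidFit", "sigmoid_eval", "fit_sigmoid", "NORMATIVE_SRT_DB"]

#: Normative behavioral SRT (dB) used to center midpoint initialization.
NORMATIVE_SRT_DB = -2.52

#: Optimization bounds: m in [-1e10, 1e10], s in [0, 1e10].
M_BOUNDS = (-1e10, 1e10)
S_BOUNDS = (0.0, 1e10)


@dataclass
class SigmoidFit:
    """Fitted sigmoid: fixed asymptotes (p, b), fitted slope s and midpoint m.

    ``m`` is the SRT_neuro in dB.  ``r_squared`` is 1 - SS_res/SS_tot on
    the fitted trial-level points; ``restarts`` records (s, m, R^2) for
    every random restart.
    """

    p: float
    b: float
    s: float
    m: float
    r_squared: float
    restarts: np.ndarray | None = field(default=None, repr=False)

    def __call__(self, snr):
        return sigmoid_eval(self, snr)

    @property
    def srt_neuro(self) -> float:
        return self.m

    def curve_frame(self, snr_grid):
        """Plot-ready table of the fitted curve on an SNR grid."""
        import pandas as pd

        snr_grid = np.asarray(snr_grid, dtype=float)
        return pd.DataFrame({"snr_db": snr_grid, "accuracy": sigmoid_eval(self, snr_grid)})


def sigmoid_eval(model, snr):
    """Evaluate the sigmoid at SNR values (model: anything with p, b, s, m)."""
    snr = np.asarray(snr, dtype=float)
    p, b, s, m = model.p, model.b, model.s, model.m
    val = (p - b) * expit(4.0 * s / (p - b) * (snr - m)) + b
    return float(val) if val.ndim == 0 else val


def _residual_and_jac(x: np.ndarray, y: np.ndarray, p: float, b: float):
    span = p - b

    def resid(theta):
        s, m = theta
        return span * expit(4.0 * s / span * (x - m)) + b - y

    def jac(theta):
        s, m = theta
        sig = expit(4.0 * s / span * (x - m))
        core = sig * (1.0 - sig)
        return np.column_stack([4.0 * core * (x - m), -4.0 * s * core])

    return resid, jac


def fit_sigmoid(
    snr: np.ndarray,
    r: np.ndarray,
    p_fixed: float,
    b_fixed: float,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 100,
    n_best: int = 10,
    init_center: float = NORMATIVE_SRT_DB,
    init_halfwidth: float = 10.0,
) -> SigmoidFit:
    """Least-squares fit of (s, m) on trial-level (SNR, accuracy) points.

    Runs ``n_restarts`` bounded least-squares fits with random midpoint
    initialization and averages the parameters of the ``n_best`` restarts
    with the highest R^2.  Deterministic given ``seed``.
    """
    x = np.asarray(snr, dtype=float)
    y = np.asarray(r, dtype=float)
    if x.shape != y.shape:
        raise ValueError("snr and r must have the same shape")
    if len(np.unique(x)) < 3:
        raise ValueError("need points at 3 or more distinct SNRs")
    if not p_fixed > b_fixed:
        raise ValueError("upper asymptote p must exceed lower asymptote b")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if np.all(y == y[0]) or ss_tot == 0:
        raise ValueError("all accuracy values identical: R^2 undefined")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    resid, jac = _residual_and_jac(x, y, p_fixed, b_fixed)

    records = np.empty((n_restarts, 3))
    for i in range(n_restarts):
        m0 = init_center + rng.uniform(-init_halfwidth, init_halfwidth)
        sol = least_squares(
            resid,
            x0=[0.0, m0],
            jac=jac,
            bounds=([S_BOUNDS[0], M_BOUNDS[0]], [S_BOUNDS[1], M_BOUNDS[1]]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        r2 = 1.0 - np.sum(sol.fun**2) / ss_tot
        records[i] = (sol.x[0], sol.x[1], r2)

    top = records[np.argsort(records[:, 2], kind="stable")[::-1][:n_best]]
    s_hat = float(top[:, 0].mean())
    m_hat = float(top[:, 1].mean())
    final = SigmoidFit(p_fixed, b_fixed, s_hat, m_hat, 0.0, restarts=records)
    resid_final = sigmoid_eval(final, x) - y
    final.r_squared = float(1.0 - np.sum(resid_final**2) / ss_tot)
    return final
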