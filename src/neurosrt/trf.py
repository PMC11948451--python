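"""Forward-model TRF estimation, deflection fits, and SNR effects.

Per condition, an encoder (envelope -> each EEG channel) is estimated by
leave-one-trial-out ridge regression with a fixed penalty, yielding one
temporal response function (TRF) per channel plus per-channel prediction
accuracies.  A global set of high-accuracy electrodes is selected, the
mean TRF over those electrodes is parameterized by three Gaussian
deflections (P1, N1, P2), and per-dB SNR effects on the deflection
latencies and amplitudes are estimated with a random-intercept linear
mixed model with Wald tests and a Holm-Bonferroni correction over the six
feature tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLEAN, EegDataset, EegTrial, condition_key
from .lagged import LagWindow, build_lag_matrix, pearson_accuracy, pooled_ridge_fit
from .simulate import make_envelope
from .stats import holm_bonferroni, permutation_test_two_sample

__all__ = [
    "ENCODER_WINDOW",
    "ENCODER_LAMBDA",
    "DEFLECTION_BOUNDS",
    "TrfEstimate",
    "DeflectionFit",
    "fit_encoder",
    "encoder_significance_gate",
    "select_channels",
    "fit_deflections",
    "lmm_snr_effects",
    "grand_average_trf",
]

#: Encoder lag window (ms): -100 ms acausal margin to 500 ms.
ENCODER_WINDOW = LagWindow(-100.0, 500.0, 64.0)

#: Fixed encoder ridge penalty, shared across participants and conditions.
ENCODER_LAMBDA = 100.0

#: Per-component bounds for the Gaussian deflection fit:
#: amplitude p (a.u.), latency l (ms), width w (ms).
DEFLECTION_BOUNDS = {
    "P1": {"p": (0.0, 5.0), "l": (0.0, 100.0), "w": (0.0, 50.0)},
    "N1": {"p": (-5.0, 0.0), "l": (70.0, 150.0), "w": (0.0, 50.0)},
    "P2": {"p": (0.0, 5.0), "l": (100.0, 300.0), "w": (0.0, 50.0)},
}

#: Deflection fits below this R^2 are excluded from further analysis.
DEFLECTION_R2_GATE = 0.5


@dataclass
class TrfEstimate:
    """Per-condition encoder outcome for one participant.

    ``kernels`` is (n_channels, n_lags): the mean of the leave-one-out
    fold models.  ``accuracy`` is the mean held-out per-channel Pearson r.
    """

    participant_id: str
    condition: float | str
    kernels: np.ndarray
    accuracy: np.ndarray
    per_trial_accuracy: np.ndarray  # (n_trials, n_channels)
    window: LagWindow
    lam: float
    trial_ids: list[str] = field(default_factory=list)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.window.lag_times_ms


def _encoder_designs(trials: list[EegTrial], window: LagWindow):
    out = []
    for t in trials:
        X = build_lag_matrix(np.asarray(t.envelope)[None, :], window, "forward")
        n = min(X.shape[0], t.n_samples)
        out.append((X[:n], t.data.T[:n]))
    return out


def fit_encoder(
    dataset: EegDataset,
    window: LagWindow = ENCODER_WINDOW,
    lam: float = ENCODER_LAMBDA,
) -> dict[str, TrfEstimate]:
    """Leave-one-trial-out encoder per condition at a fixed penalty.

    For each condition, each trial is held out in turn; the model is
    fitted on the pooled remaining trials and evaluated channel-wise on
    the held-out trial.  The condition's TRF is the mean of the fold
    models and its prediction accuracy the mean held-out correlation.
    """
    estimates: dict[str, TrfEstimate] = {}
    for cond in dataset.conditions:
        trials = dataset.by_condition(cond)
        if len(trials) < 2:
            raise ValueError(
                f"condition {cond!r} has {len(trials)} trials; leave-one-out needs >= 2"
            )
        designs = _encoder_designs(trials, window)
        n_ch = trials[0].n_channels
        fold_weights = np.empty((len(trials), window.n_lags, n_ch))
        fold_acc = np.empty((len(trials), n_ch))
        for i in range(len(trials)):
            rest = [d for j, d in enumerate(designs) if j != i]
            model = pooled_ridge_fit(rest, lam, window=window, direction="forward", n_channels=1)
            fold_weights[i] = model.weights
            Xh, Yh = designs[i]
            pred = Xh @ model.weights
            for c in range(n_ch):
                fold_acc[i, c] = pearson_accuracy(pred[:, c], Yh[:, c])
        estimates[condition_key(cond)] = TrfEstimate(
            participant_id=dataset.participant_id,
            condition=cond,
            kernels=fold_weights.mean(axis=0).T,
            accuracy=fold_acc.mean(axis=0),
            per_trial_accuracy=fold_acc,
            window=window,
            lam=lam,
            trial_ids=[t.trial_id for t in trials],
        )
    return estimates


def encoder_significance_gate(
    estimates: dict[str, TrfEstimate],
    dataset: EegDataset,
    channels: list[str],
    alpha: float = 0.05,
    n_mismatch: int = 68,
    seed: int = 131,
    window: LagWindow = ENCODER_WINDOW,
    lam: float = ENCODER_LAMBDA,
) -> dict[str, dict]:
    """Per-condition permutation gate on encoder prediction accuracy.

    For each condition, the per-trial prediction accuracies (mean over the
    selected electrodes) are tested against a noise floor built by
    predicting the EEG from mismatched surrogate envelopes with the same
    encoder.  Returns, per condition key, ``{"included": bool, "p": float}``.
    """
    ch_idx = [dataset.channel_labels.index(c) for c in channels]
    rng = np.random.default_rng(seed)
    out = {}
    for key, est in estimates.items():
        trials = dataset.by_condition(est.condition)
        duration = trials[0].n_samples / trials[0].rate
        mismatch = [
            make_envelope(duration, int(rng.integers(2**31))).values
            for _ in range(n_mismatch)
        ]
        designs = _encoder_designs(trials, window)
        model = pooled_ridge_fit(designs, lam, window=window, direction="forward", n_channels=1)
        floor = np.empty((len(trials), len(mismatch)))
        for j, env in enumerate(mismatch):
            Xm = build_lag_matrix(env[None, :], window, "forward")
            for i, (Xh, Yh) in enumerate(designs):
                n = min(Xm.shape[0], Yh.shape[0])
                pred = Xm[:n] @ model.weights
                rs = [
                    pearson_accuracy(pred[:, c], Yh[:n, c]) for c in ch_idx
                ]
                floor[i, j] = np.mean(rs)
        observed = est.per_trial_accuracy[:, ch_idx].mean(axis=1)
        p = permutation_test_two_sample(
            observed, floor.mean(axis=1), seed=np.random.default_rng(int(rng.integers(2**31)))
        )
        out[key] = {"included": bool(p < alpha), "p": float(p)}
    return out


def select_channels(
    estimates_per_participant: list[dict[str, TrfEstimate]],
    channel_labels: list[str],
    k: int = 17,
) -> list[str]:
    """Global electrode selection by grand-average prediction accuracy.

    Accuracies are averaged across participants and conditions (clean
    included); the top ``k`` channels are returned, ties broken by montage
    order.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(channel_labels):
        raise ValueError("k exceeds the number of channels")
    acc = np.mean(
        [est.accuracy for ests in estimates_per_participant for est in ests.values()],
        axis=0,
    )
    order = sorted(range(len(channel_labels)), key=lambda i: (-acc[i], i))
    return [channel_labels[i] for i in order[:k]]


@dataclass
class DeflectionFit:
    """Gaussian parameterization a(t) = p * exp(-((t - l) / w)^2).

    ``excluded`` marks fits with R^2 below the 0.5 gate; ``at_bound``
    marks latency estimates pinned to a boundary (unreliable).
    """

    component: str
    p: float
    l: float
    w: float
    r_squared: float
    excluded: bool
    at_bound: bool = False


def fit_deflections(
    mean_trf: np.ndarray,
    times_ms: np.ndarray,
    bounds: dict | None = None,
    r2_gate: float = DEFLECTION_R2_GATE,
) -> list[DeflectionFit]:
    """Fit P1/N1/P2 Gaussians to a mean TRF over their latency windows.

    Each component is fitted by bounded least squares on the TRF samples
    within its latency bounds.  Degenerate segments (zero variance) are
    returned as excluded fits with R^2 = 0.
    """
    from scipy.optimize import least_squares

    bounds = bounds or DEFLECTION_BOUNDS
    trf = np.asarray(mean_trf, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    fits = []
    for name, bnd in bounds.items():
        lo_l, hi_l = bnd["l"]
        seg = (times >= lo_l) & (times <= hi_l)
        t = times[seg]
        y = trf[seg]
        if len(t) < 4 or np.allclose(y, y[0]):
            fits.append(DeflectionFit(name, 0.0, float(t[0]) if len(t) else lo_l, 1.0, 0.0, True))
            continue
        ss_tot = np.sum((y - y.mean()) ** 2)
        positive = bnd["p"][1] > 0
        i0 = int(np.argmax(y)) if positive else int(np.argmin(y))
        p0 = float(np.clip(y[i0], bnd["p"][0] + 1e-9, bnd["p"][1] - 1e-9))
        x0 = [p0, float(t[i0]), 20.0]
        lower = [bnd["p"][0], lo_l, 1e-6]
        upper = [bnd["p"][1], hi_l, bnd["w"][1]]

        def resid(theta):
            p, l, w = theta
            return p * np.exp(-(((t - l) / w) ** 2)) - y

        sol = least_squares(resid, x0, bounds=(lower, upper))
        r2 = float(1.0 - np.sum(sol.fun**2) / ss_tot)
        p_hat, l_hat, w_hat = (float(v) for v in sol.x)
        at_bound = np.isclose(l_hat, lo_l) or np.isclose(l_hat, hi_l)
        fits.append(
            DeflectionFit(name, p_hat, l_hat, w_hat, r2, excluded=r2 < r2_gate, at_bound=at_bound)
        )
    return fits


def _fit_random_intercept(data: pd.DataFrame, feature: str):
    """ML random-intercept fit with optimizer fallbacks.

    When the between-participant variance collapses to zero the mixed-model
    Hessian is singular; in that boundary case the model degenerates to
    pooled ordinary least squares, which is used as the final fallback.
    """
    import warnings

    import statsmodels.formula.api as smf

    model = smf.mixedlm(f"{feature} ~ snr_rel", data, groups=data["participant_id"])
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=False, method=method)
            if np.isfinite(fit.bse["snr_rel"]):
                return fit
        except (np.linalg.LinAlgError, ValueError):
            continue
    return smf.ols(f"{feature} ~ snr_rel", data).fit()


def lmm_snr_effects(
    deflection_table: pd.DataFrame,
    alpha: float = 0.05,
    min_participants: int = 3,
) -> pd.DataFrame:
    """Random-intercept mixed-model SNR effects on deflection features.

    ``deflection_table`` has one row per participant x noise condition x
    component with columns ``participant_id``, ``snr_rel`` (dB relative to
    the behavioral SRT; the clean condition must already be excluded),
    ``component``, ``amplitude``, ``latency``.  For each of the six
    (component, feature) pairs a linear mixed model
    ``feature ~ snr + (1 | participant)`` is fitted by maximum likelihood;
    the fixed effect is assessed with a Wald t-test (df = n_obs -
    n_groups - 1) and a Holm-Bonferroni correction over the six tests.
    """
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    rows = []
    for component in ("P1", "N1", "P2"):
        sub = deflection_table[deflection_table["component"] == component]
        for feature in ("amplitude", "latency"):
            data = sub.dropna(subset=[feature, "snr_rel"])
            n_part = data["participant_id"].nunique()
            if n_part < min_participants:
                rows.append(
                    {
                        "component": component,
                        "feature": feature,
                        "intercept": np.nan,
                        "coefficient": np.nan,
                        "std_error": np.nan,
                        "t": np.nan,
                        "df": np.nan,
                        "p_value": np.nan,
                        "estimable": False,
                    }
                )
                continue
            fit = _fit_random_intercept(data, feature)
            coef = float(fit.params["snr_rel"])
            se = float(fit.bse["snr_rel"])
            tval = coef / se
            df = len(data) - n_part - 1
            pval = float(2 * sps.t.sf(abs(tval), df))
            rows.append(
                {
                    "component": component,
                    "feature": feature,
                    "intercept": float(fit.params["Intercept"]),
                    "coefficient": coef,
                    "std_error": se,
                    "t": tval,
                    "df": df,
                    "p_value": pval,
                    "estimable": True,
                }
            )
    out = pd.DataFrame(rows)
    ok = out["estimable"] & out["p_value"].notna()
    decisions = np.zeros(len(out), dtype=bool)
    if ok.any():
        decisions[np.flatnonzero(ok)] = holm_bonferroni(
            out.loc[ok, "p_value"].to_numpy(), alpha=alpha
        )
    out["holm_significant"] = decisions
    return out


def grand_average_trf(
    estimates_per_participant: list[dict[str, TrfEstimate]],
    channels: list[str],
    channel_labels: list[str],
    display_window_ms: tuple[float, float] = (-100.0, 400.0),
) -> pd.DataFrame:
    """Across-participant mean of the selected-electrode mean TRFs.

    The display window drops the final stretch of the lag range, where
    edge effects distort the estimate.  Returns a tidy frame with
    condition, tau_ms, weight.
    """
    ch_idx = [channel_labels.index(c) for c in channels]
    rows = []
    conditions = estimates_per_participant[0].keys()
    for key in conditions:
        per_part = [ests[key] for ests in estimates_per_participant if key in ests]
        times = per_part[0].lag_times_ms
        mean_trf = np.mean([e.kernels[ch_idx].mean(axis=0) for e in per_part], axis=0)
        keep = (times >= display_window_ms[0]) & (times <= display_window_ms[1])
        for t, w in zip(times[keep], mean_trf[keep]):
            rows.append({"condition": key, "tau_ms": float(t), "weight": float(w)})
    return pd.DataFrame(rows)
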