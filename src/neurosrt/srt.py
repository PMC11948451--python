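"""EEG-based SRT estimation: decoder accuracies, noise floor, sigmoid fit.

Per participant, a backward model (decoder) is trained on the pooled
clean-speech trials with a leave-one-trial-out selected ridge penalty,
applied to every noise trial to obtain trial-level reconstruction
accuracies (Pearson r between reconstructed and true envelope), and the
accuracy-versus-SNR points are fitted with the fixed-asymptote sigmoid of
:mod:`neurosrt.sigmoid`; the fitted midpoint is the SRT_neuro.  The lower
asymptote is the noise floor: the mean correlation between reconstructed
envelopes and a pool of mismatched envelopes that were never presented.
A per-participant permutation gate requires the clean-condition
accuracies to exceed the noise floor before any fit is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLEAN, EegDataset, EegTrial
from .lagged import (
    DEFAULT_LAMBDA_GRID,
    LaggedLinearModel,
    LagWindow,
    build_lag_matrix,
    loo_lambda_search,
    pearson_accuracy,
    pooled_ridge_fit,
)
from .sigmoid import SigmoidFit, fit_sigmoid
from .simulate import make_envelope
from .stats import permutation_test_two_sample, sign_flip_test

__all__ = [
    "DECODER_WINDOW",
    "DecoderTraining",
    "NoiseFloor",
    "GateResult",
    "SrtNeuroResult",
    "train_decoder",
    "compute_accuracies",
    "compute_noise_floor",
    "gate_participant",
    "adjacent_snr_tests",
    "estimate_srt_neuro",
]

#: Decoder decision window (ms relative to the envelope sample).
DECODER_WINDOW = LagWindow(-100.0, 350.0, 64.0)


@dataclass
class DecoderTraining:
    """A trained decoder with its cross-validation record."""

    model: LaggedLinearModel
    best_lambda: float
    clean_loo_r: np.ndarray  # held-out accuracy per clean trial at best lambda
    fold_r: np.ndarray  # (n_clean_trials, n_lambdas)
    lambda_grid: np.ndarray
    clean_trial_ids: list[str]


@dataclass
class NoiseFloor:
    """Mismatched-envelope correlations for a set of trials.

    ``raw`` is (n_trials, n_mismatch); ``per_trial_means`` averages over
    the mismatch pool within each trial; ``b`` is the grand mean used as
    the sigmoid's lower asymptote.
    """

    b: float
    raw: np.ndarray
    per_trial_means: np.ndarray
    trial_ids: list[str]


@dataclass
class GateResult:
    passed: bool
    p_value: float


@dataclass
class SrtNeuroResult:
    """Per-participant outcome of the EEG-based SRT estimation.

    ``fitted`` is False when the participant failed the noise-floor gate,
    in which case no SRT is emitted.  ``robustness_spread`` is the largest
    pairwise difference among the midpoints of repeated runs of the full
    fitting procedure.
    """

    participant_id: str
    fitted: bool
    gate: GateResult
    best_lambda: float
    p: float | None = None
    b: float | None = None
    fit: SigmoidFit | None = None
    srt_neuro: float | None = None
    robustness_spread: float | None = None
    m_repeats: np.ndarray | None = field(default=None, repr=False)
    accuracies: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [f"SRT_neuro estimation — participant {self.participant_id}"]
        lines.append(f"  decoder lambda     : {self.best_lambda:g}")
        lines.append(
            f"  noise-floor gate   : {'pass' if self.gate.passed else 'FAIL'}"
            f" (p = {self.gate.p_value:.4g})"
        )
        if self.fitted:
            lines.append(f"  clean accuracy p   : {self.p:.4f}")
            lines.append(f"  noise floor b      : {self.b:.4f}")
            lines.append(f"  slope s            : {self.fit.s:.4f} /dB")
            lines.append(f"  SRT_neuro (m)      : {self.srt_neuro:.2f} dB")
            lines.append(f"  fit R^2            : {self.fit.r_squared:.3f}")
            if self.robustness_spread is not None:
                lines.append(f"  robustness spread  : {self.robustness_spread:.3f} dB")
        else:
            lines.append("  no fit: clean accuracies not above the noise floor")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "fitted": self.fitted,
            "gate_p": self.gate.p_value,
            "lambda": self.best_lambda,
            "p": self.p,
            "b": self.b,
            "s": None if self.fit is None else self.fit.s,
            "m": self.srt_neuro,
            "r_squared": None if self.fit is None else self.fit.r_squared,
            "robustness_spread": self.robustness_spread,
        }


def _design(trial: EegTrial, window: LagWindow):
    X = build_lag_matrix(trial.data, window, "backward")
    y = np.asarray(trial.envelope, dtype=float)
    n = min(X.shape[0], len(y))
    return X[:n], y[:n]


def train_decoder(
    dataset: EegDataset,
    window: LagWindow = DECODER_WINDOW,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> DecoderTraining:
    """Train the decoder on all clean trials, pooled, with LOO-selected lambda.

    The ridge penalty is chosen by leave-one-trial-out cross-validation
    within the clean condition (mean held-out Pearson r over folds); the
    final decoder pools the rows of all clean trials at that penalty.
    """
    clean = dataset.by_condition(CLEAN)
    if not clean:
        raise ValueError("dataset has no clean-speech condition")
    designs = [_design(t, window) for t in clean]
    best, fold_r, grid = loo_lambda_search(designs, lambda_grid, return_details=True)
    model = pooled_ridge_fit(
        designs, best, window=window, direction="backward", n_channels=clean[0].n_channels
    )
    best_col = int(np.argmax(grid == best))
    return DecoderTraining(
        model=model,
        best_lambda=best,
        clean_loo_r=fold_r[:, best_col].copy(),
        fold_r=fold_r,
        lambda_grid=np.asarray(grid),
        clean_trial_ids=[t.trial_id for t in clean],
    )


def compute_accuracies(
    dataset: EegDataset,
    training: DecoderTraining,
    srt_center: float | None = None,
) -> pd.DataFrame:
    """Trial-level reconstruction accuracies for every condition.

    Noise trials are decoded with the pooled clean-trained decoder; the
    clean condition reports the leave-one-out held-out accuracies from
    training (a decoder never reconstructs its own training trial).
    Columns: participant_id, trial_id, condition, snr_db (NaN for clean),
    snr_offset (relative to ``srt_center`` when known), r.
    """
    if srt_center is None and dataset.ground_truth:
        srt_center = dataset.ground_truth.get("srt_center")
    rows = []
    loo = dict(zip(training.clean_trial_ids, training.clean_loo_r))
    for trial in dataset.trials:
        if trial.condition == CLEAN:
            r = loo[trial.trial_id]
            snr = np.nan
        else:
            rec = training.model.predict(trial.data)
            n = min(len(rec), len(trial.envelope))
            r = pearson_accuracy(rec[:n], trial.envelope[:n])
            snr = float(trial.condition)
        rows.append(
            {
                "participant_id": trial.participant_id or dataset.participant_id,
                "trial_id": trial.trial_id,
                "condition": "clean" if trial.condition == CLEAN else f"{snr:+.2f}",
                "snr_db": snr,
                # rounded so condition offsets are exact grid levels across
                # participants despite float arithmetic on absolute SNRs
                "snr_offset": np.nan
                if (np.isnan(snr) or srt_center is None)
                else round(snr - srt_center, 6),
                "r": float(r),
            }
        )
    return pd.DataFrame(rows)


def compute_noise_floor(
    dataset: EegDataset,
    model: LaggedLinearModel,
    trials: list[EegTrial] | None = None,
    n_mismatch: int = 68,
    seed: int = 97,
    mismatch_envelopes: list[np.ndarray] | None = None,
) -> NoiseFloor:
    """Correlations between reconstructed envelopes and mismatched envelopes.

    ``trials`` defaults to all noise-condition trials.  Mismatched
    envelopes are drawn from the surrogate envelope generator with seeds
    outside the dataset's seed stream (stand-ins for unused audiobook
    excerpts) and truncated to the common length with each reconstruction.
    """
    if trials is None:
        trials = [t for t in dataset.trials if t.condition != CLEAN]
    if mismatch_envelopes is None:
        if n_mismatch < 1:
            raise ValueError("mismatch pool is empty")
        rng = np.random.default_rng(seed)
        duration = trials[0].n_samples / trials[0].rate
        mismatch_envelopes = [
            make_envelope(duration, int(rng.integers(2**31))).values
            for _ in range(n_mismatch)
        ]
    if not mismatch_envelopes:
        raise ValueError("mismatch pool is empty")
    raw = np.empty((len(trials), len(mismatch_envelopes)))
    for i, trial in enumerate(trials):
        rec = model.predict(trial.data)
        for j, env in enumerate(mismatch_envelopes):
            n = min(len(rec), len(env))
            raw[i, j] = pearson_accuracy(rec[:n], env[:n])
    means = raw.mean(axis=1)
    return NoiseFloor(float(raw.mean()), raw, means, [t.trial_id for t in trials])


def gate_participant(
    clean_accuracies: np.ndarray,
    floor_means: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> GateResult:
    """One-sided permutation gate: clean accuracies above the noise floor.

    Tests mean(clean) > mean(floor) with a two-sample label-permutation
    test on equally sized samples (one floor mean per trial).
    """
    clean_accuracies = np.asarray(clean_accuracies, dtype=float)
    floor_means = np.asarray(floor_means, dtype=float)
    if clean_accuracies.size != floor_means.size:
        raise ValueError(
            "gate compares equal counts: one floor mean per clean trial"
        )
    p = permutation_test_two_sample(
        clean_accuracies, floor_means, n_permutations=n_permutations, seed=seed
    )
    return GateResult(passed=bool(p < alpha), p_value=float(p))


def adjacent_snr_tests(
    table: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    snr_column: str = "snr_offset",
) -> pd.DataFrame:
    """Population-level one-sided tests between adjacent SNR conditions.

    For each adjacent pair of noise conditions, participant-mean
    accuracies are differenced (higher SNR minus lower) and tested with a
    paired sign-flip permutation test (exact enumeration for 14 or fewer
    participants, otherwise 10^4 random sign patterns; p resolution well
    below 0.01).
    """
    noise = table.dropna(subset=[snr_column])
    levels = np.sort(noise[snr_column].unique())
    if len(levels) < 2:
        raise ValueError("need at least two noise conditions")
    means = noise.groupby(["participant_id", snr_column])["r"].mean().unstack()
    if means.shape[0] < 2:
        raise ValueError("population test needs at least 2 participants")
    rng = np.random.default_rng(seed)
    rows = []
    for lo, hi in zip(levels[:-1], levels[1:]):
        diffs = (means[hi] - means[lo]).to_numpy()
        p = sign_flip_test(diffs, n_permutations=n_permutations, seed=rng)
        rows.append(
            {
                "pair": f"{lo:+g} vs {hi:+g} dB",
                "low_snr": lo,
                "high_snr": hi,
                "mean_difference": diffs.mean(),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def estimate_srt_neuro(
    dataset: EegDataset,
    seed: int = 0,
    window: LagWindow = DECODER_WINDOW,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_mismatch: int = 68,
    n_restarts: int = 100,
    n_repeats: int = 100,
    alpha: float = 0.05,
    srt_center: float | None = None,
) -> SrtNeuroResult:
    """Full per-participant SRT_neuro estimation.

    Trains the decoder, computes accuracies and the noise floor, applies
    the clean-above-floor permutation gate, and — when the gate passes —
    fits the sigmoid on the trial-level noise-condition points with
    ``n_restarts`` random restarts.  The whole fitting procedure is
    repeated ``n_repeats`` times with fresh restart seeds; the reported
    SRT_neuro comes from the first repetition, and the spread (max - min
    of the repeated midpoints) quantifies fitting robustness.
    """
    master = np.random.default_rng(seed)
    training = train_decoder(dataset, window, lambda_grid)
    acc = compute_accuracies(dataset, training, srt_center=srt_center)

    noise_trials = [t for t in dataset.trials if t.condition != CLEAN]
    clean_trials = dataset.by_condition(CLEAN)
    floor_seed = int(master.integers(2**31))
    rng_dur = noise_trials[0].n_samples / noise_trials[0].rate
    mismatch_rng = np.random.default_rng(floor_seed)
    mismatch = [
        make_envelope(rng_dur, int(mismatch_rng.integers(2**31))).values
        for _ in range(n_mismatch)
    ]
    floor_noise = compute_noise_floor(
        dataset, training.model, trials=noise_trials, mismatch_envelopes=mismatch
    )
    floor_clean = compute_noise_floor(
        dataset, training.model, trials=clean_trials, mismatch_envelopes=mismatch
    )

    gate = gate_participant(
        training.clean_loo_r,
        floor_clean.per_trial_means,
        alpha=alpha,
        seed=np.random.default_rng(int(master.integers(2**31))),
    )
    result = SrtNeuroResult(
        participant_id=dataset.participant_id,
        fitted=False,
        gate=gate,
        best_lambda=training.best_lambda,
        accuracies=acc,
    )
    if not gate.passed:
        return result

    noise_rows = acc.dropna(subset=["snr_db"])
    x = noise_rows["snr_db"].to_numpy()
    y = noise_rows["r"].to_numpy()
    p_fixed = float(training.clean_loo_r.mean())
    b_fixed = floor_noise.b

    m_values = np.empty(max(n_repeats, 1))
    first_fit = None
    for rep in range(max(n_repeats, 1)):
        fit = fit_sigmoid(
            x,
            y,
            p_fixed,
            b_fixed,
            seed=int(master.integers(2**31)),
            n_restarts=n_restarts,
        )
        m_values[rep] = fit.m
        if rep == 0:
            first_fit = fit

    result.fitted = True
    result.p = p_fixed
    result.b = b_fixed
    result.fit = first_fit
    result.srt_neuro = first_fit.m
    result.robustness_spread = float(m_values.max() - m_values.min())
    result.m_repeats = m_values
    return result
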