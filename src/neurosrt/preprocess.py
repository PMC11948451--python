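"""Deterministic EEG preprocessing: bad channels, referencing, filtering.

Steps mirror a standard decoder-oriented EEG pipeline: channels whose RMS
exceeds 3x the mean RMS across channels are replaced by spherical-spline
interpolation; the recording is re-referenced to the common average,
band-pass filtered to 1-8 Hz (zero-phase Butterworth cascade), resampled
to 64 Hz, normalized by the mean of the per-channel standard deviations
(one scalar per trial, preserving the relative topography), and finally
re-referenced to the common average again.

Artifact removal by independent component analysis is deliberately not
included; ``preprocess`` accepts an ``artifact_hook`` so users of real
recordings can insert their own component-based cleaning between
interpolation and filtering.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre

from .containers import EegTrial
from .envelope import bandpass_zero_phase, resample_poly_rate
from .montage import MontagePositions

__all__ = [
    "detect_bad_channels",
    "spherical_interpolate",
    "preprocess",
    "preprocess_dataset",
]


def detect_bad_channels(trial_or_data, pooled: list | None = None) -> set[str]:
    """Channels with RMS above 3x the mean RMS across all channels.

    The mean includes the candidate channels themselves, so the decision
    is invariant to a global rescaling of the recording.  Pass a list of
    trials via ``pooled`` to detect once per recording on concatenated
    data.
    """
    if pooled is not None:
        data = np.concatenate([t.data for t in pooled], axis=1)
        labels = pooled[0].channel_labels
    elif isinstance(trial_or_data, EegTrial):
        data, labels = trial_or_data.data, trial_or_data.channel_labels
    else:
        data = np.asarray(trial_or_data, dtype=float)
        labels = [str(i) for i in range(data.shape[0])]
    if data.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if data.shape[1] == 0:
        raise ValueError("zero-length data")
    rms = np.sqrt(np.mean(data**2, axis=1))
    threshold = 3.0 * rms.mean()
    return {labels[i] for i in np.flatnonzero(rms > threshold)}


def _legendre_g(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin spherical-spline kernel g(cos gamma)."""
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n**stiffness * (n + 1) ** stiffness)
    out = np.zeros_like(cosang, dtype=float)
    for ni, ci in zip(n, coef):
        out += ci * eval_legendre(ni, cosang)
    return out / (4 * np.pi)


def spherical_spline_matrix(
    pos_good: np.ndarray,
    pos_bad: np.ndarray,
    stiffness: int = 4,
    n_terms: int = 50,
    reg: float = 1e-5,
) -> np.ndarray:
    """Interpolation matrix mapping good-channel values to bad channels.

    Perrin-style spherical splines with stiffness m and a Legendre-series
    kernel; the spline system is augmented with the constant term and the
    kernel Gram matrix regularized on its diagonal.
    """
    G = _legendre_g(pos_good @ pos_good.T, stiffness, n_terms)
    Gb = _legendre_g(pos_bad @ pos_good.T, stiffness, n_terms)
    k = len(pos_good)
    C = np.empty((k + 1, k + 1))
    C[:k, :k] = G + reg * np.eye(k)
    C[:k, k] = 1.0
    C[k, :k] = 1.0
    C[k, k] = 0.0
    C_inv = np.linalg.pinv(C)
    return np.hstack([Gb, np.ones((len(pos_bad), 1))]) @ C_inv[:, :k]


def spherical_interpolate(
    trial: EegTrial, bad: set[str], montage: MontagePositions
) -> EegTrial:
    """Replace bad channels by spherical-spline interpolation from the rest."""
    if not bad:
        return trial
    unknown = bad - set(trial.channel_labels)
    if unknown:
        raise ValueError(f"bad channels not in trial: {sorted(unknown)}")
    good_idx = [i for i, l in enumerate(trial.channel_labels) if l not in bad]
    bad_idx = [i for i, l in enumerate(trial.channel_labels) if l in bad]
    if len(good_idx) < 4:
        raise ValueError("spherical interpolation needs at least 4 good channels")
    mpos = montage.subset(trial.channel_labels).positions
    M = spherical_spline_matrix(mpos[good_idx], mpos[bad_idx])
    data = trial.data.copy()
    data[bad_idx] = M @ data[good_idx]
    return EegTrial(
        data=data,
        rate=trial.rate,
        channel_labels=trial.channel_labels,
        condition=trial.condition,
        trial_id=trial.trial_id,
        participant_id=trial.participant_id,
        envelope=trial.envelope,
        seed=trial.seed,
    )


def common_average_reference(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=0, keepdims=True)


def preprocess(
    trial: EegTrial,
    montage: MontagePositions | None = None,
    bad: set[str] | None = None,
    band: tuple[float, float] = (1.0, 8.0),
    filter_order_each: int = 3,
    target_rate: float = 64.0,
    artifact_hook=None,
) -> EegTrial:
    """Full per-trial pipeline; returns a new trial at ``target_rate``.

    Order: bad-channel replacement -> common-average reference ->
    optional ``artifact_hook(data, rate)`` -> zero-phase band-pass ->
    resample -> divide all channels by the mean per-channel SD ->
    common-average reference.  Synthetic data already at ``target_rate``
    skips the resampling step.
    """
    if not np.all(np.isfinite(trial.data)):
        raise ValueError("EEG data contain NaN or infinity")
    if bad is None:
        bad = detect_bad_channels(trial)
    if bad and montage is None:
        raise ValueError("montage required to interpolate bad channels")
    if bad:
        trial = spherical_interpolate(trial, bad, montage)

    data = common_average_reference(trial.data)
    if artifact_hook is not None:
        data = artifact_hook(data, trial.rate)
    data = bandpass_zero_phase(data, band, filter_order_each, trial.rate, axis=1)
    rate = trial.rate
    if rate != target_rate:
        data = resample_poly_rate(data, rate, target_rate, axis=1)
        rate = target_rate
    mean_sd = data.std(axis=1).mean()
    if mean_sd > 0:
        data = data / mean_sd
    data = common_average_reference(data)
    env = trial.envelope
    return EegTrial(
        data=data,
        rate=rate,
        channel_labels=trial.channel_labels,
        condition=trial.condition,
        trial_id=trial.trial_id,
        participant_id=trial.participant_id,
        envelope=env,
        seed=trial.seed,
    )


def preprocess_dataset(dataset, montage: MontagePositions | None = None, **kwargs):
    """Preprocess every trial; bad channels detected once, pooled over trials."""
    from .containers import EegDataset

    bad = detect_bad_channels(None, pooled=dataset.trials)
    trials = [preprocess(t, montage=montage, bad=bad, **kwargs) for t in dataset.trials]
    return EegDataset(
        trials=trials,
        channel_labels=dataset.channel_labels,
        rate=trials[0].rate,
        participant_id=dataset.participant_id,
        conditions=dataset.conditions,
        ground_truth=dataset.ground_truth,
    )
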