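"""Synthetic listeners, stimuli, and EEG with the statistical structure
the analysis pipeline assumes.

The generator produces, per simulated participant, ~1-minute trials at
five SNR conditions spaced in 2-dB steps around the (behavioral) SRT plus
a clean-speech condition, 16 trials per condition, over a 64-channel
montage.  Each EEG channel is the speech envelope convolved with an
SNR-dependent temporal response function (three Gaussian deflections:
P1, N1, P2), scaled by a smooth frontocentral topography and a logistic
listener gain, plus 1/f-shaped and white sensor noise.  A simulated
listener also answers five-word sentences through a logistic psychometric
function, which drives the behavioral staircase.

All randomness flows from one integer seed: a master generator draws one
sub-seed per generated artifact (envelope, trial, listener), and every
trial records the sub-seed it was built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .containers import CLEAN, EegDataset, EegTrial
from .envelope import EnvelopeSignal, bandpass_zero_phase
from .montage import MontagePositions, biosemi64_montage

__all__ = [
    "TrfComponent",
    "SyntheticTrfParams",
    "SimulatedListener",
    "make_envelope",
    "make_trf_kernel",
    "simulate_eeg",
    "make_dataset",
    "DEFAULT_CONDITION_OFFSETS",
]

#: Noise-condition SNR offsets (dB) relative to the behavioral SRT.
DEFAULT_CONDITION_OFFSETS = (-4.0, -2.0, 0.0, 2.0, 4.0)

#: Effective relative SNR assigned to the clean condition for the TRF
#: kernel (highest gain, shortest latencies — just above the top condition).
CLEAN_EFFECTIVE_SNR = 6.0


@dataclass(frozen=True)
class TrfComponent:
    """One Gaussian TRF deflection with linear SNR dependence.

    Latency (ms) and amplitude (a.u.) at relative SNR ``s`` are
    ``latency0 + latency_slope * s`` and ``amp0 + amp_slope * s``; the
    slopes are per dB.  Defaults follow reported mixed-model coefficients
    for envelope TRFs: latencies shorten and amplitude magnitudes grow
    with increasing SNR.
    """

    name: str
    amp0: float
    latency0: float
    width: float
    amp_slope: float
    latency_slope: float

    def amplitude(self, snr_rel: float) -> float:
        return self.amp0 + self.amp_slope * snr_rel

    def latency(self, snr_rel: float) -> float:
        return self.latency0 + self.latency_slope * snr_rel


@dataclass(frozen=True)
class SyntheticTrfParams:
    """Ground-truth TRF kernel family and topography for one simulation.

    The three components peak near 50 ms (P1, positive), 120 ms (N1,
    negative), and 200 ms (P2, positive) at the reference SNR; slope
    defaults are the per-dB coefficients −0.940/−1.517/−6.001 ms (latency)
    and 0.011/−0.015/0.018 a.u. (amplitude) for P1/N1/P2.  ``topography``
    is a unit-norm per-channel gain vector (frontocentral maximum by
    default, built from the montage geometry).
    """

    components: tuple[TrfComponent, ...] = (
        TrfComponent("P1", amp0=0.4, latency0=50.0, width=20.0, amp_slope=0.011, latency_slope=-0.940),
        TrfComponent("N1", amp0=-0.5, latency0=120.0, width=25.0, amp_slope=-0.015, latency_slope=-1.517),
        TrfComponent("P2", amp0=0.6, latency0=200.0, width=35.0, amp_slope=0.018, latency_slope=-6.001),
    )
    topography: np.ndarray | None = None
    rate: float = 64.0
    kernel_span_ms: float = 400.0

    def __post_init__(self) -> None:
        for c in self.components:
            if c.width <= 0:
                raise ValueError(f"component {c.name}: width must be positive")
        signs = {c.name: np.sign(c.amp0) for c in self.components}
        if not (signs.get("P1", 1) > 0 and signs.get("N1", -1) < 0 and signs.get("P2", 1) > 0):
            raise ValueError("P1/P2 amplitudes must be positive and N1 negative")

    def with_topography(self, montage: MontagePositions) -> "SyntheticTrfParams":
        return replace(self, topography=frontocentral_topography(montage))


def frontocentral_topography(montage: MontagePositions, spread_rad: float = 0.8) -> np.ndarray:
    """Smooth unit-norm channel gain peaking over frontocentral sites.

    The field is made zero-mean across channels (a strong frontocentral
    positive pole with a weak polarity inversion toward the rim), as an
    average-referenced scalp potential must be; this keeps the topography
    invariant under common-average re-referencing downstream.
    """
    center = np.array([0.0, 0.35, 0.94])
    center /= np.linalg.norm(center)
    ang = np.arccos(np.clip(montage.positions @ center, -1.0, 1.0))
    topo = np.exp(-((ang / spread_rad) ** 2))
    topo = topo - topo.mean()
    return topo / np.linalg.norm(topo)


@dataclass(frozen=True)
class SimulatedListener:
    """A synthetic participant.

    ``srt_true`` (dB) is the SNR at which the per-word probability of a
    correct repeat is exactly 0.5; ``word_slope`` is the logistic growth
    rate per dB of that probability.  ``gain_slope`` shapes the logistic
    neural gain g(SNR) in (0, 1] which multiplies the stimulus-driven EEG
    component; g is centered at ``srt_true`` so the informative region of
    the reconstruction-accuracy curve sits near the behavioral threshold.
    """

    srt_true: float = -5.0
    word_slope: float = 0.5
    gain_slope: float = 0.5

    def word_probability(self, snr_db: float) -> float:
        return float(expit(self.word_slope * (snr_db - self.srt_true)))

    def neural_gain(self, snr_db) -> float:
        """Monotone gain g(SNR) in (0, 1]; the clean condition has g = 1."""
        if isinstance(snr_db, str):
            if snr_db != CLEAN:
                raise ValueError(f"unknown condition {snr_db!r}")
            return 1.0
        return float(expit(self.gain_slope * (snr_db - self.srt_true)))

    def simulate_sentence_response(
        self, snr_db: float, n_words: int = 5, rng=None, seed: int | None = None
    ) -> int:
        """Words correctly repeated: Binomial(n_words, psychometric p)."""
        if n_words < 1:
            raise ValueError("n_words must be at least 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        return int(rng.binomial(n_words, self.word_probability(snr_db)))


def make_envelope(duration: float, seed: int, rate: float = 64.0) -> EnvelopeSignal:
    """A speech-like surrogate envelope: 1-8 Hz filtered Gaussian noise.

    The modulation spectrum is confined to the pass band used for real
    envelopes, peaking in the 2-6 Hz syllabic range; the output is
    mean-removed and scaled to unit variance.  Deterministic given
    ``seed``.
    """
    if duration < 10:
        raise ValueError("duration must be at least 10 s")
    rng = np.random.default_rng(seed)
    n = round(duration * rate)
    x = rng.standard_normal(n)
    env = bandpass_zero_phase(x, (1.0, 8.0), 3, rate)
    env = env - env.mean()
    env = env / env.std()
    return EnvelopeSignal(env, rate, trial_id=f"synthetic-{seed}")


def make_trf_kernel(params: SyntheticTrfParams, snr_db) -> np.ndarray:
    """Ground-truth TRF kernel over lags 0..``kernel_span_ms`` at one SNR.

    ``snr_db`` is the condition offset in dB relative to the behavioral
    SRT, or ``"clean"`` (mapped to the highest-gain, shortest-latency
    kernel).  Returns the single-channel base kernel; per-channel kernels
    are this kernel scaled by ``params.topography``.
    """
    snr_rel = CLEAN_EFFECTIVE_SNR if isinstance(snr_db, str) and snr_db == CLEAN else float(snr_db)
    lat = [c.latency(snr_rel) for c in params.components]
    if not all(a < b for a, b in zip(lat, lat[1:])):
        raise ValueError(
            f"component latency order inverted at SNR {snr_rel:+.1f} dB: {lat}"
        )
    t = np.arange(round(params.kernel_span_ms / 1000 * params.rate) + 1) / params.rate * 1000.0
    k = np.zeros_like(t)
    for c in params.components:
        k += c.amplitude(snr_rel) * np.exp(-(((t - c.latency(snr_rel)) / c.width) ** 2))
    return k


def one_over_f_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent power spectrum."""
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec /= freqs ** (exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def simulate_eeg(
    envelope: EnvelopeSignal,
    kernel: np.ndarray,
    listener: SimulatedListener,
    snr_db,
    noise_level: float = 6.0,
    seed: int = 0,
    params: SyntheticTrfParams | None = None,
    topography: np.ndarray | None = None,
) -> EegTrial:
    """Forward-simulate one EEG trial from an envelope and a TRF kernel.

    Each channel is ``g(snr) * topography[ch] * (envelope (*) kernel)``
    plus ``noise_level`` times a 90% 1/f + 10% white noise mixture (per
    channel, independent).  ``snr_db`` may be an absolute SNR in dB or
    ``"clean"``; the gain uses the listener's logistic profile.
    Deterministic given ``seed``.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    if topography is None:
        if params is not None and params.topography is not None:
            topography = params.topography
        else:
            topography = frontocentral_topography(biosemi64_montage())
    if len(kernel) > len(envelope.values):
        raise ValueError("kernel lag span exceeds the envelope duration")
    labels = biosemi64_montage().labels if len(topography) == 64 else [
        f"ch{i}" for i in range(len(topography))
    ]
    rng = np.random.default_rng(seed)
    g = listener.neural_gain(snr_db)
    driven = np.convolve(envelope.values, kernel)[: len(envelope.values)]
    data = np.outer(topography, g * driven)
    n = data.shape[1]
    if noise_level > 0:
        for ch in range(data.shape[0]):
            pink = one_over_f_noise(n, rng)
            white = rng.standard_normal(n)
            data[ch] += noise_level * (0.9 * pink + 0.1 * white)
    return EegTrial(
        data=data,
        rate=envelope.rate,
        channel_labels=labels,
        condition=snr_db,
        envelope=envelope.values.copy(),
        seed=seed,
    )


def make_dataset(
    listener: SimulatedListener,
    params: SyntheticTrfParams | None = None,
    n_trials_per_condition: int = 16,
    seed: int = 0,
    duration: float = 60.0,
    noise_level: float = 6.0,
    srt_center: float | None = None,
    condition_offsets=DEFAULT_CONDITION_OFFSETS,
    participant_id: str = "sim",
    montage: MontagePositions | None = None,
) -> EegDataset:
    """Simulate a full participant dataset: all conditions plus clean.

    Noise conditions sit at ``srt_center + condition_offsets`` (absolute
    dB); ``srt_center`` defaults to the listener's true SRT.  The TRF
    kernel of each condition uses the offset relative to ``srt_center``;
    the listener gain uses the absolute SNR.  Ground truth (parameters,
    listener, per-trial seeds) is attached to the returned dataset.
    """
    montage = montage or biosemi64_montage()
    if params is None:
        params = SyntheticTrfParams().with_topography(montage)
    elif params.topography is None:
        params = params.with_topography(montage)
    if srt_center is None:
        srt_center = listener.srt_true
    master = np.random.default_rng(seed)

    conditions: list = [srt_center + off for off in condition_offsets] + [CLEAN]
    trials = []
    for cond in conditions:
        offset = CLEAN if cond == CLEAN else float(cond) - srt_center
        kernel = make_trf_kernel(params, offset)
        for j in range(n_trials_per_condition):
            env_seed = int(master.integers(2**31))
            trial_seed = int(master.integers(2**31))
            env = make_envelope(duration, env_seed)
            trial = simulate_eeg(
                env, kernel, listener, cond, noise_level, trial_seed, params=params
            )
            trial.trial_id = f"{participant_id}-{'clean' if cond == CLEAN else f'{offset:+.0f}dB'}-{j:02d}"
            trial.participant_id = participant_id
            trials.append(trial)

    return EegDataset(
        trials=trials,
        channel_labels=montage.labels,
        rate=params.rate,
        participant_id=participant_id,
        conditions=conditions,
        ground_truth={
            "seed": seed,
            "srt_true": listener.srt_true,
            "srt_center": srt_center,
            "word_slope": listener.word_slope,
            "gain_slope": listener.gain_slope,
            "noise_level": noise_level,
            "duration": duration,
            "components": [
                {
                    "name": c.name,
                    "amp0": c.amp0,
                    "latency0": c.latency0,
                    "width": c.width,
                    "amp_slope": c.amp_slope,
                    "latency_slope": c.latency_slope,
                }
                for c in params.components
            ],
            "topography": params.topography,
        },
    )
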