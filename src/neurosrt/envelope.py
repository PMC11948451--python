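"""Broadband amplitude-envelope extraction for speech stimuli.

The acoustic feature tracked by every model in this package is the
broadband amplitude envelope of the speech signal: the magnitude of the
analytic signal (Hilbert transform), compressed with a power law to
approximate cochlear compression, band-pass filtered to the 1-8 Hz range
where cortical speech tracking is strongest, and down-sampled to a rate
matched to the EEG analysis rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "AudioTrack",
    "EnvelopeParams",
    "EnvelopeSignal",
    "spectral_match",
    "extract_envelope",
    "read_wav",
]


@dataclass
class AudioTrack:
    """A mono audio waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples (arbitrary units).
    rate : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioTrack expects a mono (1-D) sample array")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples contain NaN or infinity")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class EnvelopeParams:
    """Parameters of the envelope-extraction pipeline.

    ``compression_exponent`` is the power-law exponent applied to the
    Hilbert magnitude (0.6 approximates auditory compression).  ``band``
    is the pass band in Hz, realized as a zero-phase cascade of an
    order-``filter_order_each`` Butterworth high-pass and low-pass, each
    run forward and backward (effective band-pass order 4x
    ``filter_order_each``).  ``target_rate`` is the output rate in Hz.
    ``spectral_match_cutoff`` is the -3 dB point of the first-order
    low-pass used to match audio material spectra (Hz).
    """

    compression_exponent: float = 0.6
    band: tuple[float, float] = (1.0, 8.0)
    filter_order_each: int = 3
    target_rate: float = 64.0
    spectral_match_cutoff: float = 2000.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < self.target_rate / 2):
            raise ValueError(
                f"band must satisfy 0 < low < high < target_rate/2, got {self.band}"
            )
        if self.compression_exponent <= 0:
            raise ValueError("compression_exponent must be positive")


@dataclass
class EnvelopeSignal:
    """A processed stimulus envelope at the analysis rate.

    ``snr_db`` carries the SNR condition label of the trial the envelope
    belongs to: a float in dB (relative to the behavioral SRT) or the
    token ``"clean"``.  ``all_zero`` flags envelopes extracted from
    silent audio, for which downstream correlations are undefined.
    """

    values: np.ndarray
    rate: float
    trial_id: str | None = None
    snr_db: float | str | None = None
    all_zero: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope values contain NaN or infinity")

    def __len__(self) -> int:
        return len(self.values)


def spectral_match(track: AudioTrack, cutoff: float = 2000.0) -> AudioTrack:
    """Apply a first-order low-pass to match a target long-term spectrum.

    A single-pole Butterworth low-pass with its -3 dB point at ``cutoff``
    Hz, applied in one (causal) pass, emulating the filtering used to
    match audiobook material to the spectrum of the speech-test corpus.
    """
    if cutoff >= track.rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {track.rate / 2} Hz"
        )
    sos = signal.butter(1, cutoff, btype="low", fs=track.rate, output="sos")
    return AudioTrack(signal.sosfilt(sos, track.samples), track.rate)


def _bandpass_sos(band: tuple[float, float], order: int, fs: float) -> np.ndarray:
    """High-pass + low-pass Butterworth cascade as second-order sections."""
    hp = signal.butter(order, band[0], btype="high", fs=fs, output="sos")
    lp = signal.butter(order, band[1], btype="low", fs=fs, output="sos")
    return np.vstack([hp, lp])


def bandpass_zero_phase(
    x: np.ndarray, band: tuple[float, float], order: int, fs: float, axis: int = -1
) -> np.ndarray:
    """Zero-phase 1-8 Hz style band-pass (order-``order`` HP and LP, filtfilt).

    Reflect padding of one filter-settling length is applied at the edges
    (``sosfiltfilt`` with even-extension padding).
    """
    sos = _bandpass_sos(band, order, fs)
    return signal.sosfiltfilt(sos, x, axis=axis, padtype="even")


def resample_poly_rate(x: np.ndarray, rate_in: float, rate_out: float, axis: int = -1) -> np.ndarray:
    """Polyphase resampling (Kaiser anti-alias window) between two rates.

    The rate ratio must be rational to machine rounding; rates are
    converted to a fraction via their float ratio with limit 10^6.
    """
    if rate_in == rate_out:
        return np.asarray(x, dtype=float)
    from fractions import Fraction

    frac = Fraction(rate_out / rate_in).limit_denominator(10**6)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=axis, window=("kaiser", 5.0))


def extract_envelope(
    track: AudioTrack,
    params: EnvelopeParams | None = None,
    trial_id: str | None = None,
    snr_db: float | str | None = None,
) -> EnvelopeSignal:
    """Extract the processed broadband amplitude envelope of ``track``.

    Pipeline (order fixed): Hilbert magnitude -> power-law compression ->
    zero-phase band-pass -> polyphase resample to ``params.target_rate``.
    The output length is ``round(duration * target_rate)``.

    The band-pass removes DC, so output values may be negative; the mean
    is ~0 by construction.  All-zero audio yields an all-zero envelope
    with ``all_zero=True`` and a warning (correlations with it are
    undefined).
    """
    params = params or EnvelopeParams()
    if track.duration < 2.0:
        raise ValueError("track must be at least 2 s long for stable filtering")

    if not np.any(track.samples):
        warnings.warn("all-zero audio: envelope is identically zero", stacklevel=2)
        n_out = round(track.duration * params.target_rate)
        return EnvelopeSignal(
            np.zeros(n_out), params.target_rate, trial_id, snr_db, all_zero=True
        )

    env = np.abs(signal.hilbert(track.samples))
    env = env**params.compression_exponent
    env = bandpass_zero_phase(env, params.band, params.filter_order_each, track.rate)
    env = resample_poly_rate(env, track.rate, params.target_rate)

    n_out = round(track.duration * params.target_rate)
    if len(env) > n_out:
        env = env[:n_out]
    elif len(env) < n_out:
        env = np.pad(env, (0, n_out - len(env)))
    return EnvelopeSignal(env, params.target_rate, trial_id, snr_db)


def read_wav(path) -> AudioTrack:
    """Read a mono WAV file (PCM 16/24/32-bit or float) as an AudioTrack.

    Integer PCM is scaled to [-1, 1]; multichannel audio is averaged to
    mono.
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioTrack(data, float(rate))


def envelope_to_csv(env: EnvelopeSignal, path) -> None:
    """Write an envelope as columnar CSV with ``time_s`` and ``value``."""
    import pandas as pd

    t = np.arange(len(env.values)) / env.rate
    pd.DataFrame({"time_s": t, "value": env.values}).to_csv(path, index=False)


def psd_fraction_above(x: np.ndarray, fs: float, f_hi: float) -> float:
    """Fraction of total periodogram power above ``f_hi`` Hz (diagnostic)."""
    f, p = signal.periodogram(x, fs=fs)
    total = p.sum()
    if total == 0:
        return 0.0
    return float(p[f > f_hi].sum() / total)
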