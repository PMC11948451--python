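"""Adaptive speech-in-noise staircase (HINT-style) and behavioral SRT.

Five-word sentences are scored by words correct; the noise level for the
next sentence is moved by dL = (p_previous - p_target) * g, with the step
constant g halved after the first four sentences.  The behavioral speech
reception threshold (SRT_beh) is the mean SNR over sentences 5-40.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AdaptiveConfig", "AdaptiveTrack", "adaptive_step", "run_track", "compute_srt_beh"]


@dataclass(frozen=True)
class AdaptiveConfig:
    """Parameters of the adaptive word-scoring staircase.

    ``g_initial``/``g_final`` are the step constants (dB) before and after
    ``switch_after_sentence``; ``speech_level`` (dB SPL) is carried as
    metadata only — the speech is fixed and the noise level moves.
    """

    p_target: float = 0.5
    g_initial: float = 8.0
    g_final: float = 4.0
    switch_after_sentence: int = 4
    n_sentences: int = 40
    start_snr: float = -10.0
    words_per_sentence: int = 5
    speech_level: float = 65.0

    def __post_init__(self) -> None:
        if not 0 < self.p_target < 1:
            raise ValueError("p_target must lie in (0, 1)")
        if self.g_initial <= 0 or self.g_final <= 0:
            raise ValueError("step constants must be positive")


@dataclass
class AdaptiveTrack:
    """Per-sentence log of an adaptive run: SNR, words correct, SNR change."""

    snr_db: np.ndarray
    words_correct: np.ndarray
    snr_change: np.ndarray

    def __len__(self) -> int:
        return len(self.snr_db)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sentence": np.arange(1, len(self) + 1),
                "snr_db": self.snr_db,
                "words_correct": self.words_correct,
                "snr_change_db": self.snr_change,
            }
        )


def adaptive_step(words_correct: int, sentence_index: int, config: AdaptiveConfig | None = None) -> float:
    """SNR change (dB) applied after a sentence with ``words_correct`` repeats.

    ``sentence_index`` is 1-based.  The noise level moves by
    dL = (p_previous - p_target) * g, so the SNR changes by -dL: fewer
    words correct than the target proportion raises the SNR.
    """
    config = config or AdaptiveConfig()
    if not 0 <= words_correct <= config.words_per_sentence:
        raise ValueError(
            f"words_correct must be in [0, {config.words_per_sentence}], got {words_correct}"
        )
    if sentence_index < 1:
        raise ValueError("sentence_index is 1-based")
    g = config.g_initial if sentence_index <= config.switch_after_sentence else config.g_final
    p_previous = words_correct / config.words_per_sentence
    delta_l = (p_previous - config.p_target) * g
    return -delta_l


def run_track(listener, config: AdaptiveConfig | None = None, seed: int = 0) -> AdaptiveTrack:
    """Run the full adaptive procedure against a simulated listener.

    ``listener`` must provide ``simulate_sentence_response(snr_db, n_words,
    rng)`` (see :mod:`neurosrt.simulate`).  Deterministic given ``seed``.
    """
    config = config or AdaptiveConfig()
    rng = np.random.default_rng(seed)
    snrs = np.empty(config.n_sentences)
    words = np.empty(config.n_sentences, dtype=int)
    changes = np.empty(config.n_sentences)
    snr = config.start_snr
    for i in range(config.n_sentences):
        snrs[i] = snr
        words[i] = listener.simulate_sentence_response(
            snr, n_words=config.words_per_sentence, rng=rng
        )
        changes[i] = adaptive_step(int(words[i]), i + 1, config)
        snr = snr + changes[i]
    return AdaptiveTrack(snrs, words, changes)


def compute_srt_beh(track: AdaptiveTrack, first_sentence: int = 5) -> float:
    """Behavioral SRT: mean SNR of sentences ``first_sentence``..end.

    With the default 40-sentence track this is the mean over sentences
    5-40 (36 values).
    """
    if len(track) < first_sentence:
        raise ValueError(
            f"track has {len(track)} sentences; need at least {first_sentence}"
        )
    return float(np.mean(track.snr_db[first_sentence - 1 :]))
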