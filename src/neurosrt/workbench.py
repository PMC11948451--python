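"""End-to-end experiment orchestration over a simulated cohort.

``run_experiment`` composes every stage: simulated listeners, the
behavioral adaptive staircase (SRT_beh), synthetic EEG datasets at SNRs
placed in 2-dB steps around each listener's SRT_beh, the decoder/sigmoid
pipeline (SRT_neuro), the population-level adjacent-SNR tests, and the
forward-model TRF analysis with its mixed-model SNR effects.  A run is
fully reproducible from its configuration and master seed; every derived
seed flows from the master through one generator in a fixed order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavioral as beh
from . import simulate as sim
from .containers import CLEAN, condition_key
from .montage import biosemi64_montage
from .preprocess import preprocess_dataset
from .srt import adjacent_snr_tests, estimate_srt_neuro
from .trf import (
    encoder_significance_gate,
    fit_deflections,
    fit_encoder,
    grand_average_trf,
    lmm_snr_effects,
    select_channels,
)

__all__ = ["RunConfig", "RunSummary", "run_experiment", "report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulated experiment.

    Defaults mirror the study design: 20 listeners, 16 trials of ~1 min
    per condition at SRT_beh + {-4, -2, 0, +2, +4} dB plus clean speech.
    ``robustness_repeats`` controls how many times the sigmoid fitting
    procedure is repeated to measure its spread.
    """

    seed: int = 0
    cohort_size: int = 20
    n_trials_per_condition: int = 16
    trial_duration_s: float = 60.0
    noise_level: float = 6.0
    condition_offsets: tuple = sim.DEFAULT_CONDITION_OFFSETS
    srt_mean: float = -5.35
    srt_sd: float = 0.7
    word_slope: float = 0.5
    gain_slope: float = 0.5
    n_mismatch: int = 68
    n_restarts: int = 100
    robustness_repeats: int = 100
    n_select_channels: int = 17
    include_trf: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be at least 1")
        if self.n_trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "condition_offsets" in mapping:
            mapping = dict(mapping, condition_offsets=tuple(mapping["condition_offsets"]))
        return cls(**mapping)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["condition_offsets"] = list(self.condition_offsets)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunSummary:
    """All cohort-level outputs of one experiment run."""

    config: RunConfig
    participants: pd.DataFrame
    adjacent_tests: pd.DataFrame
    accuracies: pd.DataFrame
    deflections: pd.DataFrame | None = None
    lmm: pd.DataFrame | None = None
    grand_trf: pd.DataFrame | None = None
    selected_channels: list[str] | None = None

    def cohort_stats(self) -> dict:
        fitted = self.participants.dropna(subset=["srt_neuro"])
        diff = fitted["difference"]
        return {
            "n_participants": int(len(self.participants)),
            "n_fitted": int(len(fitted)),
            "median_srt_beh": float(self.participants["srt_beh"].median()),
            "median_srt_neuro": float(fitted["srt_neuro"].median()) if len(fitted) else None,
            "median_difference": float(diff.median()) if len(fitted) else None,
            "sd_difference": float(diff.std(ddof=1)) if len(fitted) > 1 else None,
            "fraction_within_2db": float((diff.abs() <= 2.0).mean()) if len(fitted) else None,
            "fraction_within_3db": float((diff.abs() <= 3.0).mean()) if len(fitted) else None,
        }

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "cohort": self.cohort_stats(),
            "participants": json.loads(
                self.participants.to_json(orient="records", double_precision=10)
            ),
            "adjacent_tests": json.loads(
                self.adjacent_tests.to_json(orient="records", double_precision=10)
            ),
            "lmm": None
            if self.lmm is None
            else json.loads(self.lmm.to_json(orient="records", double_precision=10)),
            "selected_channels": self.selected_channels,
        }


def run_experiment(config: RunConfig) -> RunSummary:
    """Simulate and analyze a full cohort; see the module docstring."""
    master = np.random.default_rng(config.seed)
    montage = biosemi64_montage()

    rows = []
    acc_tables = []
    datasets = []
    for i in range(config.cohort_size):
        pid = f"sim{i:02d}"
        srt_true = float(master.normal(config.srt_mean, config.srt_sd))
        listener = sim.SimulatedListener(
            srt_true=srt_true,
            word_slope=config.word_slope,
            gain_slope=config.gain_slope,
        )
        track = beh.run_track(listener, seed=int(master.integers(2**31)))
        srt_beh = beh.compute_srt_beh(track)

        dataset = sim.make_dataset(
            listener,
            n_trials_per_condition=config.n_trials_per_condition,
            seed=int(master.integers(2**31)),
            duration=config.trial_duration_s,
            noise_level=config.noise_level,
            srt_center=srt_beh,
            condition_offsets=config.condition_offsets,
            participant_id=pid,
            montage=montage,
        )
        dataset = preprocess_dataset(dataset, montage=montage)
        datasets.append(dataset)

        result = estimate_srt_neuro(
            dataset,
            seed=int(master.integers(2**31)),
            n_mismatch=config.n_mismatch,
            n_restarts=config.n_restarts,
            n_repeats=config.robustness_repeats,
            alpha=config.alpha,
            srt_center=srt_beh,
        )
        acc_tables.append(result.accuracies)
        rows.append(
            {
                "participant_id": pid,
                "srt_true": srt_true,
                "srt_beh": srt_beh,
                "srt_neuro": np.nan if result.srt_neuro is None else result.srt_neuro,
                "difference": np.nan
                if result.srt_neuro is None
                else result.srt_neuro - srt_beh,
                "error_vs_true": np.nan
                if result.srt_neuro is None
                else result.srt_neuro - srt_true,
                "gate_p": result.gate.p_value,
                "fitted": result.fitted,
                "lambda": result.best_lambda,
                "p": np.nan if result.p is None else result.p,
                "b": np.nan if result.b is None else result.b,
                "s": np.nan if result.fit is None else result.fit.s,
                "r_squared": np.nan if result.fit is None else result.fit.r_squared,
                "robustness_spread": np.nan
                if result.robustness_spread is None
                else result.robustness_spread,
            }
        )

    participants = pd.DataFrame(rows)
    accuracies = pd.concat(acc_tables, ignore_index=True)
    adjacent = (
        adjacent_snr_tests(accuracies, seed=int(master.integers(2**31)))
        if config.cohort_size >= 2
        else pd.DataFrame()
    )

    summary = RunSummary(
        config=config,
        participants=participants,
        adjacent_tests=adjacent,
        accuracies=accuracies,
    )

    if config.include_trf:
        _run_trf_stage(summary, datasets, config, master)
    return summary


def _run_trf_stage(summary: RunSummary, datasets, config: RunConfig, master) -> None:
    estimates_all = [fit_encoder(ds) for ds in datasets]
    channels = select_channels(
        estimates_all, datasets[0].channel_labels, k=config.n_select_channels
    )
    summary.selected_channels = channels
    ch_idx = [datasets[0].channel_labels.index(c) for c in channels]

    defl_rows = []
    for ds, ests in zip(datasets, estimates_all):
        gate = encoder_significance_gate(
            ests,
            ds,
            channels,
            alpha=config.alpha,
            n_mismatch=config.n_mismatch,
            seed=int(master.integers(2**31)),
        )
        srt_center = ds.ground_truth["srt_center"]
        for key, est in ests.items():
            if not gate[key]["included"]:
                continue
            mean_trf = est.kernels[ch_idx].mean(axis=0)
            fits = fit_deflections(mean_trf, est.lag_times_ms)
            is_clean = est.condition == CLEAN
            for f in fits:
                defl_rows.append(
                    {
                        "participant_id": ds.participant_id,
                        "condition": key,
                        "snr_rel": np.nan
                        if is_clean
                        else round(float(est.condition) - srt_center, 6),
                        "component": f.component,
                        "amplitude": np.nan if f.excluded else f.p,
                        "latency": np.nan if f.excluded else f.l,
                        "width": np.nan if f.excluded else f.w,
                        "r_squared": f.r_squared,
                        "excluded": f.excluded,
                    }
                )
    deflections = pd.DataFrame(defl_rows)
    summary.deflections = deflections
    noise_defl = deflections.dropna(subset=["snr_rel"]) if len(deflections) else deflections
    if len(noise_defl):
        summary.lmm = lmm_snr_effects(noise_defl, alpha=config.alpha)
    summary.grand_trf = grand_average_trf(
        estimates_all, channels, datasets[0].channel_labels
    )


def report(summary: RunSummary, out_dir: str) -> dict:
    """Write JSON and CSV outputs; returns the JSON dict.

    The JSON includes the cohort medians, the SD of the SRT_neuro -
    SRT_beh difference, and the fractions of participants within +/-2 and
    +/-3 dB.
    """
    import os

    if len(summary.participants) == 0:
        raise ValueError("empty summary: nothing to report")
    os.makedirs(out_dir, exist_ok=True)
    payload = summary.to_json_dict()
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    summary.participants.to_csv(os.path.join(out_dir, "participants.csv"), index=False)
    summary.accuracies.to_csv(os.path.join(out_dir, "accuracies.csv"), index=False)
    summary.adjacent_tests.to_csv(os.path.join(out_dir, "adjacent_tests.csv"), index=False)
    if summary.deflections is not None:
        summary.deflections.to_csv(os.path.join(out_dir, "deflections.csv"), index=False)
    if summary.lmm is not None:
        summary.lmm.to_csv(os.path.join(out_dir, "lmm_snr_effects.csv"), index=False)
    if summary.grand_trf is not None:
        summary.grand_trf.to_csv(os.path.join(out_dir, "grand_average_trf.csv"), index=False)
    return payload
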