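"""Raw EMG to 101-point gait-cycle envelopes.

The chain per trial is: 20-450 Hz band-pass -> 60 Hz band-stop ->
per-cycle SNR gating against a quiet-baseline reference -> full-wave
rectification -> 6 Hz low-pass linear envelope -> time normalization to
101 points per cycle -> averaging across surviving cycles and trials ->
amplitude normalization to the muscle's maximum of the averaged waveform.

All filters are applied forward-backward (zero phase) so envelope peak
latencies are not shifted; the stated filter orders are the design orders
before the bidirectional pass (effective order doubles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import (
    MUSCLES,
    N_CYCLE_POINTS,
    GaitEventSet,
    NormalizedEnvelope,
    RawEMGTrial,
    ValidationError,
)

logger = logging.getLogger(__name__)

BAND_LOW_HZ = 20.0
BAND_HIGH_HZ = 450.0
NOTCH_HZ = 60.0
NOTCH_Q = 30.0
ENVELOPE_CUTOFF_HZ = 6.0
SNR_THRESHOLD_DB = 18.0


class NoUsableCyclesError(RuntimeError):
    """Raised when the SNR gate leaves no surviving cycles for a muscle."""


def bandpass_20_450(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, 20-450 Hz."""
    if fs <= 2 * BAND_HIGH_HZ:
        raise ValueError(
            f"fs={fs} Hz too low: need fs > {2 * BAND_HIGH_HZ} Hz for the "
            f"{BAND_LOW_HZ}-{BAND_HIGH_HZ} Hz band"
        )
    sos = sps.butter(4, [BAND_LOW_HZ, BAND_HIGH_HZ], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def notch_60(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase second-order notch at 60 Hz (Q=30, ~2 Hz wide)."""
    if fs <= 2 * NOTCH_HZ:
        raise ValueError(f"fs={fs} Hz too low to notch {NOTCH_HZ} Hz")
    b, a = sps.iirnotch(NOTCH_HZ, NOTCH_Q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))


def snr_db(epoch: np.ndarray, noise_reference: np.ndarray) -> float:
    """SNR in dB: 20*log10(RMS(epoch) / RMS(noise_reference))."""
    epoch = np.asarray(epoch, dtype=float)
    ref = np.asarray(noise_reference, dtype=float)
    if epoch.size == 0 or ref.size == 0:
        raise ValueError("epoch and noise reference must be nonempty")
    ref_rms = float(np.sqrt(np.mean(ref**2)))
    if ref_rms == 0.0:
        raise ValueError("noise reference has zero RMS")
    epoch_rms = float(np.sqrt(np.mean(epoch**2)))
    if epoch_rms == 0.0:
        return -np.inf
    return 20.0 * np.log10(epoch_rms / ref_rms)


def gate_epochs(
    epochs: list[tuple[str, np.ndarray]],
    noise_reference: np.ndarray,
    threshold_db: float = SNR_THRESHOLD_DB,
) -> tuple[list[tuple[str, np.ndarray]], list[dict]]:
    """Drop epochs whose SNR falls below ``threshold_db``.

    The boundary is inclusive for survival: an epoch at exactly the
    threshold is retained (only epochs *below* threshold are excluded).
    Returns the surviving epochs and an exclusion log with measured SNRs.
    """
    if not np.isfinite(threshold_db) and threshold_db > 0:
        raise ValueError("threshold_db must be finite or -inf")
    survivors: list[tuple[str, np.ndarray]] = []
    exclusions: list[dict] = []
    for epoch_id, epoch in epochs:
        value = snr_db(epoch, noise_reference)
        if value >= threshold_db:
            survivors.append((epoch_id, epoch))
        else:
            exclusions.append({"epoch_id": epoch_id, "snr_db": value})
    return survivors, exclusions


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def linear_envelope(rectified: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass at 6 Hz, clipped at 0."""
    if fs <= 2 * ENVELOPE_CUTOFF_HZ:
        raise ValueError(f"fs={fs} Hz too low for a {ENVELOPE_CUTOFF_HZ} Hz low-pass")
    sos = sps.butter(2, ENVELOPE_CUTOFF_HZ, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, np.asarray(rectified, dtype=float))
    return np.clip(env, 0.0, None)


def time_normalize(
    envelope: np.ndarray,
    heel_strike: float,
    toe_off: float,
    next_heel_strike: float,
    fs: float,
    muscle: str = "",
) -> NormalizedEnvelope:
    """Resample one cycle to 101 points (0-100% at 1% increments).

    Linear interpolation over the cycle interval; the stance boundary is
    the rounded percent-of-cycle position of toe-off, clipped to [1, 99].
    """
    envelope = np.asarray(envelope, dtype=float)
    if not (heel_strike < toe_off < next_heel_strike):
        raise ValueError("events must satisfy heel_strike < toe_off < next_heel_strike")
    duration = (len(envelope) - 1) / fs
    if heel_strike < 0 or next_heel_strike > duration:
        raise ValueError(
            f"events [{heel_strike:.4f}, {next_heel_strike:.4f}]s fall outside "
            f"the signal (0-{duration:.4f}s)"
        )
    t = np.arange(len(envelope)) / fs
    grid = np.linspace(heel_strike, next_heel_strike, N_CYCLE_POINTS)
    values = np.interp(grid, t, envelope)
    stance_frac = (toe_off - heel_strike) / (next_heel_strike - heel_strike)
    boundary = int(np.clip(round(100.0 * stance_frac), 1, 99))
    return NormalizedEnvelope(
        values=np.clip(values, 0.0, None),
        stance_boundary=boundary,
        muscle=muscle,
    )


def average_and_normalize(cycles: list[NormalizedEnvelope]) -> NormalizedEnvelope:
    """Pointwise mean across cycles, then scale so the maximum equals 1.

    Per-muscle amplitude normalization uses the maximum of the *averaged*
    waveform (no MVC data available), so the normalizing waveform attains
    1.0 exactly. The stance boundary is the rounded mean across cycles.
    """
    if not cycles:
        raise ValueError("cannot average an empty cycle list")
    muscles = {c.muscle for c in cycles}
    if len(muscles) > 1:
        raise ValueError(f"cycles span multiple muscles: {sorted(muscles)}")
    stacked = np.stack([c.values for c in cycles])
    mean = stacked.mean(axis=0)
    peak = float(mean.max())
    if peak <= 0:
        raise ValueError("averaged envelope is identically zero; cannot normalize")
    boundary = int(np.clip(round(np.mean([c.stance_boundary for c in cycles])), 1, 99))
    return NormalizedEnvelope(
        values=mean / peak,
        stance_boundary=boundary,
        muscle=cycles[0].muscle,
        amplitude_scale=peak,
    )


@dataclass
class TrialResult:
    """Gated, time-normalized cycles for one trial, plus the exclusion log."""

    cycles: dict[str, list[NormalizedEnvelope]]
    exclusions: list[dict]


def process_trial(
    trial: RawEMGTrial,
    events: GaitEventSet,
    snr_threshold_db: float = SNR_THRESHOLD_DB,
) -> TrialResult:
    """Run the filter chain and per-cycle SNR gate on one trial.

    SNR is computed per cycle per muscle on the band-passed,
    notch-filtered signal against the identically filtered quiet-baseline
    reference supplied with the trial.
    """
    if trial.noise_reference is None:
        raise ValueError("trial carries no noise reference; cannot gate epochs")
    cycles: dict[str, list[NormalizedEnvelope]] = {}
    exclusions: list[dict] = []
    for muscle, raw in trial.signals.items():
        filtered = notch_60(bandpass_20_450(raw, trial.fs), trial.fs)
        ref = notch_60(bandpass_20_450(trial.noise_reference[muscle], trial.fs), trial.fs)
        envelope = linear_envelope(rectify(filtered), trial.fs)

        epochs = []
        for ci, (hs, _to, nhs) in enumerate(events.cycles()):
            i0, i1 = int(round(hs * trial.fs)), int(round(nhs * trial.fs))
            epochs.append((f"{trial.trial_id}/{muscle}/cycle{ci}", filtered[i0:i1]))
        survivors, excluded = gate_epochs(epochs, ref, snr_threshold_db)
        exclusions.extend(excluded)
        surviving_ids = {eid for eid, _ in survivors}

        kept: list[NormalizedEnvelope] = []
        for ci, (hs, to, nhs) in enumerate(events.cycles()):
            if f"{trial.trial_id}/{muscle}/cycle{ci}" not in surviving_ids:
                continue
            kept.append(time_normalize(envelope, hs, to, nhs, trial.fs, muscle=muscle))
        cycles[muscle] = kept
    return TrialResult(cycles=cycles, exclusions=exclusions)


def process_limb(
    trials: list[tuple[RawEMGTrial, GaitEventSet]],
    snr_threshold_db: float = SNR_THRESHOLD_DB,
) -> tuple[dict[str, NormalizedEnvelope], list[dict]]:
    """Average surviving cycles across a limb's trials, per muscle.

    Raises :class:`NoUsableCyclesError` if any muscle loses every cycle
    to the SNR gate.
    """
    pooled: dict[str, list[NormalizedEnvelope]] = {m: [] for m in MUSCLES}
    exclusions: list[dict] = []
    for trial, events in trials:
        result = process_trial(trial, events, snr_threshold_db)
        exclusions.extend(result.exclusions)
        for muscle, cyc in result.cycles.items():
            pooled.setdefault(muscle, []).extend(cyc)
    averaged: dict[str, NormalizedEnvelope] = {}
    for muscle, cyc in pooled.items():
        if not trials:
            raise ValidationError("no trials supplied")
        if muscle not in trials[0][0].signals:
            continue
        if not cyc:
            raise NoUsableCyclesError(
                f"no usable cycles for muscle {muscle}: all epochs fell below "
                f"the {snr_threshold_db} dB SNR gate"
            )
        averaged[muscle] = average_and_normalize(cyc)
    return averaged, exclusions
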