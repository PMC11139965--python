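"""Reproducible synthetic gait-EMG cohort generator.

Produces raw 1500 Hz 4-channel EMG trials with gait events,
temporospatial variables and PROM scores, all driven by a per-subject
latent severity in [0, 1]. The generator inverts the preprocessing chain:
each muscle's raw signal is a 20-450 Hz band-limited Gaussian carrier,
amplitude-modulated by a severity-dependent activation template, plus an
optional 60 Hz line component, a broadband noise floor, and occasional
low-SNR artifact epochs that exercise the 18 dB exclusion gate.

Severity raises gastrocnemius activity in the weight-acceptance and
swing windows (``severity_effect_g``) and raises antagonist activity
inside the agonist's active windows (``severity_effect_cci``), which is
what drives the co-contraction indices upward. Speed and stride/step
length fall with severity; cadence is severity-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import (
    MUSCLES,
    N_CYCLE_POINTS,
    VAS_MAX,
    WOMAC_ITEM_MAX,
    WOMAC_N_ITEMS,
    GaitEventSet,
    PROMRecord,
    RawEMGTrial,
    TemporospatialRecord,
    ValidationError,
)

#: RMS of the broadband in-band noise floor, relative to the signal scale.
NOISE_FLOOR_REL = 0.012
#: Factor applied to in-band signal content inside an artifact epoch;
#: drives the epoch's SNR to roughly 12 dB, safely below the 18 dB gate.
ARTIFACT_SIGNAL_SCALE = 0.1
#: Small tonic activity added to every template so modulation never hits zero.
TEMPLATE_BASELINE = 0.08


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort. All randomness flows from ``seed``."""

    n_subjects: int
    limbs_per_subject: int = 2
    trials_per_limb: int = 5
    cycles_per_trial: int = 4
    fs: float = 1500.0
    severity_effect_cci: float = 0.8
    severity_effect_g: float = 0.8
    line_noise_amp: float = 0.05
    artifact_prob: float = 0.02
    prom_noise_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "limbs_per_subject", "trials_per_limb", "cycles_per_trial"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.fs <= 900:
            raise ValidationError(f"fs must exceed 900 Hz, got {self.fs}")
        if not (0.0 <= self.artifact_prob <= 1.0):
            raise ValidationError(f"artifact_prob must lie in [0, 1], got {self.artifact_prob}")
        if self.line_noise_amp < 0:
            raise ValidationError(f"line_noise_amp must be >= 0, got {self.line_noise_amp}")
        if self.prom_noise_sd < 0:
            raise ValidationError(f"prom_noise_sd must be >= 0, got {self.prom_noise_sd}")


@dataclass
class SyntheticLimb:
    limb: str
    trials: list[tuple[RawEMGTrial, GaitEventSet]]
    temporospatial: TemporospatialRecord
    templates: dict[str, np.ndarray]
    artifact_cycles: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SyntheticSubject:
    subject_id: str
    latent_severity: float
    prom: PROMRecord
    limbs: dict[str, SyntheticLimb]


def _gauss(p: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((p - center) / width) ** 2)


def generate_activation_template(
    muscle: str,
    severity: float,
    effect_cci: float = 0.8,
    effect_g: float = 0.8,
) -> np.ndarray:
    """101-point nonnegative activation template for one muscle.

    Templates are sums of phase-localized Gaussian bumps. Severity scales
    the gastrocnemius weight-acceptance (~10%) and swing (~75%) bumps and
    the antagonist activity inside agonist windows (medial-hamstring
    midstance plateau), leaving each muscle's main bump fixed so that
    severity survives per-muscle max normalization as a shape change.
    """
    if not (0.0 <= severity <= 1.0):
        raise ValidationError(f"severity must lie in [0, 1], got {severity}")
    if muscle not in MUSCLES:
        raise ValidationError(f"unknown muscle label {muscle!r}")
    p = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    s_g = effect_g * severity
    s_c = effect_cci * severity
    if muscle == "RF":
        tpl = 1.0 * _gauss(p, 0.08, 0.06) + (0.25 + 0.15 * s_c) * _gauss(p, 0.55, 0.08)
    elif muscle == "MH":
        tpl = (
            1.0 * _gauss(p, 0.05, 0.07)
            + (0.55 + 0.30 * s_c) * _gauss(p, 0.95, 0.06)
            + (0.15 + 0.45 * s_c) * _gauss(p, 0.35, 0.12)
        )
    elif muscle == "TA":
        # constant mid-swing dorsiflexion keeps TA the higher muscle of the
        # TA-G pair throughout swing, so the pair's CCI grows with G
        tpl = (
            1.0 * _gauss(p, 0.02, 0.06)
            + 0.85 * _gauss(p, 0.97, 0.06)
            + 0.45 * _gauss(p, 0.75, 0.12)
        )
    else:  # G
        tpl = (
            1.0 * _gauss(p, 0.40, 0.10)
            + (0.20 + 0.40 * s_g) * _gauss(p, 0.10, 0.06)
            + (0.12 + 0.22 * s_g + 0.12 * s_c) * _gauss(p, 0.75, 0.09)
        )
    return tpl


def _normalized_template(muscle: str, severity: float, spec: CohortSpec) -> np.ndarray:
    """Ground-truth modulation envelope on the unit scale (max = 1)."""
    tpl = generate_activation_template(
        muscle, severity, spec.severity_effect_cci, spec.severity_effect_g
    ) + TEMPLATE_BASELINE
    return tpl / tpl.max()


def _bandlimited_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to 20-450 Hz."""
    sos = sps.butter(4, [20.0, min(450.0, 0.49 * fs)], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


def prom_from_severity(
    latent_severity: float,
    rng: np.random.Generator,
    prom_noise_sd: float = 0.12,
) -> PROMRecord:
    """Draw a PROM record whose expected scores increase with severity.

    Each WOMAC item is ``round(4 * clip(severity + noise, 0, 1))``; VAS is
    ``clip(10 * (severity + noise), 0, 10)``. With zero noise, severity 0
    maps to all-zero scores and severity 1 saturates every scale.
    """
    if not (0.0 <= latent_severity <= 1.0):
        raise ValidationError(f"latent_severity must lie in [0, 1], got {latent_severity}")
    noise = rng.normal(0.0, prom_noise_sd, size=WOMAC_N_ITEMS) if prom_noise_sd > 0 else np.zeros(WOMAC_N_ITEMS)
    levels = np.clip(latent_severity + noise, 0.0, 1.0)
    items = np.round(WOMAC_ITEM_MAX * levels).astype(int)
    vas_noise = rng.normal(0.0, prom_noise_sd) if prom_noise_sd > 0 else 0.0
    vas = float(np.clip(VAS_MAX * (latent_severity + vas_noise), 0.0, VAS_MAX))
    return PROMRecord(womac_items=items, vas=vas)


def synthesize_raw_trial(
    templates: dict[str, np.ndarray],
    spec: CohortSpec,
    rng: np.random.Generator,
    limb: str = "left",
    trial_id: str = "trial0",
    cadence: float = 112.0,
) -> tuple[RawEMGTrial, GaitEventSet, list[int]]:
    """Synthesize one raw trial and its gait events from muscle templates.

    Returns the trial, the events, and the indices of cycles into which a
    low-SNR artifact epoch was injected. The trial carries a quiet-baseline
    noise-reference segment per muscle for downstream SNR gating.
    """
    fs = spec.fs
    mean_cycle = 120.0 / cadence
    durations = mean_cycle * rng.normal(1.0, 0.02, size=spec.cycles_per_trial)
    durations = np.clip(durations, 0.6 * mean_cycle, 1.4 * mean_cycle)
    pad = 0.4
    heel_strikes = pad + np.concatenate([[0.0], np.cumsum(durations)])
    stance_frac = np.clip(rng.normal(0.60, 0.015, size=spec.cycles_per_trial), 0.55, 0.65)
    toe_offs = heel_strikes[:-1] + stance_frac * durations
    events = GaitEventSet(heel_strikes=heel_strikes, toe_offs=toe_offs)

    n = int(np.ceil((heel_strikes[-1] + pad) * fs)) + 1
    t = np.arange(n) / fs
    phase = np.full(n, np.nan)
    for i in range(spec.cycles_per_trial):
        mask = (t >= heel_strikes[i]) & (t < heel_strikes[i + 1])
        phase[mask] = (t[mask] - heel_strikes[i]) / durations[i]

    artifact_cycles = [
        i for i in range(spec.cycles_per_trial) if rng.random() < spec.artifact_prob
    ]

    pgrid = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    signals: dict[str, np.ndarray] = {}
    reference: dict[str, np.ndarray] = {}
    for muscle in templates:
        tpl = templates[muscle]
        modulation = np.full(n, TEMPLATE_BASELINE / 2)
        inside = ~np.isnan(phase)
        modulation[inside] = np.interp(phase[inside], pgrid, tpl)
        for ci in artifact_cycles:
            mask = (t >= heel_strikes[ci]) & (t < heel_strikes[ci + 1])
            modulation[mask] *= ARTIFACT_SIGNAL_SCALE
        carrier = _bandlimited_noise(n, fs, rng)
        floor = NOISE_FLOOR_REL * _bandlimited_noise(n, fs, rng)
        raw = modulation * carrier + floor
        for ci in artifact_cycles:
            mask = (t >= heel_strikes[ci]) & (t < heel_strikes[ci + 1])
            window = np.hanning(int(mask.sum()))
            raw[mask] += 1.5 * np.sin(2 * np.pi * 4.0 * (t[mask] - heel_strikes[ci])) * window
        if spec.line_noise_amp > 0:
            raw = raw + spec.line_noise_amp * np.sin(2 * np.pi * 60.0 * t)
        signals[muscle] = raw
        n_ref = int(0.5 * fs)
        reference[muscle] = NOISE_FLOOR_REL * _bandlimited_noise(n_ref, fs, rng)

    trial = RawEMGTrial(
        signals=signals, fs=fs, limb=limb, trial_id=trial_id, noise_reference=reference
    )
    return trial, events, artifact_cycles


def _temporospatial_from_severity(
    severity: float, cadence: float, rng: np.random.Generator
) -> TemporospatialRecord:
    # Speed and lengths fall with severity; cadence is severity-independent.
    stride = float(np.clip(1.25 - 0.35 * severity + rng.normal(0.0, 0.04), 0.4, 2.0))
    step = float(np.clip(stride / 2 + rng.normal(0.0, 0.02), 0.2, 1.0))
    cycle_duration = 120.0 / cadence
    speed = stride / cycle_duration
    return TemporospatialRecord(
        speed=speed, step_length=step, stride_length=stride, cadence=cadence
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate a deterministic cohort of synthetic subjects.

    Each subject draws a uniform latent severity, a PROM record linked to
    it, and per-limb raw trials whose activation templates carry the
    severity-dependent amplitude and co-contraction structure.
    """
    root = np.random.SeedSequence(spec.seed)
    subjects: list[SyntheticSubject] = []
    for si, seq in enumerate(root.spawn(spec.n_subjects)):
        rng = np.random.default_rng(seq)
        severity = float(rng.uniform(0.0, 1.0))
        prom = prom_from_severity(severity, rng, spec.prom_noise_sd)
        limbs: dict[str, SyntheticLimb] = {}
        for li in range(spec.limbs_per_subject):
            limb = ("left", "right")[li % 2] if spec.limbs_per_subject <= 2 else f"limb{li}"
            limb_severity = float(np.clip(severity + rng.normal(0.0, 0.03), 0.0, 1.0))
            templates = {
                m: _normalized_template(m, limb_severity, spec) for m in MUSCLES
            }
            cadence = float(np.clip(rng.normal(112.0, 4.0), 90.0, 130.0))
            trials = []
            artifact_log: list[tuple[int, int]] = []
            for ti in range(spec.trials_per_limb):
                trial, ev, art = synthesize_raw_trial(
                    templates,
                    spec,
                    rng,
                    limb=limb,
                    trial_id=f"s{si:03d}_{limb}_t{ti}",
                    cadence=cadence,
                )
                trials.append((trial, ev))
                artifact_log.extend((ti, ci) for ci in art)
            limbs[limb] = SyntheticLimb(
                limb=limb,
                trials=trials,
                temporospatial=_temporospatial_from_severity(limb_severity, cadence, rng),
                templates=templates,
                artifact_cycles=artifact_log,
            )
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{si:03d}",
                latent_severity=severity,
                prom=prom,
                limbs=limbs,
            )
        )
    return subjects
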