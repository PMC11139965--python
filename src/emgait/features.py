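"""Fiducial envelope features, co-contraction indices and the feature table.

The co-contraction index at each normalized time point t is

    CCI(t) = (EMG_L(t) / EMG_H(t)) * (EMG_L(t) + EMG_H(t))

where EMG_L/EMG_H are the lower/higher of the two muscle envelopes at t
(per-sample assignment, which makes the index symmetric in its inputs and
keeps the ratio <= 1). The window statistic is the arithmetic mean of
CCI(t) over the inclusive index range [t1, t2]; the variant that divides
the sum by (t2 - t1) instead of the sample count is available via
``divisor="span"``.

Windows over the 101-point cycle: full = [0, 100], stance =
[0, stance_boundary], swing = [stance_boundary, 100] (boundary shared).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CCI_PAIRS,
    MUSCLES,
    N_CYCLE_POINTS,
    GaitEventSet,
    LimbRecord,
    NormalizedEnvelope,
    TemporospatialRecord,
)

logger = logging.getLogger(__name__)

#: Window keys in canonical order: full cycle, stance phase, swing phase.
WINDOWS: tuple[str, ...] = ("", "ST", "SW")
#: Statistics computed per window.
STATS: tuple[str, ...] = ("A", "MAX", "MIN", "T_MAX", "T_MIN", "AUC")
#: Target column names appended to the feature table.
TARGET_COLUMNS: tuple[str, ...] = ("womac_total", "pain", "stiffness", "function", "vas")
#: Temporospatial column names.
TEMPOROSPATIAL_COLUMNS: tuple[str, ...] = ("speed", "step_length", "stride_length", "cadence")


@dataclass
class CCISeries:
    """Per-time-point co-contraction index for one muscle pair."""

    pair: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CYCLE_POINTS,):
            raise ValueError(f"CCI series must have {N_CYCLE_POINTS} points")


def cci_timeseries(env_a: NormalizedEnvelope, env_b: NormalizedEnvelope) -> CCISeries:
    """Pointwise co-contraction index of two envelopes (symmetric)."""
    a, b = env_a.values, env_b.values
    if a.shape != b.shape:
        raise ValueError("envelope length mismatch")
    low = np.minimum(a, b)
    high = np.maximum(a, b)
    values = np.zeros_like(low)
    active = high > 0
    values[active] = (low[active] / high[active]) * (low[active] + high[active])
    return CCISeries(pair=f"{env_a.muscle}-{env_b.muscle}", values=values)


def window_bounds(window: str, stance_boundary: int) -> tuple[int, int]:
    """Inclusive index bounds of a window key over the 101-point cycle."""
    if window == "":
        return 0, 100
    if window == "ST":
        return 0, int(stance_boundary)
    if window == "SW":
        return int(stance_boundary), 100
    raise ValueError(f"unknown window {window!r}; expected '', 'ST' or 'SW'")


def cci_window(
    series: CCISeries, t1: int, t2: int, divisor: str = "count"
) -> float:
    """Window co-contraction statistic over the inclusive range [t1, t2].

    ``divisor="count"`` (default) averages over the t2 - t1 + 1 included
    samples; ``divisor="span"`` divides the sum by t2 - t1 instead.
    """
    if not (0 <= t1 < t2 <= 100):
        raise ValueError(f"window bounds must satisfy 0 <= t1 < t2 <= 100, got ({t1}, {t2})")
    chunk = series.values[t1 : t2 + 1]
    total = float(chunk.sum())
    if divisor == "count":
        return total / (t2 - t1 + 1)
    if divisor == "span":
        return total / (t2 - t1)
    raise ValueError(f"unknown divisor {divisor!r}")


def fiducial_features(values: np.ndarray, t1: int, t2: int) -> dict[str, float]:
    """Window statistics of an envelope: mean, extrema, latencies, AUC.

    Latencies (``T_MAX``/``T_MIN``) are the percent-of-full-cycle index of
    the first occurrence of the window extremum; ``AUC`` is the trapezoidal
    integral over the window in amplitude x percent-cycle units.
    """
    values = np.asarray(values, dtype=float)
    if t2 - t1 < 1:
        raise ValueError(f"degenerate window ({t1}, {t2}): needs at least 2 points")
    chunk = values[t1 : t2 + 1]
    return {
        "A": float(chunk.mean()),
        "MAX": float(chunk.max()),
        "MIN": float(chunk.min()),
        "T_MAX": float(t1 + int(np.argmax(chunk))),
        "T_MIN": float(t1 + int(np.argmin(chunk))),
        "AUC": float(np.trapezoid(chunk)),
    }


def envelope_features(env: NormalizedEnvelope, window: str = "") -> dict[str, float]:
    """Fiducial statistics of one envelope over a named window
    ('' = full cycle, 'ST' = stance, 'SW' = swing), with the window bounds
    resolved from the envelope's stance boundary."""
    t1, t2 = window_bounds(window, env.stance_boundary)
    return fiducial_features(env.values, t1, t2)


def temporospatial_features(
    events: GaitEventSet,
    stride_length_m: float,
    step_length_m: float,
) -> TemporospatialRecord:
    """Cadence and speed from event timing; lengths are passed through.

    Cadence = 120 / mean cycle duration (steps/min, two steps per cycle);
    speed = stride length / mean cycle duration.
    """
    if len(events.heel_strikes) < 2:
        raise ValueError("need at least two heel strikes")
    mean_duration = float(np.mean(np.diff(events.heel_strikes)))
    return TemporospatialRecord(
        speed=stride_length_m / mean_duration,
        step_length=step_length_m,
        stride_length=stride_length_m,
        cadence=120.0 / mean_duration,
    )


def feature_name(base: str, window: str, stat: str) -> str:
    parts = [base] + ([window] if window else []) + [stat]
    return "_".join(parts)


def feature_columns() -> list[str]:
    """Deterministic feature column order for the limb-level table."""
    cols: list[str] = []
    for m in MUSCLES:
        for w in WINDOWS:
            for s in STATS:
                cols.append(feature_name(m, w, s))
    for a, b in CCI_PAIRS:
        for w in WINDOWS:
            for s in STATS:
                cols.append(feature_name(f"CCI_{a}-{b}", w, s))
    cols.extend(TEMPOROSPATIAL_COLUMNS)
    return cols


def limb_features(
    envelopes: dict[str, NormalizedEnvelope],
    temporospatial: TemporospatialRecord,
    divisor: str = "count",
) -> dict[str, float]:
    """Feature vector for one limb from its averaged envelopes."""
    missing = [m for m in MUSCLES if m not in envelopes]
    if missing:
        raise KeyError(f"missing muscles: {missing}")
    boundary = int(round(np.mean([envelopes[m].stance_boundary for m in MUSCLES])))
    row: dict[str, float] = {}
    for m in MUSCLES:
        for w in WINDOWS:
            t1, t2 = window_bounds(w, boundary)
            for s, v in fiducial_features(envelopes[m].values, t1, t2).items():
                row[feature_name(m, w, s)] = v
    for a, b in CCI_PAIRS:
        series = cci_timeseries(envelopes[a], envelopes[b])
        for w in WINDOWS:
            t1, t2 = window_bounds(w, boundary)
            stats = fiducial_features(series.values, t1, t2)
            stats["A"] = cci_window(series, t1, t2, divisor=divisor)
            for s, v in stats.items():
                row[feature_name(f"CCI_{a}-{b}", w, s)] = v
    row["speed"] = temporospatial.speed
    row["step_length"] = temporospatial.step_length
    row["stride_length"] = temporospatial.stride_length
    row["cadence"] = temporospatial.cadence
    return row


def build_feature_table(records: list[LimbRecord], divisor: str = "count") -> pd.DataFrame:
    """Assemble the limb-level feature table (one row per limb).

    Limbs missing a muscle are skipped with a logged warning. Columns are
    id columns, EMG/CCI features, temporospatial variables, then PROM
    targets, in a deterministic order independent of input dict order.
    """
    cols = feature_columns()
    rows = []
    for rec in records:
        try:
            row = limb_features(rec.envelopes, rec.temporospatial, divisor=divisor)
        except KeyError as exc:
            logger.warning("skipping limb %s/%s: %s", rec.subject_id, rec.limb, exc)
            continue
        row = {c: row[c] for c in cols}
        row["subject_id"] = rec.subject_id
        row["limb"] = rec.limb
        row["womac_total"] = rec.prom.total
        row["pain"] = rec.prom.pain
        row["stiffness"] = rec.prom.stiffness
        row["function"] = rec.prom.function
        row["vas"] = rec.prom.vas
        if rec.latent_severity is not None:
            row["latent_severity"] = rec.latent_severity
        rows.append(row)
    ordered = ["subject_id", "limb"] + cols + list(TARGET_COLUMNS)
    if rows and "latent_severity" in rows[0]:
        ordered.append("latent_severity")
    return pd.DataFrame(rows, columns=ordered)


def emg_feature_columns(table: pd.DataFrame) -> list[str]:
    """EMG-derived feature columns of a feature table (no temporospatial)."""
    skip = set(("subject_id", "limb", "latent_severity"))
    skip.update(TARGET_COLUMNS)
    skip.update(TEMPOROSPATIAL_COLUMNS)
    return [c for c in table.columns if c not in skip]
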