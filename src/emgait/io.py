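"""CSV/JSON readers and writers for every pipeline artifact.

All files are comma-separated UTF-8 with a mandatory header row and '.'
decimals, independent of locale. Schema violations raise
:class:`SchemaError` naming the missing/extra columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MUSCLES,
    N_CYCLE_POINTS,
    GaitEventSet,
    NormalizedEnvelope,
    PROMRecord,
    RawEMGTrial,
    TemporospatialRecord,
)

TRIAL_COLUMNS = ["time_s", *MUSCLES]
EVENT_COLUMNS = ["cycle_index", "heel_strike_s", "toe_off_s", "next_heel_strike_s"]
TS_COLUMNS = ["subject_id", "limb", "speed", "step_length", "stride_length", "cadence"]
PROM_COLUMNS = ["subject_id", *[f"item{i:02d}" for i in range(1, 25)], "vas"]


class SchemaError(ValueError):
    """A CSV file does not match its documented header."""


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; extra {extra}")


def write_trial_csv(path, trial: RawEMGTrial) -> None:
    t = np.arange(trial.n_samples) / trial.fs
    df = pd.DataFrame({"time_s": t})
    for m in MUSCLES:
        if m in trial.signals:
            df[m] = trial.signals[m]
    df.to_csv(path, index=False)


def read_trial_csv(path, fs: float | None = None, limb: str = "left", trial_id: str | None = None) -> RawEMGTrial:
    df = pd.read_csv(path)
    _check_columns(df, TRIAL_COLUMNS, path)
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    return RawEMGTrial(
        signals={m: df[m].to_numpy(dtype=float) for m in MUSCLES},
        fs=fs,
        limb=limb,
        trial_id=trial_id or Path(path).stem,
    )


def write_events_csv(path, events: GaitEventSet) -> None:
    rows = [
        {"cycle_index": i, "heel_strike_s": hs, "toe_off_s": to, "next_heel_strike_s": nhs}
        for i, (hs, to, nhs) in enumerate(events.cycles())
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path) -> GaitEventSet:
    df = pd.read_csv(path)
    _check_columns(df, EVENT_COLUMNS, path)
    hs = df["heel_strike_s"].to_numpy(dtype=float)
    heel_strikes = np.append(hs, df["next_heel_strike_s"].iloc[-1])
    return GaitEventSet(heel_strikes=heel_strikes, toe_offs=df["toe_off_s"].to_numpy(dtype=float))


def write_reference_csv(path, reference: dict[str, np.ndarray]) -> None:
    pd.DataFrame({m: reference[m] for m in MUSCLES if m in reference}).to_csv(path, index=False)


def read_reference_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {m: df[m].to_numpy(dtype=float) for m in df.columns}


def write_envelope_csv(path, envelopes: dict[str, NormalizedEnvelope]) -> None:
    """Per-limb envelope CSV: 101 rows of (pct, RF, MH, TA, G) plus a
    stance_boundary column (constant per muscle, stored wide)."""
    df = pd.DataFrame({"pct": np.arange(N_CYCLE_POINTS)})
    for m in MUSCLES:
        if m in envelopes:
            df[m] = envelopes[m].values
            df[f"{m}_stance_boundary"] = envelopes[m].stance_boundary
    df.to_csv(path, index=False)


def read_envelope_csv(path) -> dict[str, NormalizedEnvelope]:
    df = pd.read_csv(path)
    if len(df) != N_CYCLE_POINTS:
        raise SchemaError(f"{path}: expected {N_CYCLE_POINTS} rows, got {len(df)}")
    out = {}
    for m in MUSCLES:
        if m not in df.columns:
            raise SchemaError(f"{path}: missing column(s) ['{m}']")
        out[m] = NormalizedEnvelope(
            values=df[m].to_numpy(dtype=float),
            stance_boundary=int(df[f"{m}_stance_boundary"].iloc[0]),
            muscle=m,
        )
    return out


def write_prom_csv(path, records: list[tuple[str, PROMRecord]]) -> None:
    rows = []
    for subject_id, prom in records:
        row = {"subject_id": subject_id}
        row.update({f"item{i + 1:02d}": int(v) for i, v in enumerate(prom.womac_items)})
        row["vas"] = prom.vas
        rows.append(row)
    pd.DataFrame(rows, columns=PROM_COLUMNS).to_csv(path, index=False)


def read_prom_csv(path) -> list[tuple[str, PROMRecord]]:
    df = pd.read_csv(path)
    _check_columns(df, PROM_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        items = np.array([row[f"item{i:02d}"] for i in range(1, 25)], dtype=int)
        out.append((str(row["subject_id"]), PROMRecord(womac_items=items, vas=float(row["vas"]))))
    return out


def write_temporospatial_csv(path, records: list[tuple[str, str, TemporospatialRecord]]) -> None:
    rows = [
        {
            "subject_id": sid,
            "limb": limb,
            "speed": ts.speed,
            "step_length": ts.step_length,
            "stride_length": ts.stride_length,
            "cadence": ts.cadence,
        }
        for sid, limb, ts in records
    ]
    pd.DataFrame(rows, columns=TS_COLUMNS).to_csv(path, index=False)


def read_temporospatial_csv(path) -> list[tuple[str, str, TemporospatialRecord]]:
    df = pd.read_csv(path)
    _check_columns(df, TS_COLUMNS, path)
    return [
        (
            str(r["subject_id"]),
            str(r["limb"]),
            TemporospatialRecord(
                speed=float(r["speed"]),
                step_length=float(r["step_length"]),
                stride_length=float(r["stride_length"]),
                cadence=float(r["cadence"]),
            ),
        )
        for _, r in df.iterrows()
    ]


def write_feature_table(path, table: pd.DataFrame, sidecar: dict | None = None) -> None:
    table.to_csv(path, index=False)
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
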