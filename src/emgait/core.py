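"""Shared domain types for the EMG gait analysis pipeline.

All stages exchange a small set of dataclasses: raw multi-channel EMG
trials, gait event sets delimiting cycles, 101-point time-normalized
envelopes, and patient-reported outcome (PROM) records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Recorded lower-extremity muscles, in canonical column order.
MUSCLES: tuple[str, ...] = ("RF", "MH", "TA", "G")

#: Muscle pairs for which a co-contraction index is computed.
CCI_PAIRS: tuple[tuple[str, str], ...] = (
    ("TA", "G"),
    ("RF", "MH"),
    ("TA", "MH"),
    ("RF", "G"),
)

#: Number of samples in a time-normalized gait-cycle envelope
#: (0-100% of the cycle at 1% increments, inclusive of both ends).
N_CYCLE_POINTS: int = 101

#: WOMAC item counts per subscale: pain, stiffness, physical function.
WOMAC_SUBSCALES: dict[str, int] = {"pain": 5, "stiffness": 2, "function": 17}
WOMAC_N_ITEMS: int = 24
WOMAC_ITEM_MAX: int = 4
VAS_MAX: float = 10.0


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class GaitEventSet:
    """Heel-strike and toe-off times (seconds) delimiting gait cycles.

    ``heel_strikes`` has one entry more than ``toe_offs``: cycle *i* spans
    ``heel_strikes[i]`` to ``heel_strikes[i + 1]`` and contains
    ``toe_offs[i]`` strictly inside it.
    """

    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=float)
        self.toe_offs = np.asarray(self.toe_offs, dtype=float)
        if self.heel_strikes.ndim != 1 or self.toe_offs.ndim != 1:
            raise ValidationError("event arrays must be one-dimensional")
        if len(self.heel_strikes) != len(self.toe_offs) + 1:
            raise ValidationError(
                "expected len(heel_strikes) == len(toe_offs) + 1, got "
                f"{len(self.heel_strikes)} and {len(self.toe_offs)}"
            )
        if np.any(np.diff(self.heel_strikes) <= 0):
            raise ValidationError("heel strikes must be strictly increasing")
        for i, to in enumerate(self.toe_offs):
            if not (self.heel_strikes[i] < to < self.heel_strikes[i + 1]):
                raise ValidationError(
                    f"toe-off {i} ({to:.4f}s) not strictly inside its cycle"
                )

    @property
    def n_cycles(self) -> int:
        return len(self.toe_offs)

    def cycles(self) -> Iterator[tuple[float, float, float]]:
        """Yield (heel_strike, toe_off, next_heel_strike) per cycle."""
        for i in range(self.n_cycles):
            yield (
                float(self.heel_strikes[i]),
                float(self.toe_offs[i]),
                float(self.heel_strikes[i + 1]),
            )


@dataclass
class RawEMGTrial:
    """Raw multi-channel EMG for one walking trial of one limb.

    ``noise_reference`` holds a per-muscle quiet-baseline segment recorded
    with the same gain, used downstream as the denominator of the SNR gate.
    """

    signals: dict[str, np.ndarray]
    fs: float
    limb: str
    trial_id: str
    noise_reference: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 900:
            raise ValidationError(
                f"fs must exceed 900 Hz (twice the 450 Hz band edge), got {self.fs}"
            )
        self.signals = {m: np.asarray(x, dtype=float) for m, x in self.signals.items()}
        lengths = {len(x) for x in self.signals.values()}
        if len(lengths) > 1:
            raise ValidationError(f"channels have unequal lengths: {sorted(lengths)}")
        for m in self.signals:
            if m not in MUSCLES:
                raise ValidationError(f"unknown muscle label {m!r}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class NormalizedEnvelope:
    """101-point envelope of one muscle over one gait cycle (0-100%).

    ``stance_boundary`` is the percent-of-cycle index of toe-off;
    ``amplitude_scale`` records the divisor applied during amplitude
    normalization (1.0 when not yet normalized).
    """

    values: np.ndarray
    stance_boundary: int
    muscle: str
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CYCLE_POINTS,):
            raise ValidationError(
                f"envelope must have exactly {N_CYCLE_POINTS} points, "
                f"got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValidationError("envelope values must be nonnegative")
        sb = int(self.stance_boundary)
        if not (1 <= sb <= 99):
            raise ValidationError(f"stance_boundary must lie in [1, 99], got {sb}")
        self.stance_boundary = sb


@dataclass
class PROMRecord:
    """One subject's patient-reported outcomes.

    24 WOMAC items (5 pain, 2 stiffness, 17 physical function), each an
    integer in 0..4, plus a 0-10 VAS pain rating.
    """

    womac_items: np.ndarray
    vas: float

    def __post_init__(self) -> None:
        items = np.asarray(self.womac_items)
        if items.shape != (WOMAC_N_ITEMS,):
            raise ValidationError(
                f"expected {WOMAC_N_ITEMS} WOMAC items, got shape {items.shape}"
            )
        if not np.all((items >= 0) & (items <= WOMAC_ITEM_MAX)):
            raise ValidationError("WOMAC items must lie in 0..4")
        if np.any(items != np.round(items)):
            raise ValidationError("WOMAC items must be integers")
        self.womac_items = items.astype(int)
        if not (0.0 <= self.vas <= VAS_MAX):
            raise ValidationError(f"VAS must lie in [0, {VAS_MAX}], got {self.vas}")

    @property
    def pain(self) -> int:
        return int(self.womac_items[:5].sum())

    @property
    def stiffness(self) -> int:
        return int(self.womac_items[5:7].sum())

    @property
    def function(self) -> int:
        return int(self.womac_items[7:].sum())

    @property
    def total(self) -> int:
        return int(self.womac_items.sum())


@dataclass
class TemporospatialRecord:
    """Temporospatial gait variables for one limb."""

    speed: float
    step_length: float
    stride_length: float
    cadence: float


@dataclass
class LimbRecord:
    """Per-limb analysis row: averaged envelopes plus covariates/targets."""

    subject_id: str
    limb: str
    envelopes: dict[str, NormalizedEnvelope]
    temporospatial: TemporospatialRecord
    prom: PROMRecord
    latent_severity: float | None = None
    excluded_epochs: list[dict] = field(default_factory=list)
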