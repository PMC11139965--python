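"""PROM scoring, midpoint-rule severity categorization and group statistics.

WOMAC: 24 items (5 pain, 2 stiffness, 17 physical function), each 0-4.
Severity cut-offs come from the midpoints of the per-item scale between
mild/moderate (1.5) and moderate/severe (2.5), multiplied by the item
count: (36, 60) for the 24-item total. Scores strictly below the lower
cut-off are mild, strictly above the upper cut-off severe, and the closed
interval in between moderate. The same midpoint fractions (1.5/4, 2.5/4)
rescaled to the 0-10 VAS give cut-offs (3.75, 6.25) — an implementation
default, since no printed VAS cut-offs exist.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .core import (
    VAS_MAX,
    WOMAC_ITEM_MAX,
    WOMAC_N_ITEMS,
    WOMAC_SUBSCALES,
    ValidationError,
)

SEVERITY_LABELS: tuple[str, ...] = ("mild", "moderate", "severe")

#: Per-item midpoints of the 0-4 scale between adjacent severity levels.
ITEM_MIDPOINT_LOW = 1.5
ITEM_MIDPOINT_HIGH = 2.5

#: Default VAS cut-offs: item midpoints / 4, rescaled to the 0-10 scale.
VAS_CUTOFFS: tuple[float, float] = (
    ITEM_MIDPOINT_LOW / WOMAC_ITEM_MAX * VAS_MAX,
    ITEM_MIDPOINT_HIGH / WOMAC_ITEM_MAX * VAS_MAX,
)

WomacScores = namedtuple("WomacScores", ["pain", "stiffness", "function", "total"])


def womac_scores(items) -> WomacScores:
    """Subscale sums and total of 24 WOMAC items (5 pain, 2 stiff, 17 func)."""
    items = np.asarray(items)
    if items.shape != (WOMAC_N_ITEMS,):
        raise ValidationError(f"expected {WOMAC_N_ITEMS} items, got shape {items.shape}")
    if not np.all((items >= 0) & (items <= WOMAC_ITEM_MAX)):
        bad = items[(items < 0) | (items > WOMAC_ITEM_MAX)]
        raise ValidationError(f"items out of 0..{WOMAC_ITEM_MAX}: {bad.tolist()}")
    pain = int(items[:5].sum())
    stiffness = int(items[5:7].sum())
    function = int(items[7:].sum())
    return WomacScores(pain, stiffness, function, pain + stiffness + function)


def midpoint_cutoffs(n_items: int) -> tuple[float, float]:
    """Severity cut-offs for an n-item scale: (1.5 * n, 2.5 * n)."""
    if n_items < 1:
        raise ValidationError(f"n_items must be >= 1, got {n_items}")
    return ITEM_MIDPOINT_LOW * n_items, ITEM_MIDPOINT_HIGH * n_items


def categorize(score: float, low: float, high: float) -> str:
    """Three-way severity: below ``low`` mild, above ``high`` severe,
    the closed interval [low, high] moderate."""
    if not low < high:
        raise ValidationError(f"require low < high, got ({low}, {high})")
    if score < low:
        return "mild"
    if score > high:
        return "severe"
    return "moderate"


def categorize_womac_total(total: float) -> str:
    low, high = midpoint_cutoffs(WOMAC_N_ITEMS)
    return categorize(total, low, high)


def categorize_subscale(score: float, subscale: str) -> str:
    if subscale not in WOMAC_SUBSCALES:
        raise ValidationError(f"unknown subscale {subscale!r}")
    low, high = midpoint_cutoffs(WOMAC_SUBSCALES[subscale])
    return categorize(score, low, high)


def categorize_vas(vas: float) -> str:
    if not (0.0 <= vas <= VAS_MAX):
        raise ValidationError(f"VAS must lie in [0, {VAS_MAX}], got {vas}")
    return categorize(vas, *VAS_CUTOFFS)


def group_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across severity groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least two observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical: ANOVA undefined")
    f, p = spstats.f_oneway(*arrays)
    return float(f), float(p)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided t-test between two severity groups (Welch by default)."""
    t, p = spstats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)


def ensemble_waveform(
    groups: dict[str, list[np.ndarray]]
) -> dict[str, dict[str, np.ndarray]]:
    """Per-group pointwise mean and 95% CI (mean +/- 1.96 SE) of envelopes.

    Empty groups are skipped. Each returned entry has keys ``mean``,
    ``lo``, ``hi`` and ``n``.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for label, members in groups.items():
        if len(members) == 0:
            continue
        stacked = np.stack([np.asarray(m, dtype=float) for m in members])
        mean = stacked.mean(axis=0)
        n = stacked.shape[0]
        se = stacked.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(stacked.shape[1])
        out[label] = {"mean": mean, "lo": mean - 1.96 * se, "hi": mean + 1.96 * se, "n": n}
    return out


def label_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append severity class columns for every PROM scale of a feature table."""
    out = table.copy()
    out["class_womac_total"] = out["womac_total"].map(categorize_womac_total)
    for sub in WOMAC_SUBSCALES:
        out[f"class_{sub}"] = out[sub].map(lambda s, sub=sub: categorize_subscale(s, sub))
    out["class_vas"] = out["vas"].map(categorize_vas)
    return out


def group_summary(
    table: pd.DataFrame,
    feature_cols: list[str],
    class_col: str = "class_womac_total",
) -> pd.DataFrame:
    """Per-class mean (sd) of features plus the one-way ANOVA p-value."""
    rows = []
    for col in feature_cols:
        groups = [
            table.loc[table[class_col] == label, col].to_numpy(dtype=float)
            for label in SEVERITY_LABELS
        ]
        present = [g for g in groups if len(g) >= 2]
        try:
            _, p = group_anova(present)
        except ValueError:
            p = np.nan
        row = {"feature": col, "p_value": p}
        for label, g in zip(SEVERITY_LABELS, groups):
            row[f"{label}_mean"] = float(np.mean(g)) if len(g) else np.nan
            row[f"{label}_sd"] = float(np.std(g, ddof=1)) if len(g) > 1 else np.nan
            row[f"{label}_n"] = len(g)
        rows.append(row)
    return pd.DataFrame(rows)
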