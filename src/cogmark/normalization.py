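"""Age-windowed normative z-scores against the online control sample.

Multi-visit rows are averaged per participant first. Each raw metric value is
then expressed as the number of SDs from the mean of normative participants
within ±3 years of the subject's age (inclusive). The raw metric direction is
preserved: error-type metrics yield positive z when performance is worse.

Reference members are normalized leave-one-out against their own group so a
participant never standardizes against themselves; everyone else uses the full
age window. Cells whose window holds fewer than ``n_min`` reference members
(or zero reference SD) are missing, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_WINDOW_YEARS = 3.0
DEFAULT_N_MIN = 20


def average_visits(metric_rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse to one row per participant: cell-wise mean of numeric columns
    ignoring missing values; identity columns (group, sex) take the first visit."""
    if "participant_id" not in metric_rows.columns:
        raise ValueError("metric_rows must have a participant_id column")
    numeric = metric_rows.select_dtypes(include="number").columns.difference(["visit"])
    other = [
        c
        for c in metric_rows.columns
        if c not in numeric and c not in ("participant_id", "visit")
    ]
    grouped = metric_rows.groupby("participant_id", sort=False)
    out = grouped[list(numeric)].mean()
    for c in other:
        out[c] = grouped[c].first()
    return out.reset_index()[
        ["participant_id"] + other + [c for c in metric_rows.columns if c in numeric]
    ]


@dataclass
class NormativeTable:
    """Per-metric (age, value) reference pairs with the contributing ids."""

    ages: np.ndarray
    ids: np.ndarray
    values: dict[str, np.ndarray]

    @classmethod
    def from_frame(cls, reference: pd.DataFrame, metrics: list[str]) -> "NormativeTable":
        return cls(
            ages=reference["age"].to_numpy(float),
            ids=reference["participant_id"].to_numpy(),
            values={m: reference[m].to_numpy(float) for m in metrics},
        )


def zscore(
    value: float,
    age: float,
    metric_values: np.ndarray,
    reference_ages: np.ndarray,
    window: float = DEFAULT_WINDOW_YEARS,
    n_min: int = DEFAULT_N_MIN,
    exclude: np.ndarray | None = None,
) -> tuple[float, int]:
    """z = (value - mean(ref)) / sd(ref) over reference members with
    |ref_age - age| <= window; sd uses the n-1 denominator.

    Returns (z, n_reference); z is NaN when the value is missing, the window
    holds fewer than ``n_min`` usable members, or the reference SD is zero.
    ``exclude`` is a boolean mask of reference rows to drop (leave-one-out).
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan"), 0
    mask = np.abs(reference_ages - age) <= window
    if exclude is not None:
        mask &= ~exclude
    vals = metric_values[mask]
    vals = vals[~np.isnan(vals)]
    n = len(vals)
    if n < n_min:
        return float("nan"), n
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        return float("nan"), n
    return (float(value) - float(np.mean(vals))) / sd, n


def build_zscore_table(
    table: pd.DataFrame,
    reference: pd.DataFrame,
    metrics: list[str],
    window: float = DEFAULT_WINDOW_YEARS,
    n_min: int = DEFAULT_N_MIN,
) -> pd.DataFrame:
    """Standardize every metric column of ``table`` against ``reference``.

    Both frames need ``participant_id`` and ``age`` columns. Rows whose
    participant_id appears in the reference are scored leave-one-out. Output
    keeps the identity columns and adds one ``"<metric> (z)"`` column each.
    """
    norm = NormativeTable.from_frame(reference, metrics)
    id_cols = [c for c in ("participant_id", "group", "age", "sex", "education_years") if c in table.columns]
    out = table[id_cols].copy()
    for m in metrics:
        zs = []
        for _, row in table.iterrows():
            exclude = norm.ids == row["participant_id"]
            z, _ = zscore(
                row[m],
                row["age"],
                norm.values[m],
                norm.ages,
                window=window,
                n_min=n_min,
                exclude=exclude if exclude.any() else None,
            )
            zs.append(z)
        out[f"{m} (z)"] = zs
    return out
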