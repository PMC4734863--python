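"""Test-day records: file dialect, edit rules, residual classes, summaries.

Records live in a pandas DataFrame with columns
``cow, herd, test_date, parity, age_months, freq, dim, milk``:
one row per daily milk-yield measurement, with the cow's herd, calendar
test date, parity (1 or 2), age at calving in months, milking-frequency
group (3X or 4X), days in milk and yield in kg.

The edit rules mirror routine milk-recording practice: keep DIM 5–305,
yields 1–70 kg, cows calving first at 20–36 months, and cows with 4–10
usable records per parity × frequency group.  Residual variance is treated
as heterogeneous over ten 30-day DIM classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["cow", "herd", "test_date", "parity", "age_months", "freq", "dim", "milk"]

#: order in which edit rules claim a removed record
EDIT_RULES = ("dim_window", "milk_range", "age_at_first_calving", "record_count")

DIM_MIN, DIM_MAX = 5, 305
MILK_MIN, MILK_MAX = 1.0, 70.0
AGE_MIN, AGE_MAX = 20.0, 36.0
COUNT_MIN, COUNT_MAX = 4, 10

N_RESIDUAL_CLASSES = 10


@dataclass
class EditReport:
    """Record counts removed per rule (first-violated-rule attribution)."""

    n_input: int
    n_removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    def __post_init__(self):
        for rule in EDIT_RULES:
            self.n_removed_by_rule.setdefault(rule, 0)
        assert self.n_input == self.n_retained + sum(self.n_removed_by_rule.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed:{r}", self.n_removed_by_rule[r]) for r in EDIT_RULES]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["item", "records"])


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"cow": str, "herd": str, "test_date": str, "freq": str},
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"test-day CSV missing columns {missing}")
    df = df[COLUMNS].copy()
    df["parity"] = df["parity"].astype(int)
    df["dim"] = df["dim"].astype(int)
    bad = set(df["freq"].unique()) - {"3X", "4X"}
    if bad:
        raise ValueError(f"freq must be 3X or 4X, got {sorted(bad)}")
    return df


def write_records_csv(df: pd.DataFrame, path) -> None:
    df[COLUMNS].to_csv(path, index=False)


def apply_edits(records: pd.DataFrame) -> tuple[pd.DataFrame, EditReport]:
    """Apply the edit rules; removed records are attributed to the first
    rule they violate, in :data:`EDIT_RULES` order.

    Record-level filters (DIM window, yield range) run before the cow-level
    count rule, so the count rule sees post-filter record counts.  The age
    rule removes every record of a cow whose age at first calving (its
    parity-1 ``age_months``) is outside 20–36 months; cows with no parity-1
    records are not judged by it.  The count rule operates within
    parity × frequency group.
    """
    df = records.copy()
    removed = dict.fromkeys(EDIT_RULES, 0)
    n_input = len(df)
    if n_input == 0:
        return df, EditReport(0, removed, 0)

    bad_dim = (df["dim"] < DIM_MIN) | (df["dim"] > DIM_MAX)
    removed["dim_window"] = int(bad_dim.sum())
    df = df[~bad_dim]

    bad_milk = (df["milk"] < MILK_MIN) | (df["milk"] > MILK_MAX)
    removed["milk_range"] = int(bad_milk.sum())
    df = df[~bad_milk]

    first = df[df["parity"] == 1].groupby("cow")["age_months"].first()
    bad_cows = set(first[(first < AGE_MIN) | (first > AGE_MAX)].index)
    bad_age = df["cow"].isin(bad_cows)
    removed["age_at_first_calving"] = int(bad_age.sum())
    df = df[~bad_age]

    counts = df.groupby(["cow", "parity", "freq"])["milk"].transform("size")
    bad_count = (counts < COUNT_MIN) | (counts > COUNT_MAX)
    removed["record_count"] = int(bad_count.sum())
    df = df[~bad_count]

    report = EditReport(n_input, removed, len(df))
    return df.reset_index(drop=True), report


def assign_residual_class(dim) -> np.ndarray | int:
    """Residual-variance class 1..10 for DIM in 5–305.

    Closed 30-day bins 5–35, 36–65, …, 276–305 (the first bin absorbs the
    odd day so that ten equal 30-day segments tile the window).
    """
    dim = np.asarray(dim)
    if np.any(dim < DIM_MIN) or np.any(dim > DIM_MAX):
        raise ValueError(f"DIM outside [{DIM_MIN}, {DIM_MAX}]")
    cls = np.where(dim <= 35, 1, 2 + (dim - 36) // 30).astype(int)
    return cls if cls.ndim else int(cls)


def residual_class_bins() -> list[tuple[int, int]]:
    """Closed (lo, hi) DIM bounds of the ten residual classes."""
    return [(5, 35)] + [(36 + 30 * i, 65 + 30 * i) for i in range(9)]


def group_summary(records: pd.DataFrame, bins=None) -> pd.DataFrame:
    """Per parity × frequency × DIM-bin count, mean and sample SD of yield.

    SD uses the n−1 denominator; bins with a single record carry NaN SD and
    ``sd_defined=False``.  Default bins are the ten residual classes.
    """
    if bins is None:
        bins = residual_class_bins()
    df = records.copy()
    labels = [f"{lo}-{hi}" for lo, hi in bins]
    edges = [bins[0][0] - 0.5] + [hi + 0.5 for _, hi in bins]
    df["dim_bin"] = pd.cut(df["dim"], bins=edges, labels=labels)
    df = df[df["dim_bin"].notna()]
    out = (
        df.groupby(["parity", "freq", "dim_bin"], observed=False)["milk"]
        .agg(N="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    out.loc[out["N"] == 0, ["mean", "sd"]] = np.nan
    out["sd_defined"] = out["N"] >= 2
    return out


def percent_yield_increase(mean_ref: float, mean_alt: float) -> float:
    """Percent change of mean_alt over mean_ref, to one decimal place."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return round(100.0 * (mean_alt - mean_ref) / mean_ref, 1)
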