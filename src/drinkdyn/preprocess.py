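"""Daily-diary ingestion and descriptive preprocessing.

Handles the observation-level plumbing of a 12-week (84-day) evening diary:
the 0-12 desire composite built from three Likert items, winsorization of
nightly drink counts, the cohort inclusion filter, weekly averages, and the
pooled binned lag tables that motivate each linear term of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .references import STUDY_DAYS, WINSOR_CAP

__all__ = [
    "DailyRecord",
    "PatientSeries",
    "LagRelationTable",
    "desire_composite",
    "winsorize_drinks",
    "winsorize_cohort",
    "inclusion_filter",
    "weekly_average",
    "binned_lag_relationships",
    "LAG_PANELS",
    "read_diary_csv",
    "read_baseline_csv",
    "load_cohort",
    "write_diary_csv",
    "write_baseline_csv",
]


def desire_composite(item1: int, item2: int, item3: int) -> int:
    """Sum three 0-4 Likert desire items into a 0-12 composite.

    The first item ("I really don't feel like drinking") is phrased against
    desire and is reverse-coded before summation.
    """
    items = (item1, item2, item3)
    for it in items:
        if it not in (0, 1, 2, 3, 4):
            raise ValueError(f"Likert item out of range 0-4: {it!r}")
    return (4 - item1) + item2 + item3


@dataclass
class DailyRecord:
    """One evening's diary entry; None marks a missing field."""

    day: int
    drinks: float | None = None
    desire: float | None = None

    @property
    def complete(self) -> bool:
        return self.drinks is not None and self.desire is not None


@dataclass
class PatientSeries:
    """One subject's diary plus their pre-study baseline drinking level."""

    patient_id: str
    records: list[DailyRecord]
    tlfb_baseline: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.tlfb_baseline) or self.tlfb_baseline < 0:
            raise ValueError("tlfb_baseline must be finite and nonnegative")
        self.records = sorted(self.records, key=lambda r: r.day)
        days = [r.day for r in self.records]
        if len(set(days)) != len(days):
            raise ValueError(f"duplicate days in series {self.patient_id}")

    def day_map(self) -> dict[int, DailyRecord]:
        return {r.day: r for r in self.records}

    def complete_days(self) -> list[int]:
        return [r.day for r in self.records if r.complete]

    def observed_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(days_A, drinks, days_D, desire) over non-missing entries."""
        da = [(r.day, r.drinks) for r in self.records if r.drinks is not None]
        dd = [(r.day, r.desire) for r in self.records if r.desire is not None]
        days_a = np.array([d for d, _ in da], dtype=int)
        drinks = np.array([v for _, v in da], dtype=float)
        days_d = np.array([d for d, _ in dd], dtype=int)
        desire = np.array([v for _, v in dd], dtype=float)
        return days_a, drinks, days_d, desire


def winsorize_drinks(
    values: Sequence[float],
    k: float = 2.0,
    fixed_cap: float | None = None,
) -> tuple[np.ndarray, float, int]:
    """Cap extreme drink counts at ``mean + k*sd`` of the pooled values.

    The sample standard deviation (n-1 denominator) is used and the cap is
    rounded to the nearest integer, since the capped quantity is a count.
    A ``fixed_cap`` (e.g. a cap derived on a wider sample) overrides the
    data-driven one.  Returns (capped values, cap, number replaced).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("winsorize_drinks requires a nonempty sequence")
    if np.any(~np.isfinite(vals)) or np.any(vals < 0):
        raise ValueError("winsorize_drinks requires finite nonnegative values")
    if k <= 0:
        raise ValueError("k must be positive")
    if fixed_cap is not None:
        cap = float(fixed_cap)
    else:
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        cap = float(round(float(np.mean(vals)) + k * sd))
    capped = np.minimum(vals, cap)
    n_affected = int(np.sum(vals > cap))
    return capped, cap, n_affected


def winsorize_cohort(
    cohort: Iterable[PatientSeries],
    k: float = 2.0,
    fixed_cap: float | None = WINSOR_CAP,
) -> tuple[list[PatientSeries], float, int]:
    """Winsorize drink counts pooled across a whole cohort, in place.

    Only the upper tail is capped, so raw-scale synthetic observations that
    dip below zero (Gaussian noise without rounding) pass through unchanged.
    """
    cohort = list(cohort)
    pooled = np.array(
        [r.drinks for s in cohort for r in s.records if r.drinks is not None]
    )
    if pooled.size == 0:
        raise ValueError("no drink observations to winsorize")
    if fixed_cap is not None:
        cap = float(fixed_cap)
    else:
        cap = float(round(pooled.mean() + k * pooled.std(ddof=1)))
    n_affected = 0
    for s in cohort:
        for r in s.records:
            if r.drinks is not None and r.drinks > cap:
                r.drinks = cap
                n_affected += 1
    return cohort, cap, n_affected


def inclusion_filter(
    series: PatientSeries,
    min_completeness: float = 0.30,
    min_last_day: int = 42,
    study_days: int = STUDY_DAYS,
) -> bool:
    """Cohort inclusion rule: enough complete diary days, reaching past the
    study midpoint.

    A day counts as complete when both drinks and desire were reported; the
    completeness denominator is the full study window, not days enrolled.
    """
    complete = series.complete_days()
    if not complete:
        return False
    observed_days = [
        r.day for r in series.records if r.drinks is not None or r.desire is not None
    ]
    return (
        len(complete) / study_days >= min_completeness
        and max(observed_days) > min_last_day
    )


def weekly_average(series: PatientSeries, study_days: int = STUDY_DAYS) -> pd.DataFrame:
    """Mean drinks and desire over non-overlapping 7-day windows.

    Weeks with no observations yield NaN; means are taken over whatever is
    observed inside each window.
    """
    n_weeks = math.ceil(study_days / 7)
    rows = []
    dm = series.day_map()
    for w in range(1, n_weeks + 1):
        days = range(7 * (w - 1) + 1, 7 * w + 1)
        drinks = [dm[d].drinks for d in days if d in dm and dm[d].drinks is not None]
        desire = [dm[d].desire for d in days if d in dm and dm[d].desire is not None]
        rows.append(
            {
                "week": w,
                "mean_drinks": float(np.mean(drinks)) if drinks else np.nan,
                "mean_desire": float(np.mean(desire)) if desire else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LagRelationTable:
    """Binned mean response against an integer-binned lagged predictor."""

    predictor: str
    response: str
    bin_centers: np.ndarray
    mean_response: np.ndarray
    count: np.ndarray
    low_support: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.low_support = self.count < 10

    @property
    def n_pairs(self) -> int:
        return int(self.count.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictor,
                "response": self.response,
                "bin": self.bin_centers,
                "mean_response": self.mean_response,
                "count": self.count,
                "low_support": self.low_support,
            }
        )


# (panel key, predictor description, response) — the six empirical
# relationships that motivate the model's six linear terms.
LAG_PANELS = (
    ("A_vs_dD", "D_n - D_{n-1}", "A_n"),
    ("A_vs_Alag", "A_{n-1}", "A_n"),
    ("A_vs_dA", "A_{n-1} - A_{n-2}", "A_n"),
    ("D_vs_Alag", "A_{n-1}", "D_n"),
    ("D_vs_Dlag", "D_{n-1}", "D_n"),
    ("D_vs_dA", "A_{n-1} - A_{n-2}", "D_n"),
)


def _panel_pairs(series: PatientSeries, panel: str) -> list[tuple[float, float]]:
    dm = series.day_map()
    pairs: list[tuple[float, float]] = []
    days = sorted(dm)
    for n in days:
        r_n = dm[n]
        r_1 = dm.get(n - 1)
        r_2 = dm.get(n - 2)
        if panel == "A_vs_dD":
            if r_1 and r_n.drinks is not None and r_n.desire is not None and r_1.desire is not None:
                pairs.append((r_n.desire - r_1.desire, r_n.drinks))
        elif panel == "A_vs_Alag":
            if r_1 and r_n.drinks is not None and r_1.drinks is not None:
                pairs.append((r_1.drinks, r_n.drinks))
        elif panel == "A_vs_dA":
            if r_1 and r_2 and r_n.drinks is not None and r_1.drinks is not None and r_2.drinks is not None:
                pairs.append((r_1.drinks - r_2.drinks, r_n.drinks))
        elif panel == "D_vs_Alag":
            if r_1 and r_n.desire is not None and r_1.drinks is not None:
                pairs.append((r_1.drinks, r_n.desire))
        elif panel == "D_vs_Dlag":
            if r_1 and r_n.desire is not None and r_1.desire is not None:
                pairs.append((r_1.desire, r_n.desire))
        elif panel == "D_vs_dA":
            if r_1 and r_2 and r_n.desire is not None and r_1.drinks is not None and r_2.drinks is not None:
                pairs.append((r_1.drinks - r_2.drinks, r_n.desire))
        else:
            raise ValueError(f"unknown panel {panel!r}")
    return pairs


def binned_lag_relationships(
    cohort: Iterable[PatientSeries],
) -> dict[str, LagRelationTable]:
    """Pool all patients' consecutive-day tuples and bin each predictor at
    integer values, reporting the mean response and support per bin.

    Bins with fewer than 10 contributing pairs are flagged low-support.
    A tuple is used only when every field it requires is observed on
    consecutive calendar days; nothing is imputed.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("binned_lag_relationships requires at least one series")
    tables: dict[str, LagRelationTable] = {}
    for panel, pred_name, resp_name in LAG_PANELS:
        pairs: list[tuple[float, float]] = []
        for s in cohort:
            pairs.extend(_panel_pairs(s, panel))
        if not pairs:
            tables[panel] = LagRelationTable(
                predictor=pred_name,
                response=resp_name,
                bin_centers=np.array([]),
                mean_response=np.array([]),
                count=np.array([], dtype=int),
            )
            continue
        x = np.array([p for p, _ in pairs])
        y = np.array([r for _, r in pairs])
        bins = np.round(x).astype(int)
        centers = np.unique(bins)
        means = np.array([y[bins == c].mean() for c in centers])
        counts = np.array([int(np.sum(bins == c)) for c in centers])
        tables[panel] = LagRelationTable(
            predictor=pred_name,
            response=resp_name,
            bin_centers=centers.astype(float),
            mean_response=means,
            count=counts,
        )
    return tables


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_diary_csv(path) -> dict[str, list[DailyRecord]]:
    """Read a diary CSV with columns patient_id, day, drinks and either
    desire or item1,item2,item3 (composite built on the fly).  Empty fields
    are missing; a missing Likert item makes the whole composite missing.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "day", "drinks"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"diary CSV missing columns: {sorted(missing_cols)}")
    has_items = {"item1", "item2", "item3"} <= set(df.columns)
    has_desire = "desire" in df.columns
    if not (has_items or has_desire):
        raise ValueError("diary CSV needs either a desire column or item1-3")
    out: dict[str, list[DailyRecord]] = {}
    for idx, row in df.iterrows():
        try:
            day = int(row["day"])
            drinks = None if pd.isna(row["drinks"]) else float(row["drinks"])
            if has_desire and not pd.isna(row.get("desire", np.nan)):
                desire = float(row["desire"])
            elif has_items:
                items = [row[f"item{i}"] for i in (1, 2, 3)]
                if any(pd.isna(v) for v in items):
                    desire = None
                else:
                    desire = float(desire_composite(*(int(v) for v in items)))
            else:
                desire = None
        except (ValueError, TypeError) as exc:
            raise ValueError(f"diary CSV line {idx + 2}: {exc}") from exc
        out.setdefault(str(row["patient_id"]), []).append(
            DailyRecord(day=day, drinks=drinks, desire=desire)
        )
    return out


def read_baseline_csv(path) -> dict[str, float]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "tlfb_avg_drinks_per_day"}
    if not required <= set(df.columns):
        raise ValueError(f"baseline CSV needs columns {sorted(required)}")
    return {
        str(r["patient_id"]): float(r["tlfb_avg_drinks_per_day"])
        for _, r in df.iterrows()
    }


def load_cohort(diary_path, baseline_path) -> list[PatientSeries]:
    diaries = read_diary_csv(diary_path)
    baselines = read_baseline_csv(baseline_path)
    cohort = []
    for pid, records in diaries.items():
        if pid not in baselines:
            raise ValueError(f"patient {pid} has diary rows but no baseline")
        cohort.append(
            PatientSeries(patient_id=pid, records=records, tlfb_baseline=baselines[pid])
        )
    return cohort


def write_diary_csv(cohort: Iterable[PatientSeries], path) -> None:
    rows = []
    for s in cohort:
        for r in s.records:
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "day": r.day,
                    "drinks": r.drinks,
                    "desire": r.desire,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_baseline_csv(cohort: Iterable[PatientSeries], path) -> None:
    pd.DataFrame(
        [
            {"patient_id": s.patient_id, "tlfb_avg_drinks_per_day": s.tlfb_baseline}
            for s in cohort
        ]
    ).to_csv(path, index=False)
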