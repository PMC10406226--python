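"""Global sensitivity analysis: LHS designs, PRCC, monotonicity sweeps.

Nine inputs are perturbed jointly — the six model parameters and the three
initial conditions — over ranges of mean +/- two standard deviations around
the calibrated baselines, floored at 0.001 where positivity is required and
capped for a1 and d1 at values chosen so that single-parameter excursions
keep daily alcohol at or below the 17-drink observation cap.  Outputs per
sample are the total and maximum daily alcohol and desire over the horizon
(84 days, the observation period, or one year), simulated with
non-negativity clipping on so long sweeps stay biologically interpretable.

Influence is measured by partial rank correlation coefficients: the
correlation between an input and an output after rank-transforming both and
removing the rank-linear effect of all the other inputs.  Significance uses
the usual large-sample z statistic on the PRCC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .model import InitialConditions, ModelParameters
from .references import (
    IC_STATS,
    INDIVIDUAL_SPREAD,
    LHS_A1_MAX,
    LHS_D1_MAX,
    LHS_FLOOR,
    MEDIAN_ICS,
    POPULATION_PARAMS,
    STUDY_DAYS,
)

__all__ = [
    "INPUT_NAMES",
    "OUTPUT_NAMES",
    "SamplingRange",
    "SensitivityResult",
    "default_ranges",
    "lhs_design",
    "simulate_design",
    "evaluate_outputs",
    "prcc",
    "prcc_significance",
    "run_lhs_prcc",
    "monotonicity_sweep",
]

INPUT_NAMES = ("a1", "a2", "a3", "d1", "d2", "d3", "A0", "A1", "D1")
OUTPUT_NAMES = ("sumA", "sumD", "maxA", "maxD")
YEAR_DAYS = 365


@dataclass
class SamplingRange:
    """Per-input lower/upper sampling bounds."""

    bounds: dict[str, tuple[float, float]]
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"range for {name} must satisfy lower < upper")

    def array(self, names: Sequence[str] = INPUT_NAMES) -> np.ndarray:
        return np.array([self.bounds[n] for n in names])


def default_ranges(
    posterior_summary: pd.DataFrame | None = None,
    ic_stats: dict | None = None,
) -> SamplingRange:
    """Baseline mean +/- 2 sd ranges with the positivity/cap overrides.

    ``posterior_summary`` is a table with 'parameter', 'mean' and 'sd'
    columns (as produced by ``calibration.summarize_posterior``); when
    absent, the packaged reference estimates are used.  a1 and d1 span
    [0.001, 1.0015] and [0.001, 2.2742]; d2 and the initial conditions are
    floored at 0.001.  Inputs whose sd is zero and that have no override are
    reported as degenerate rather than given an empty range.
    """
    if posterior_summary is not None:
        col = "population" if "population" in posterior_summary.columns else "mean"
        table = {
            str(r["parameter"]): (float(r[col]), float(r["sd"]))
            for _, r in posterior_summary.iterrows()
        }
    else:
        # centre on the population (fixed-effect) values, spread from the
        # individual-level standard deviations
        table = {
            p: (getattr(POPULATION_PARAMS, p), INDIVIDUAL_SPREAD[p]["sd"])
            for p in INDIVIDUAL_SPREAD
        }
    ics = ic_stats or IC_STATS
    for name, s in ics.items():
        table[name] = (s["mean"], s["sd"])

    bounds: dict[str, tuple[float, float]] = {}
    degenerate: list[str] = []
    for name in INPUT_NAMES:
        mean, sd = table[name]
        lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
        if name == "a1":
            lo, hi = LHS_FLOOR, LHS_A1_MAX
        elif name == "d1":
            lo, hi = LHS_FLOOR, LHS_D1_MAX
        elif name in ("d2", "A0", "A1", "D1"):
            lo = max(lo, LHS_FLOOR)
        if not lo < hi:
            degenerate.append(name)
            continue
        bounds[name] = (lo, hi)
    if degenerate:
        raise ValueError(
            f"degenerate sampling ranges (sd = 0, no override): {degenerate}"
        )
    return SamplingRange(bounds=bounds)


def lhs_design(
    ranges: SamplingRange, n_samples: int = 1000, seed: int | None = 0
) -> pd.DataFrame:
    """Latin hypercube over the 9 inputs: one uniform draw per equal-width
    stratum per input, strata permuted independently per column."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    names = [n for n in INPUT_NAMES if n in ranges.bounds]
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n_samples)
    arr = ranges.array(names)
    scaled = qmc.scale(unit, arr[:, 0], arr[:, 1])
    return pd.DataFrame(scaled, columns=names)


def simulate_design(design: pd.DataFrame, horizon: int) -> tuple[np.ndarray, np.ndarray]:
    """Simulate every design row at once (vectorized across samples).

    Returns (A, D) arrays of shape (n_samples, horizon) computed with
    non-negativity clipping on.
    """
    g = {n: design[n].to_numpy() for n in design.columns}
    n = len(design)
    A = np.empty((n, horizon))
    D = np.empty((n, horizon))
    A[:, 0], D[:, 0] = g["A1"], g["D1"]
    a_prev, a_prev2, d_prev = g["A1"].copy(), g["A0"].copy(), g["D1"].copy()
    for k in range(1, horizon):
        trend = a_prev - a_prev2
        d_n = g["d1"] * a_prev + g["d2"] * d_prev + g["d3"] * trend
        a_n = g["a1"] * (d_n - d_prev) + g["a2"] * a_prev + g["a3"] * trend
        np.maximum(a_n, 0.0, out=a_n)
        np.maximum(d_n, 0.0, out=d_n)
        A[:, k], D[:, k] = a_n, d_n
        a_prev2, a_prev, d_prev = a_prev, a_n, d_n
    return A, D


def evaluate_outputs(design: pd.DataFrame, horizon: int = STUDY_DAYS) -> pd.DataFrame:
    """Four output measures per design row over days 1..horizon."""
    A, D = simulate_design(design, horizon)
    return pd.DataFrame(
        {
            "sumA": A.sum(axis=1),
            "sumD": D.sum(axis=1),
            "maxA": A.max(axis=1),
            "maxD": D.max(axis=1),
        }
    )


def _partial_rank_corr(xr: np.ndarray, yr: np.ndarray, Z: np.ndarray) -> float:
    """Pearson correlation of the residuals of rank-x and rank-y after
    regressing each on the other inputs' ranks (with intercept)."""
    Zc = np.column_stack([np.ones(len(xr)), Z])
    bx, *_ = np.linalg.lstsq(Zc, xr, rcond=None)
    by, *_ = np.linalg.lstsq(Zc, yr, rcond=None)
    rx = xr - Zc @ bx
    ry = yr - Zc @ by
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        return float("nan")
    return float(rx @ ry) / denom


def prcc(design: pd.DataFrame, outputs: pd.DataFrame) -> pd.DataFrame:
    """PRCC of every input against every output measure.

    Ties get average ranks.  A constant input or output column yields NaN
    for the affected entries (flagged by the caller via isna).
    """
    n, k = design.shape
    if n <= k + 2:
        raise ValueError("PRCC needs n_samples > n_inputs + 2")
    ranks_in = {c: stats.rankdata(design[c]) for c in design.columns}
    result = {}
    for out_name in outputs.columns:
        y = outputs[out_name].to_numpy()
        yr = stats.rankdata(y)
        col = {}
        for c in design.columns:
            if np.ptp(design[c].to_numpy()) == 0.0 or np.ptp(y) == 0.0:
                col[c] = float("nan")
                continue
            others = [ranks_in[o] for o in design.columns if o != c]
            col[c] = _partial_rank_corr(ranks_in[c], yr, np.column_stack(others))
        result[out_name] = col
    return pd.DataFrame(result)


def prcc_significance(
    prcc_values: pd.DataFrame | float,
    n_samples: int,
    n_inputs: int,
    reference: str = "normal",
):
    """Two-sided p-values for PRCC values.

    The statistic is r * sqrt((n - 2 - k) / (1 - r^2)) with k the number of
    conditioned inputs, referred to the standard normal (default, a plain
    z-test) or to Student's t with n - 2 - k degrees of freedom.  |r| = 1 is
    degenerate and reported as p = 0.
    """
    df = n_samples - 2 - (n_inputs - 1)
    if df <= 0:
        raise ValueError("not enough samples for a significance test")

    def one(r: float) -> float:
        if np.isnan(r):
            return float("nan")
        if abs(r) >= 1.0:
            return 0.0
        z = r * math.sqrt(df / (1.0 - r * r))
        if reference == "normal":
            return 2.0 * float(stats.norm.sf(abs(z)))
        elif reference == "t":
            return 2.0 * float(stats.t.sf(abs(z), df))
        raise ValueError(f"unknown reference {reference!r}")

    if isinstance(prcc_values, pd.DataFrame):
        return prcc_values.map(one)
    return one(float(prcc_values))


@dataclass
class SensitivityResult:
    """Bundle of one LHS/PRCC run."""

    design: pd.DataFrame
    outputs: pd.DataFrame
    prcc: pd.DataFrame
    p_values: pd.DataFrame
    horizon: int
    seed: int | None


def run_lhs_prcc(
    ranges: SamplingRange | None = None,
    n_samples: int = 1000,
    horizon: int = STUDY_DAYS,
    seed: int | None = 0,
    reference: str = "normal",
) -> SensitivityResult:
    """End-to-end LHS + PRCC at one horizon."""
    ranges = ranges or default_ranges()
    design = lhs_design(ranges, n_samples=n_samples, seed=seed)
    outputs = evaluate_outputs(design, horizon=horizon)
    r = prcc(design, outputs)
    p = prcc_significance(r, n_samples, design.shape[1], reference=reference)
    return SensitivityResult(
        design=design, outputs=outputs, prcc=r, p_values=p, horizon=horizon, seed=seed
    )


def _baseline_row(
    params: ModelParameters | None = None, ics: InitialConditions | None = None
) -> dict[str, float]:
    params = params or POPULATION_PARAMS
    ics = ics or MEDIAN_ICS
    row = params.as_dict()
    row.update({"A0": ics.A0, "A1": ics.A1, "D1": ics.D1})
    return row


def monotonicity_sweep(
    input_name: str,
    value_range: tuple[float, float] | None = None,
    base: dict[str, float] | None = None,
    n_grid: int = 41,
    horizon: int = STUDY_DAYS,
    atol: float = 1e-9,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Vary one input over an even grid with everything else frozen.

    Returns the curve of the four output measures against the swept input
    plus a per-measure monotonicity verdict (no sign change in successive
    differences, up to ``atol`` on the output scale).  Used to check that
    inputs relate monotonically to outputs, the condition under which PRCC
    ranking is meaningful.
    """
    if n_grid < 3:
        raise ValueError("n_grid must be >= 3")
    base = dict(base or _baseline_row())
    if value_range is None:
        value_range = default_ranges().bounds[input_name]
    grid = np.linspace(value_range[0], value_range[1], n_grid)
    rows = []
    for v in grid:
        r = dict(base)
        r[input_name] = float(v)
        rows.append(r)
    design = pd.DataFrame(rows)[list(INPUT_NAMES)]
    outputs = evaluate_outputs(design, horizon=horizon)
    curve = pd.concat([pd.Series(grid, name=input_name), outputs], axis=1)
    verdict = {}
    for m in OUTPUT_NAMES:
        y = outputs[m].to_numpy()
        d = np.diff(y)
        scale = max(float(np.max(np.abs(y))), 1.0)
        active = d[np.abs(d) > atol * scale]
        if active.size == 0:
            verdict[m] = True  # flat counts as (weakly) monotone
        else:
            s = np.sign(active)
            verdict[m] = bool(np.all(s == s[0]))
    return curve, verdict
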