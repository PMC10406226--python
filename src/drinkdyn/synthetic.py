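"""Synthetic EMA-cohort generator.

Emulates the statistical structure the downstream analysis assumes: each
patient's effective parameters are a population vector plus a Gaussian
random effect on the varying subset {a2, a3, d2, d3}; initial conditions are
drawn from truncated normals matching the reference cohort's summary
statistics; observations are the noiseless model trajectory plus i.i.d.
Gaussian noise, optionally rounded/clipped to the observation scales, with
days masked missing completely at random.

Ground truth (effective parameters, initial conditions, noiseless paths) is
attached to every series so calibration and identifiability stages can be
validated by recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import json
import numpy as np
from scipy import stats

from .model import InitialConditions, ModelParameters, simulate
from .preprocess import DailyRecord, PatientSeries, write_baseline_csv, write_diary_csv
from .references import (
    COHORT_SIZE,
    DESIRE_MAX,
    IC_STATS,
    INDIVIDUAL_SPREAD,
    POPULATION_PARAMS,
    STUDY_DAYS,
    VARYING_PARAMS,
    WINSOR_CAP,
)

__all__ = ["CohortSpec", "GroundTruth", "draw_effective_parameters", "generate_cohort",
           "write_cohort_csvs"]


def _default_psi() -> np.ndarray:
    sds = np.array([INDIVIDUAL_SPREAD[p]["sd"] for p in VARYING_PARAMS])
    return np.diag(sds**2)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the reference study: 37 patients observed nightly for 84
    days, population parameters at the published fixed-effect estimates,
    diagonal random-effects covariance with the published per-patient
    standard deviations, truncated-normal initial conditions matching the
    published summary statistics.  sigma2 is the shared observation-noise
    variance on both outcomes (about one drink / one desire unit of nightly
    reporting noise at the default); missingness is the per-day probability
    of a skipped diary entry (defaults to a typical ~80% compliance rate).
    """

    n_patients: int = COHORT_SIZE
    horizon: int = STUDY_DAYS
    beta: ModelParameters = POPULATION_PARAMS
    psi: np.ndarray = field(default_factory=_default_psi)
    sigma2: float = 1.0
    sigma2_desire: float | None = None  # optional second variance for D
    missingness: float = 0.2
    round_and_clip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        p = len(VARYING_PARAMS)
        if self.psi.shape != (p, p):
            raise ValueError(f"psi must be {p}x{p} over {VARYING_PARAMS}")
        if not np.allclose(self.psi, self.psi.T):
            raise ValueError("psi must be symmetric")
        eigs = np.linalg.eigvalsh(self.psi)
        if eigs.min() < -1e-12:
            raise ValueError("psi must be positive semi-definite")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must lie in [0, 1)")
        if self.n_patients < 1 or self.horizon < 2:
            raise ValueError("need n_patients >= 1 and horizon >= 2")


@dataclass
class GroundTruth:
    """Generating quantities stored alongside a synthetic series."""

    params: ModelParameters
    ics: InitialConditions
    noiseless_A: np.ndarray
    noiseless_D: np.ndarray


def draw_effective_parameters(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> list[ModelParameters]:
    """Draw per-patient effective parameters beta_i = beta + b_i.

    b_i ~ Normal(0, psi) on the varying subset; a1 and d1 are copied from
    the population vector.  Draws violating the nonnegativity of a2 or d2
    are rejected and redrawn.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    mean = np.array([getattr(spec.beta, p) for p in VARYING_PARAMS])
    out: list[ModelParameters] = []
    for _ in range(spec.n_patients):
        for _attempt in range(1000):
            draw = rng.multivariate_normal(mean, spec.psi, method="eigh")
            vals = dict(zip(VARYING_PARAMS, draw))
            if vals.get("a2", 0.0) >= 0.0 and vals.get("d2", 0.0) >= 0.0:
                break
        else:  # pragma: no cover - would need absurd psi
            raise RuntimeError("rejection sampling failed: psi too wide for a2/d2 >= 0")
        out.append(spec.beta.replace(**{k: float(v) for k, v in vals.items()}))
    return out


def _draw_ics(rng: np.random.Generator) -> InitialConditions:
    vals = {}
    for name in ("A0", "A1", "D1"):
        s = IC_STATS[name]
        a = (s["min"] - s["mean"]) / s["sd"]
        b = (s["max"] - s["mean"]) / s["sd"]
        vals[name] = float(
            stats.truncnorm.rvs(a, b, loc=s["mean"], scale=s["sd"], random_state=rng)
        )
    return InitialConditions(**vals)


def generate_cohort(spec: CohortSpec) -> list[PatientSeries]:
    """Generate a cohort of PatientSeries with ground truth attached.

    Each series carries a ``truth`` attribute (GroundTruth).  With
    ``round_and_clip`` the drink observations are rounded to integers in
    [0, 17] and desire to integers in [0, 12], mimicking the observation
    scales of a real diary; left off, observations stay inside the Gaussian
    likelihood family the calibration assumes.

    The day-1 record is emitted noise-free and is never masked: in the
    analysis model the first diary values *define* the initial conditions
    the trajectory is simulated from (they are seeds, not measurements of a
    latent state), so a generator emulating that model must make the day-1
    record coincide with the generating initial conditions.  Noise applies
    to days 2 onward.
    """
    rng = np.random.default_rng(spec.seed)
    betas = draw_effective_parameters(spec, rng)
    sigma_a = float(np.sqrt(spec.sigma2))
    sigma_d = float(
        np.sqrt(spec.sigma2 if spec.sigma2_desire is None else spec.sigma2_desire)
    )
    cohort: list[PatientSeries] = []
    for i, params in enumerate(betas):
        ics = _draw_ics(rng)
        traj = simulate(params, ics, spec.horizon, clip_nonneg=False)
        noise_a = rng.normal(0.0, sigma_a, spec.horizon)
        noise_d = rng.normal(0.0, sigma_d, spec.horizon)
        noise_a[0] = 0.0
        noise_d[0] = 0.0
        obs_A = traj.A + noise_a
        obs_D = traj.D + noise_d
        if spec.round_and_clip:
            obs_A = np.clip(np.round(obs_A), 0, WINSOR_CAP)
            obs_D = np.clip(np.round(obs_D), 0, DESIRE_MAX)
        miss = rng.random(spec.horizon) < spec.missingness
        miss[0] = False
        records = [
            DailyRecord(
                day=n + 1,
                drinks=None if miss[n] else float(obs_A[n]),
                desire=None if miss[n] else float(obs_D[n]),
            )
            for n in range(spec.horizon)
        ]
        series = PatientSeries(
            patient_id=f"S{i + 1:03d}", records=records, tlfb_baseline=ics.A0
        )
        series.truth = GroundTruth(  # type: ignore[attr-defined]
            params=params, ics=ics, noiseless_A=traj.A, noiseless_D=traj.D
        )
        cohort.append(series)
    return cohort


def write_cohort_csvs(cohort: Sequence[PatientSeries], outdir) -> dict[str, Path]:
    """Emit the diary/baseline CSV dialect plus a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    diary = outdir / "diary.csv"
    baseline = outdir / "baseline.csv"
    truth_path = outdir / "ground_truth.json"
    write_diary_csv(cohort, diary)
    write_baseline_csv(cohort, baseline)
    truth = {}
    for s in cohort:
        t = getattr(s, "truth", None)
        if t is not None:
            truth[s.patient_id] = {
                "params": t.params.as_dict(),
                "ics": {"A0": t.ics.A0, "A1": t.ics.A1, "D1": t.ics.D1},
            }
    truth_path.write_text(json.dumps(truth, indent=1))
    return {"diary": diary, "baseline": baseline, "ground_truth": truth_path}
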