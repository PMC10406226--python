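"""Bayesian mixed-effects calibration of the drinking-desire model.

The hierarchical model: each patient i has effective parameters
beta_i = beta + b_i with b_i ~ N(0, Psi) over the varying subset (default
{a2, a3, d2, d3}; a1 and d1 are fixed for identifiability).  Observations
are the patient's full simulated trajectory from their own data-derived
initial conditions plus i.i.d. N(0, sigma2) noise, with A and D residuals
sharing one error variance.

Priors: flat (improper) on beta, Inv-Gamma on sigma2 with a unit prior
weight, Inverse-Wishart on Psi with a strong prior degree-of-freedom count
(rho0 = 100) centred on a preliminary frequentist estimate, so the random
effects stay near an empirically plausible spread while the chain is short.

Sampling is Metropolis-within-Gibbs: each beta_i is a 4-dimensional
Delayed-Rejection Adaptive-Metropolis (DRAM) block, while beta, Psi and
sigma2 have conjugate draws (normal, Inverse-Wishart, Inverse-Gamma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import InitialConditions, ModelParameters, PARAM_NAMES, simulate
from .preprocess import PatientSeries
from .references import POPULATION_PARAMS, VARYING_PARAMS

__all__ = [
    "MixedEffectsSpec",
    "MixedEffectsState",
    "PriorConfig",
    "Chain",
    "PatientData",
    "count_parameters",
    "patient_data",
    "log_likelihood",
    "log_prior_effective",
    "per_patient_fit",
    "initial_frequentist_fit",
    "gibbs_beta",
    "gibbs_psi",
    "gibbs_sigma2",
    "fit_mixed_effects",
    "summarize_posterior",
    "convergence_diagnostics",
]

NONNEG_PARAMS = frozenset({"a1", "a2", "d1", "d2"})

# A patient is numerically stiff when their best trajectory-matching
# residual variance exceeds the cohort median by this factor: strongly
# unstable dynamics amplify parameter perturbations past double-precision
# resolution, so the exact conditional posterior (a point mass at the
# generating values, approximated by the one-step regression estimate) is
# substituted and the patient's residuals carry no usable information on
# sigma2.  Six orders of magnitude separates genuine misfit from numerical
# degeneracy unambiguously.
STIFF_FACTOR = 1e6


def count_parameters(m: int, N: int) -> int:
    """Total quantities estimated by the hierarchical model.

    m fixed effects + m*N random effects + 1 error variance + m(m+1)/2
    random-effects covariance elements.  For nine varying quantities and 37
    patients this is 388; reducing to four varying parameters gives 163.
    """
    if m < 1 or N < 1:
        raise ValueError("count_parameters requires m >= 1 and N >= 1")
    return m + m * N + 1 + m * (m + 1) // 2


@dataclass(frozen=True)
class MixedEffectsSpec:
    """Which parameters vary across patients and which are fixed.

    Initial conditions are always taken from the data (first observed
    drinks/desire values, TLFB baseline), never estimated.
    """

    varying: tuple[str, ...] = VARYING_PARAMS
    fixed_values: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fixed_values is None:
            fixed = {
                p: getattr(POPULATION_PARAMS, p)
                for p in PARAM_NAMES
                if p not in self.varying
            }
            object.__setattr__(self, "fixed_values", fixed)
        overlap = set(self.varying) & set(self.fixed_values)
        if overlap:
            raise ValueError(f"parameters both varying and fixed: {sorted(overlap)}")
        covered = set(self.varying) | set(self.fixed_values)
        if covered != set(PARAM_NAMES):
            raise ValueError(f"varying + fixed must cover {PARAM_NAMES}")

    @property
    def dim(self) -> int:
        return len(self.varying)

    def build_params(self, theta: Sequence[float]) -> ModelParameters:
        d = dict(self.fixed_values)
        d.update(zip(self.varying, theta))
        return ModelParameters(**d)

    def in_support(self, theta: Sequence[float]) -> bool:
        return all(
            v >= 0.0 for p, v in zip(self.varying, theta) if p in NONNEG_PARAMS
        )


@dataclass
class MixedEffectsState:
    """One point in the joint posterior space."""

    beta: np.ndarray  # (m,) fixed effects over the varying subset
    effective: np.ndarray  # (N, m) per-patient effective parameters
    sigma2: float
    psi: np.ndarray  # (m, m)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.effective = np.atleast_2d(np.asarray(self.effective, dtype=float))
        self.psi = np.asarray(self.psi, dtype=float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not np.allclose(self.psi, self.psi.T):
            raise ValueError("psi must be symmetric")


@dataclass
class PriorConfig:
    """Hyperparameters; beta gets a flat improper prior (Sigma0 = diag(inf)).

    sigma2 ~ Inv-Gamma with shape n0/2 and scale n0*s0_squared/2 (so n0 acts
    as a prior observation count); Psi ~ Inv-Wishart(Psi0, rho0) in the
    scale-matrix parameterization.
    """

    beta0: np.ndarray
    s0_squared: float
    Psi0: np.ndarray
    n0: float = 1.0
    rho0: float = 100.0

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.Psi0 = np.asarray(self.Psi0, dtype=float)
        p = self.Psi0.shape[0]
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.rho0 <= p - 1:
            raise ValueError("rho0 must exceed dimension - 1")


# ---------------------------------------------------------------------------
# Per-patient data access
# ---------------------------------------------------------------------------


@dataclass
class PatientData:
    """Observation arrays and initial conditions for one patient."""

    patient_id: str
    ics: InitialConditions
    days_a: np.ndarray
    y_a: np.ndarray
    days_d: np.ndarray
    y_d: np.ndarray
    horizon: int

    @property
    def n_obs(self) -> int:
        return len(self.y_a) + len(self.y_d)

    def ssr(self, params: ModelParameters) -> float:
        """Sum of squared residuals of the full simulated trajectory."""
        traj = simulate(params, self.ics, self.horizon)
        ra = traj.A[self.days_a - 1] - self.y_a
        rd = traj.D[self.days_d - 1] - self.y_d
        val = float(ra @ ra + rd @ rd)
        return val if math.isfinite(val) else float("inf")

    def residuals(self, params: ModelParameters) -> np.ndarray:
        traj = simulate(params, self.ics, self.horizon)
        return np.concatenate(
            [traj.A[self.days_a - 1] - self.y_a, traj.D[self.days_d - 1] - self.y_d]
        )


def patient_data(series: PatientSeries) -> PatientData:
    """Extract observation arrays; A1/D1 are the first observed diary values
    and A0 is the TLFB baseline."""
    days_a, y_a, days_d, y_d = series.observed_arrays()
    if days_a.size == 0 or days_d.size == 0:
        raise ValueError(f"patient {series.patient_id}: no usable observations")
    a1 = float(y_a[0])
    d1 = float(np.clip(y_d[0], 0.0, 12.0))
    ics = InitialConditions(A0=series.tlfb_baseline, A1=max(a1, 0.0), D1=d1)
    horizon = int(max(days_a.max(), days_d.max(), 2))
    return PatientData(
        patient_id=series.patient_id,
        ics=ics,
        days_a=days_a,
        y_a=y_a,
        days_d=days_d,
        y_d=y_d,
        horizon=horizon,
    )


# ---------------------------------------------------------------------------
# Likelihood and prior kernels
# ---------------------------------------------------------------------------


def log_likelihood(
    cohort: Sequence[PatientData],
    state: MixedEffectsState,
    spec: MixedEffectsSpec,
    normalized: bool = False,
) -> float:
    """Log of the Gaussian likelihood kernel.

    sum_i [ -1/(2 sigma2) * sum_j (y_ij - f_ij)^2 ] over observed days of
    both outcomes, where f is the full trajectory simulated from the
    patient's initial conditions under beta_i.  With ``normalized`` the
    -(n/2) log(2 pi sigma2) constant is included (needed wherever sigma2
    itself is compared, e.g. the sigma2 Gibbs step).
    """
    total_ss = 0.0
    n_obs = 0
    for i, pd_i in enumerate(cohort):
        params = spec.build_params(state.effective[i])
        total_ss += pd_i.ssr(params)
        n_obs += pd_i.n_obs
    ll = -total_ss / (2.0 * state.sigma2)
    if normalized:
        ll -= 0.5 * n_obs * math.log(2.0 * math.pi * state.sigma2)
    return ll


def log_prior_effective(state: MixedEffectsState) -> float:
    """Log kernel of the random-effects prior:
    sum_i -0.5 (beta_i - beta)' Psi^{-1} (beta_i - beta)."""
    try:
        chol = np.linalg.cholesky(state.psi)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("psi is numerically singular") from exc
    from scipy.linalg import solve_triangular

    dev = state.effective - state.beta  # (N, m)
    z = solve_triangular(chol, dev.T, lower=True)
    return float(-0.5 * np.sum(z * z))


# ---------------------------------------------------------------------------
# Frequentist initialization
# ---------------------------------------------------------------------------

_MULTISTARTS = (
    # population-scale guess, a neutral decay guess, a low-feedback guess
    (0.28, 0.99, -0.45, 0.81, 0.41, -0.06),
    (0.10, 0.90, 0.00, 0.50, 0.50, 0.00),
    (0.50, 0.70, 0.20, 1.00, 0.20, 0.10),
)


def _regression_start(
    data: PatientData, fixed: dict[str, float] | None = None
) -> dict[str, float] | None:
    """One-step-ahead linear-regression estimate of the model parameters.

    Conditional on the observed lagged values, both equations are ordinary
    linear regressions (D_n on A_{n-1}, D_{n-1}, dA; A_n on dD, A_{n-1},
    dA), which gives a nearly unbiased estimate when observation noise is
    small — crucially including patients with near-unit-root (escalating)
    dynamics, where the trajectory-matching objective is too sharp for
    generic starting points.  Parameters named in ``fixed`` are clamped and
    their contribution subtracted from the response before regressing.
    """
    fixed = fixed or {}
    am = dict(zip(data.days_a.tolist(), data.y_a.tolist()))
    dm = dict(zip(data.days_d.tolist(), data.y_d.tolist()))
    am.setdefault(0, data.ics.A0)
    rows_a, ya = [], []
    rows_d, yd = [], []
    a_regs = [p for p in ("a1", "a2", "a3") if p not in fixed]
    d_regs = [p for p in ("d1", "d2", "d3") if p not in fixed]
    for n in sorted(am):
        if n - 1 in am and n - 2 in am and n - 1 in dm:
            trend = am[n - 1] - am[n - 2]
            if n in dm:
                feats_d = {"d1": am[n - 1], "d2": dm[n - 1], "d3": trend}
                rows_d.append([feats_d[p] for p in d_regs])
                yd.append(dm[n] - sum(fixed[p] * feats_d[p] for p in fixed if p in feats_d))
                if n in am:
                    feats_a = {"a1": dm[n] - dm[n - 1], "a2": am[n - 1], "a3": trend}
                    rows_a.append([feats_a[p] for p in a_regs])
                    ya.append(
                        am[n] - sum(fixed[p] * feats_a[p] for p in fixed if p in feats_a)
                    )
    if len(rows_a) < len(a_regs) + 3 or len(rows_d) < len(d_regs) + 3:
        return None
    try:
        coef_a, *_ = np.linalg.lstsq(np.asarray(rows_a), np.asarray(ya), rcond=None)
        coef_d, *_ = np.linalg.lstsq(np.asarray(rows_d), np.asarray(yd), rcond=None)
    except np.linalg.LinAlgError:
        return None
    est = dict(fixed)
    est.update(dict(zip(a_regs, coef_a)))
    est.update(dict(zip(d_regs, coef_d)))
    return {
        k: max(float(v), 0.0) if k in NONNEG_PARAMS else float(v)
        for k, v in est.items()
    }


def per_patient_fit(
    series: PatientSeries | PatientData,
    spec: MixedEffectsSpec | None = None,
    full: bool = True,
    starts: Sequence[Sequence[float]] = _MULTISTARTS,
) -> tuple[ModelParameters, float, dict]:
    """Least-squares fit of one patient's trajectory.

    With ``full`` all six parameters are estimated (the preliminary round
    used both to seed the collinearity analysis and to initialize the
    hierarchical fit); otherwise only ``spec.varying`` is free.  A small
    multistart of documented initial guesses guards against local minima;
    the best endpoint wins.  Returns (estimate, residual variance,
    diagnostics).
    """
    data = series if isinstance(series, PatientData) else patient_data(series)
    if full:
        names = PARAM_NAMES
        fixed: dict[str, float] = {}
    else:
        assert spec is not None
        names = spec.varying
        fixed = dict(spec.fixed_values)

    def build(theta: np.ndarray) -> ModelParameters:
        d = dict(fixed)
        d.update(zip(names, theta))
        return ModelParameters(**d)

    lower = np.array([0.0 if p in NONNEG_PARAMS else -np.inf for p in names])
    upper = np.full(len(names), np.inf)

    def resid(theta: np.ndarray) -> np.ndarray:
        return data.residuals(build(theta))

    start_dicts = [dict(zip(PARAM_NAMES, s)) for s in starts]
    reg = _regression_start(data, fixed=fixed)
    if reg is not None:
        start_dicts.insert(0, reg)

    best = None
    tried = []
    for sd_ in start_dicts:
        x0 = np.array([sd_[p] for p in names])
        x0 = np.clip(x0, lower, upper)
        try:
            res = optimize.least_squares(
                resid, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:  # singular steps on degenerate data
            continue
        tried.append(res)
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"all fits failed for patient {data.patient_id}")
    ssr = 2.0 * best.cost
    resvar = ssr / data.n_obs
    diag = {
        "converged": bool(best.success),
        "n_starts": len(tried),
        "ssr": ssr,
        "n_obs": data.n_obs,
        "regression_estimate": reg,
    }
    return build(best.x), resvar, diag


def initial_frequentist_fit(
    cohort: Sequence[PatientSeries | PatientData],
    spec: MixedEffectsSpec | None = None,
    rho0: float = 100.0,
) -> tuple[PriorConfig, pd.DataFrame]:
    """Two-stage starting estimate for the hierarchical model.

    Stage one fits every patient separately with all six parameters free
    (the estimates a downstream collinearity screen evaluates at).  Stage
    two re-fits each patient with the non-varying parameters clamped to
    ``spec.fixed_values``, because a varying-subset value is only meaningful
    conditional on the clamped ones; these conditional estimates (the
    ``start_*`` columns) seed the chain's effective parameters.

    Priors: beta0 = componentwise median of the conditional estimates;
    s0_squared = pooled conditional residual variance; Psi0 scaled so the
    Inverse-Wishart prior with ``rho0`` degrees of freedom is *centred* on
    the sample covariance C of the conditional estimates
    (Psi0 = (rho0 - m - 1) C, since an IW(Psi0, rho0) has mean
    Psi0/(rho0 - m - 1)) — rho0 expresses confidence in C, not a rescaling
    of it.  C is jittered to positive definiteness if degenerate.

    Patients whose trajectory-matching fit is *numerically stiff* — the
    residual variance exceeds the cohort median by more than a factor of
    1e6, the signature of strongly unstable dynamics whose least-squares
    needle is below double-precision resolution — have their starting values
    replaced by the one-step regression estimate (which stays well
    conditioned) and are excluded from the pooled residual-variance seed;
    the ``stiff`` column flags them.
    """
    spec = spec or MixedEffectsSpec()
    if len(cohort) < 2:
        raise ValueError("need at least two patients to form a covariance seed")
    rows = []
    ssrs, n_obss = [], []
    for s in cohort:
        est_full, resvar_full, _ = per_patient_fit(s, full=True)
        est_cond, resvar_cond, diag = per_patient_fit(s, spec=spec, full=False)
        row = {"patient_id": s.patient_id, **est_full.as_dict(), "resvar": resvar_full}
        for p in spec.varying:
            row[f"start_{p}"] = getattr(est_cond, p)
        row["resvar_cond"] = resvar_cond
        row["_regression"] = diag.get("regression_estimate")
        rows.append(row)
        ssrs.append(diag["ssr"])
        n_obss.append(diag["n_obs"])
    table = pd.DataFrame(rows)
    med = float(np.median(table["resvar_cond"]))
    stiff = table["resvar_cond"].to_numpy() > STIFF_FACTOR * max(med, 1e-12)
    for i in np.flatnonzero(stiff):
        reg = table.at[i, "_regression"]
        if reg is not None:
            for p in spec.varying:
                table.at[i, f"start_{p}"] = reg[p]
    table["stiff"] = stiff
    table = table.drop(columns=["_regression"])
    est_mat = table[[f"start_{p}" for p in spec.varying]].to_numpy()
    beta0 = np.median(est_mat, axis=0)
    Psi0 = np.cov(est_mat, rowvar=False)
    Psi0 = np.atleast_2d(Psi0)
    # degenerate (e.g. identical patients) -> jitter for positive definiteness
    min_eig = float(np.linalg.eigvalsh(Psi0)[0])
    if min_eig < 1e-10:
        Psi0 = Psi0 + (1e-8 - min(min_eig, 0.0)) * np.eye(spec.dim)
    Psi0 = max(rho0 - spec.dim - 1.0, 1.0) * Psi0
    keep = ~stiff
    s0sq = float(np.sum(np.array(ssrs)[keep]) / np.sum(np.array(n_obss)[keep]))
    return PriorConfig(beta0=beta0, s0_squared=s0sq, Psi0=Psi0, rho0=rho0), table


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


@dataclass
class Chain:
    """Post-burn-in posterior samples with sampling metadata."""

    varying: tuple[str, ...]
    beta: np.ndarray  # (K, m)
    effective: np.ndarray  # (K, N, m)
    sigma2: np.ndarray  # (K,)
    psi: np.ndarray  # (K, m, m)
    acceptance: np.ndarray  # per-patient first-stage+DR acceptance rate
    seed: int
    n_iter: int
    burn: int
    stiff: np.ndarray | None = None  # patients frozen at their regression estimate

    @property
    def n_kept(self) -> int:
        return len(self.sigma2)

    def scalar_samples(self) -> dict[str, np.ndarray]:
        out = {f"beta_{p}": self.beta[:, k] for k, p in enumerate(self.varying)}
        out["sigma2"] = self.sigma2
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scalar_samples())


def gibbs_beta(
    effective: np.ndarray, psi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Conjugate draw of the fixed effects under the flat (improper) prior:
    beta | {beta_i}, Psi ~ N(mean of beta_i, Psi / N)."""
    N, m = effective.shape
    chol = np.linalg.cholesky(psi)
    return effective.mean(axis=0) + (chol @ rng.standard_normal(m)) / math.sqrt(N)


def gibbs_psi(
    effective: np.ndarray,
    beta: np.ndarray,
    priors: PriorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate Inverse-Wishart draw of the random-effects covariance:
    Psi | {beta_i}, beta ~ IW(Psi0 + sum_i dev dev', rho0 + N)."""
    dev = effective - beta
    scale = priors.Psi0 + dev.T @ dev
    psi = stats.invwishart.rvs(
        df=priors.rho0 + len(effective), scale=scale, random_state=rng
    )
    psi = np.atleast_2d(psi)
    return 0.5 * (psi + psi.T)


def gibbs_sigma2(
    ssr_total: float, n_obs: int, priors: PriorConfig, rng: np.random.Generator
) -> float:
    """Conjugate Inverse-Gamma draw of the error variance:
    sigma2 | residuals ~ IG(shape=(n0 + n)/2, scale=(n0 s0^2 + SS)/2)."""
    shape = 0.5 * (priors.n0 + n_obs)
    rate = 0.5 * (priors.n0 * priors.s0_squared + ssr_total)
    return float(stats.invgamma.rvs(a=shape, scale=rate, random_state=rng))


def _dram_update(
    theta: np.ndarray,
    logpost: float,
    log_target,
    chol: np.ndarray,
    rng: np.random.Generator,
    dr_shrink: float,
    delayed_rejection: bool,
) -> tuple[np.ndarray, float, bool]:
    """One DRAM step for a single block; returns (theta, logpost, accepted)."""
    d = len(theta)
    y1 = theta + chol @ rng.standard_normal(d)
    lp1 = log_target(y1)
    log_a1 = lp1 - logpost
    if math.log(rng.random()) < min(0.0, log_a1):
        return y1, lp1, True
    if not delayed_rejection:
        return theta, logpost, False
    # second-stage (narrower) proposal
    y2 = theta + dr_shrink * (chol @ rng.standard_normal(d))
    lp2 = log_target(y2)
    if not math.isfinite(lp2):
        return theta, logpost, False
    # alpha2 = min(1, N2/D2) with
    # N2 = pi(y2) q1(y2,y1) [1 - alpha1(y2,y1)],  D2 = pi(x) q1(x,y1) [1 - alpha1(x,y1)]
    # q1 Gaussian with covariance chol chol'; log q ratio uses the quadratic forms.
    from scipy.linalg import solve_triangular

    z_x = solve_triangular(chol, y1 - theta, lower=True)
    z_2 = solve_triangular(chol, y1 - y2, lower=True)
    log_q_num = -0.5 * float(z_2 @ z_2)
    log_q_den = -0.5 * float(z_x @ z_x)
    log_a1_from_y2 = lp1 - lp2
    if log_a1_from_y2 >= 0.0:
        return theta, logpost, False  # 1 - alpha1(y2, y1) = 0
    log_1m_a1_num = math.log1p(-math.exp(log_a1_from_y2))
    log_1m_a1_den = math.log1p(-math.exp(min(log_a1, -1e-12)))
    log_a2 = (lp2 + log_q_num + log_1m_a1_num) - (logpost + log_q_den + log_1m_a1_den)
    if math.log(rng.random()) < min(0.0, log_a2):
        return y2, lp2, True
    return theta, logpost, False


def fit_mixed_effects(
    cohort: Sequence[PatientSeries | PatientData],
    spec: MixedEffectsSpec | None = None,
    priors: PriorConfig | None = None,
    n_iter: int = 5000,
    seed: int = 0,
    burn_frac: float = 0.5,
    start_effective: np.ndarray | None = None,
    adapt_interval: int = 100,
    dr_shrink: float = 0.2,
    adapt: bool = True,
    delayed_rejection: bool = True,
    thin: int = 1,
) -> Chain:
    """Metropolis-within-Gibbs sampler for the hierarchical model.

    Each sweep updates (a) every beta_i by a blocked DRAM proposal targeting
    its conditional posterior, (b) beta by its conjugate normal draw (flat
    prior: mean of the beta_i, covariance Psi/N), (c) Psi by Inverse-Wishart
    with scale Psi0 + sum_i dev dev' and df rho0 + N, and (d) sigma2 by
    Inverse-Gamma with shape (n0 + n_obs)/2 and scale (n0 s0^2 + SS)/2.

    ``adapt=False`` freezes the proposal covariance (plain Metropolis-
    Hastings blocks); ``delayed_rejection=False`` drops the second-stage
    proposal (adaptive Metropolis).  Identical seeds give identical chains.

    Numerically stiff patients (see ``STIFF_FACTOR``) keep their starting
    effective parameters throughout and contribute to the beta and Psi
    updates but not to sigma2; the ``Chain.stiff`` mask records them.
    """
    spec = spec or MixedEffectsSpec()
    data = [s if isinstance(s, PatientData) else patient_data(s) for s in cohort]
    if priors is None:
        priors, table = initial_frequentist_fit(data, spec)
        if start_effective is None:
            start_effective = table[[f"start_{p}" for p in spec.varying]].to_numpy()
    rng = np.random.default_rng(seed)
    N, m = len(data), spec.dim
    n_obs = sum(pd_i.n_obs for pd_i in data)

    beta = priors.beta0.copy()
    effective = (
        np.tile(beta, (N, 1)) if start_effective is None else start_effective.copy()
    )
    # start Psi at its prior mean Psi0/(rho0 - m - 1)
    psi = priors.Psi0 / max(priors.rho0 - m - 1.0, 1.0)
    sigma2 = float(priors.s0_squared)

    # cached per-patient sum of squared residuals at the current effective params
    ssr = np.array(
        [pd_i.ssr(spec.build_params(effective[i])) for i, pd_i in enumerate(data)]
    )
    # numerically stiff patients: their effective parameters stay frozen at
    # the (well-conditioned) starting estimate and their residuals are
    # excluded from the sigma2 update -- see STIFF_FACTOR
    resvar0 = ssr / np.array([pd_i.n_obs for pd_i in data])
    stiff = resvar0 > STIFF_FACTOR * max(float(np.median(resvar0)), 1e-12)
    active = np.flatnonzero(~stiff)
    n_obs_active = sum(data[i].n_obs for i in active)

    sd = 2.38**2 / m
    base_cov = sd * (psi + 1e-10 * np.eye(m))
    chols = [np.linalg.cholesky(base_cov) for _ in range(N)]
    # running moments per patient for adaptive covariance
    run_mean = effective.copy()
    run_cov = np.tile(np.zeros((m, m)), (N, 1, 1))
    n_seen = 1

    burn = int(burn_frac * n_iter)
    kept_beta, kept_eff, kept_sigma2, kept_psi = [], [], [], []
    accepts = np.zeros(N)
    proposals = 0

    psi_chol = np.linalg.cholesky(psi)
    psi_inv = np.linalg.inv(psi)

    for it in range(n_iter):
        # (a) per-patient DRAM blocks
        for i in active:
            pd_i = data[i]
            theta_i = effective[i]

            def log_target(th: np.ndarray, _pd=pd_i) -> float:
                if not spec.in_support(th):
                    return -math.inf
                s = _pd.ssr(spec.build_params(th))
                if not math.isfinite(s):
                    return -math.inf
                dev = th - beta
                return -s / (2.0 * sigma2) - 0.5 * float(dev @ psi_inv @ dev)

            dev0 = theta_i - beta
            lp0 = -ssr[i] / (2.0 * sigma2) - 0.5 * float(dev0 @ psi_inv @ dev0)
            new_theta, new_lp, acc = _dram_update(
                theta_i, lp0, log_target, chols[i], rng, dr_shrink, delayed_rejection
            )
            if acc:
                effective[i] = new_theta
                ssr[i] = pd_i.ssr(spec.build_params(new_theta))
                accepts[i] += 1
            # running covariance (Welford) for adaptation
            if adapt:
                delta = effective[i] - run_mean[i]
                run_mean[i] += delta / (n_seen + 1)
                run_cov[i] += np.outer(delta, effective[i] - run_mean[i])
        proposals += 1
        n_seen += 1

        if adapt and it > 0 and it % adapt_interval == 0 and n_seen > 2 * m:
            for i in active:
                cov_i = run_cov[i] / (n_seen - 1)
                prop = sd * cov_i + sd * 1e-10 * np.eye(m)
                try:
                    chols[i] = np.linalg.cholesky(prop)
                except np.linalg.LinAlgError:
                    chols[i] = np.linalg.cholesky(prop + 1e-8 * np.eye(m))

        # (b) beta | effective, psi  (flat prior: normal around the mean)
        beta = gibbs_beta(effective, psi, rng)

        # (c) psi | effective, beta  (Inverse-Wishart)
        psi = gibbs_psi(effective, beta, priors, rng)
        try:
            psi_chol = np.linalg.cholesky(psi)
        except np.linalg.LinAlgError:
            psi = psi + 1e-10 * np.eye(m)
            psi_chol = np.linalg.cholesky(psi)
        psi_inv = np.linalg.inv(psi)

        # (d) sigma2 | residuals  (Inverse-Gamma); stiff patients excluded
        sigma2 = gibbs_sigma2(float(ssr[active].sum()), n_obs_active, priors, rng)

        if it >= burn and (it - burn) % thin == 0:
            kept_beta.append(beta.copy())
            kept_eff.append(effective.copy())
            kept_sigma2.append(sigma2)
            kept_psi.append(psi.copy())

    return Chain(
        varying=spec.varying,
        beta=np.array(kept_beta),
        effective=np.array(kept_eff),
        sigma2=np.array(kept_sigma2),
        psi=np.array(kept_psi),
        acceptance=accepts / max(proposals, 1),
        seed=seed,
        n_iter=n_iter,
        burn=burn,
        stiff=stiff,
    )


# ---------------------------------------------------------------------------
# Summaries and diagnostics
# ---------------------------------------------------------------------------


def summarize_posterior(
    chain: Chain, spec: MixedEffectsSpec | None = None
) -> pd.DataFrame:
    """Population and individual-level parameter table.

    Population value = posterior mean of beta.  The individual-level spread
    columns (min/max/mean/median/sd) are computed across the per-patient
    posterior means of the effective parameters.  Fixed parameters are
    echoed with zero spread.
    """
    if chain.n_kept == 0:
        raise ValueError("chain holds no post-burn-in samples")
    spec = spec or MixedEffectsSpec(varying=chain.varying)
    eff_means = chain.effective.mean(axis=0)  # (N, m)
    rows = []
    for p in PARAM_NAMES:
        if p in chain.varying:
            k = chain.varying.index(p)
            vals = eff_means[:, k]
            rows.append(
                {
                    "parameter": p,
                    "population": float(chain.beta[:, k].mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "mean": float(vals.mean()),
                    "median": float(np.median(vals)),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "fixed": False,
                }
            )
        else:
            v = float(spec.fixed_values[p])
            rows.append(
                {
                    "parameter": p,
                    "population": v,
                    "min": v,
                    "max": v,
                    "mean": v,
                    "median": v,
                    "sd": 0.0,
                    "fixed": True,
                }
            )
    return pd.DataFrame(rows)


def _spectral_variance_at_zero(x: np.ndarray) -> float:
    """Newey-West estimate of the long-run variance of a (weakly stationary)
    scalar chain segment."""
    n = len(x)
    x = x - x.mean()
    gamma0 = float(x @ x) / n
    lags = max(int(n ** (1.0 / 3.0)), 1)
    s = gamma0
    for k in range(1, min(lags, n - 1) + 1):
        gk = float(x[k:] @ x[:-k]) / n
        s += 2.0 * (1.0 - k / (lags + 1.0)) * gk
    return max(s, 1e-300)


def geweke_z(x: np.ndarray, first: float = 0.10, last: float = 0.50) -> float:
    """Geweke convergence statistic: standardized difference between the
    means of the first 10% and last 50% of the chain, with long-run
    (spectral) variances."""
    n = len(x)
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    if np.ptp(x) == 0.0:
        return 0.0
    va = _spectral_variance_at_zero(a) / len(a)
    vb = _spectral_variance_at_zero(b) / len(b)
    return float((a.mean() - b.mean()) / math.sqrt(va + vb))


def convergence_diagnostics(chain: Chain) -> pd.DataFrame:
    """Geweke z and effective sample size for every scalar of interest.

    |z| > 2 flags a scalar whose early and late chain segments disagree;
    constant scalars get an undefined ESS flag instead of a value.
    """
    if chain.n_kept < 200:
        raise ValueError("diagnostics need at least 200 post-burn-in samples")
    import arviz as az

    rows = []
    for name, x in chain.scalar_samples().items():
        constant = bool(np.ptp(x) == 0.0)
        if constant:
            z, ess = 0.0, float("nan")
        else:
            z = geweke_z(x)
            ess = float(az.ess(az.convert_to_dataset({name: x[None, :]}))[name])
        rows.append(
            {
                "scalar": name,
                "geweke_z": z,
                "flagged": bool(abs(z) > 2.0),
                "ess": ess,
                "constant": constant,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["mean_acceptance"] = float(chain.acceptance.mean())
    return out
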