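"""Normal-approximation frequency likelihood, constrained MLE, Fisher standard
errors, and the relative-sensitivity statistic.

Exact likelihoods of multi-type branching counts are intractable, and sacrifice
sampling means counts at different steps come from different animals.  The
likelihood therefore treats each animal's relative-frequency vector f (over the
measured organ x generation categories) as approximately normal with the
delta-method mean ``pi(n)`` and covariance ``Omega(n)`` implied by the model at
that animal's step.  ``Omega`` is singular (frequencies sum to one), so one
category is dropped per scope before inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize

from .data import ObservedDataset
from .model import (
    ModelParameters,
    NetworkTopology,
    PopulationState,
    THETA_NAMES,
    build_type_space,
    default_topology,
    offspring_mean_matrix,
    validate_parameters,
)
from .moments import MomentOperators, frequency_moments, propagate_moments

__all__ = [
    "InferenceConfig",
    "FitResult",
    "SensitivityProfile",
    "FitError",
    "negative_log_likelihood",
    "gaussian_frequency_nll",
    "fit_mle",
    "fisher_standard_errors",
    "relative_sensitivity",
    "scale_profile",
    "initial_state_from_data",
]

_LOG_2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class InferenceConfig:
    """Structural constants and numerical knobs of the likelihood and fit."""

    topology: NetworkTopology = field(default_factory=default_topology)
    p: int = 7
    dt_hours: float = 4.0
    migrating_generations: frozenset = frozenset({1, 2, 3})
    proliferate_in_transit: bool = False
    divide_at_cap: bool = True
    scope: str = "global"  # "global": one frequency vector per animal; "per_organ"
    omega_jitter: float = 1e-10  # trace-scaled ridge added before inversion
    n_starts: int = 20
    ftol: float = 1e-8
    maxiter: int = 300
    bound_margin: float = 1e-6
    renormalize_rho_in_sensitivity: bool = False

    def make_parameters(self, theta: Sequence[float]) -> ModelParameters:
        t = np.asarray(theta, dtype=float)
        return ModelParameters(
            gamma=(t[1], t[3], t[5]),
            delta=(t[0], t[2], t[4]),
            m=t[6],
            rho={"SPL": t[7], "ILN": t[8], "MLN": t[9]},
            dt_hours=self.dt_hours,
            p=self.p,
            migrating_generations=self.migrating_generations,
            proliferate_in_transit=self.proliferate_in_transit,
            divide_at_cap=self.divide_at_cap,
        )


@dataclass
class FitResult:
    theta: dict[str, float]
    se: dict[str, float]
    nll: float
    converged: bool
    n_starts: int
    start_diagnostics: list[dict]
    singular_information: bool = False
    rho_identifiable: bool = True

    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[k] for k in THETA_NAMES])


@dataclass
class SensitivityProfile:
    parameter: str
    delta_grid: np.ndarray
    values: np.ndarray

    def summary(self) -> float:
        """Mean |S| over the grid; the per-parameter sensitivity score."""
        return float(np.mean(np.abs(self.values)))


def initial_state_from_data(data: ObservedDataset, config: InferenceConfig
                            ) -> PopulationState:
    """Deterministic initial condition: mean draining-node generation counts
    over the step-0 animals, rounded to integers."""
    ts = build_type_space(config.topology, config.p)
    vec = np.zeros(ts.size)
    src_counts = data.mean_source_counts(0)
    for i in range(config.p + 1):
        vec[ts.index(config.topology.source, i)] = round(src_counts[i])
    return PopulationState(n=0, counts=vec, type_space=ts)


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Caches everything theta-independent: observed frequency vectors per
    step/scope and the structurally reachable measurement categories."""

    def __init__(
        self,
        data: ObservedDataset,
        initial: PopulationState,
        config: InferenceConfig,
        allow_unnormalized_rho: bool = False,
    ):
        self.config = config
        self.initial = initial
        self.allow_unnormalized_rho = allow_unnormalized_rho
        self.type_space = initial.type_space
        self.max_step = max(data.steps) if len(data.steps) else 0
        self._reach = self._reachable_sets()
        # blocks: list of (step n, category index array, category labels,
        #                  observed frequency matrix (animals x k))
        self.blocks = self._build_blocks(data)

    def _reachable_sets(self) -> list[np.ndarray]:
        """Support of the mean vector at each step, assuming all rates positive.

        Uses a strictly positive placeholder parameter set so the support
        pattern (hence the active category set) does not depend on theta; this
        keeps the likelihood continuous during optimization.
        """
        cfg = self.config
        placeholder = cfg.make_parameters(
            [0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 1 / 3, 1 / 3, 1 / 3]
        )
        A = offspring_mean_matrix(placeholder, cfg.topology, self.type_space) > 0
        support = self.initial.counts > 0
        out = [support.copy()]
        for _ in range(self.max_step):
            support = (A.T @ support) > 0
            out.append(support.copy())
        return out

    def _build_blocks(self, data: ObservedDataset):
        cfg = self.config
        ts = self.type_space
        measured = set(cfg.topology.measured_compartments)
        blocks = []
        for n in data.steps:
            if n == 0:
                # the initial state is treated as deterministic: Omega(0) = 0,
                # so step-0 animals carry no likelihood information
                continue
            reach = self._reach[n]
            if cfg.scope == "global":
                organ_groups = [tuple(cfg.topology.measured_compartments)]
            elif cfg.scope == "per_organ":
                organ_groups = [(o,) for o in cfg.topology.measured_compartments]
            else:
                raise ValueError(f"unknown scope {cfg.scope!r}")
            for organs in organ_groups:
                cats, idx = [], []
                for k, (comp, gen) in enumerate(ts.types):
                    if comp in organs and comp in measured and reach[k]:
                        cats.append((comp, gen))
                        idx.append(k)
                if len(cats) < 2:
                    continue  # a single category has frequency 1 identically
                freqs = []
                for a in data.animals_at(n):
                    z = data.count_vector(a, cats)
                    tot = z.sum()
                    if tot <= 0:
                        continue  # zero-cell scope skipped
                    freqs.append(z / tot)
                if not freqs:
                    continue
                blocks.append((n, np.array(idx), tuple(cats), np.array(freqs)))
        return blocks

    def nll(self, theta: Sequence[float]) -> float:
        """Normal-approximation negative log likelihood of the frequencies."""
        cfg = self.config
        theta = np.asarray(theta, dtype=float)
        params = cfg.make_parameters(theta)
        violations = validate_parameters(params, cfg.topology)
        if self.allow_unnormalized_rho:
            violations = [
                v for v in violations if "splitting" not in v and "rho" not in v
            ]
        if violations:
            return math.inf
        try:
            ops = MomentOperators(
                params, cfg.topology, self.type_space,
                allow_unnormalized_rho=self.allow_unnormalized_rho,
            )
        except ValueError:
            return math.inf
        traj = propagate_moments(self.initial, params, cfg.topology,
                                 self.max_step, ops=ops)
        total = 0.0
        for n, idx, cats, F in self.blocks:
            state = traj[n]
            mu_s = state.mean[idx]
            if mu_s.sum() <= 0:
                continue  # zero predicted total: scope skipped
            fm = frequency_moments(state, idx, cats)
            if np.trace(fm.omega) <= 0:
                continue  # deterministic frequencies carry no information
            try:
                total += gaussian_frequency_nll(F, fm.pi, fm.omega, cfg.omega_jitter)
            except linalg.LinAlgError:
                return math.inf
        return total


def gaussian_frequency_nll(
    freqs: np.ndarray, pi: np.ndarray, omega: np.ndarray, jitter: float = 1e-10
) -> float:
    """Normal NLL of frequency vectors on the reduced (last-category-dropped)
    space: sum over rows f of 1/2 [(f - pi)' Omega_r^{-1} (f - pi)
    + log det(2 pi_circle Omega_r)].

    ``omega`` is the full singular frequency covariance; the last category is
    dropped to obtain a full-rank normal, and a trace-scaled ridge ``jitter``
    is added before inversion.
    """
    F = np.atleast_2d(np.asarray(freqs, dtype=float))
    pi = np.asarray(pi, dtype=float)
    k = len(pi) - 1
    if k < 1:
        return 0.0
    omega_r = np.asarray(omega, dtype=float)[:k, :k]
    tr = np.trace(omega_r)
    if tr <= 0:
        raise linalg.LinAlgError("frequency covariance is identically zero")
    omega_r = omega_r + (jitter * tr / k) * np.eye(k)
    cho = linalg.cho_factor(omega_r, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    resid = F[:, :k] - pi[:k]
    sols = linalg.cho_solve(cho, resid.T)
    quad = np.einsum("ij,ji->i", resid, sols)
    return 0.5 * float(np.sum(quad)) + 0.5 * F.shape[0] * (logdet + k * _LOG_2PI)


def negative_log_likelihood(
    theta: Sequence[float],
    data: ObservedDataset,
    initial: PopulationState,
    config: InferenceConfig | None = None,
    *,
    allow_unnormalized_rho: bool = False,
) -> float:
    """One-shot evaluation; build a :class:`LikelihoodEngine` for repeated calls."""
    config = config or InferenceConfig()
    engine = LikelihoodEngine(data, initial, config,
                              allow_unnormalized_rho=allow_unnormalized_rho)
    return engine.nll(theta)


# ---------------------------------------------------------------------------
# Constrained maximum likelihood
# ---------------------------------------------------------------------------

def _reduce(theta10: np.ndarray) -> np.ndarray:
    """10 reported parameters -> 9 free coordinates (rho_mes eliminated)."""
    return np.asarray(theta10, dtype=float)[:9].copy()


def _expand(x9: np.ndarray) -> np.ndarray:
    theta = np.empty(10)
    theta[:9] = x9
    theta[9] = 1.0 - x9[7] - x9[8]
    return theta


def _constraints(margin: float):
    return [
        {"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1]},            # gen 0
        {"type": "ineq", "fun": lambda x: 1.0 - x[2] - x[3] - x[6]},     # gen 1
        {"type": "ineq", "fun": lambda x: 1.0 - x[4] - x[5] - x[6]},     # gen >= 2
        {"type": "ineq", "fun": lambda x: 1.0 - margin - x[7] - x[8]},   # rho_mes > 0
    ]


def _feasible(x: np.ndarray, margin: float) -> bool:
    return (
        x[0] + x[1] <= 1.0
        and x[2] + x[3] + x[6] <= 1.0
        and x[4] + x[5] + x[6] <= 1.0
        and x[7] + x[8] <= 1.0 - margin
    )


def _draw_start(rng: np.random.Generator, margin: float) -> np.ndarray:
    while True:
        x = rng.uniform(margin, 1.0 - margin, size=9)
        if _feasible(x, margin):
            return x


def fit_mle(
    data: ObservedDataset,
    initial: PopulationState | None = None,
    config: InferenceConfig | None = None,
    seed: int = 0,
    theta0: Sequence[float] | None = None,
) -> FitResult:
    """Multi-start constrained minimization of the frequency NLL.

    theta is estimated on the reduced 9-dimensional parameterization
    (rho_mes = 1 - rho_spl - rho_il) under the box [0, 1] and the per-generation
    simplex constraints; the best of ``config.n_starts`` constrained-uniform
    starts (deterministic given ``seed``) is returned with Fisher standard
    errors.
    """
    config = config or InferenceConfig()
    informative_steps = [n for n in data.steps if len(data.animals_at(n))]
    if len(informative_steps) < 2:
        raise FitError(
            f"data must cover at least two time steps, got {informative_steps}"
        )
    if initial is None:
        initial = initial_state_from_data(data, config)
    engine = LikelihoodEngine(data, initial, config)
    margin = config.bound_margin
    bounds = [(margin, 1.0 - margin)] * 9

    def objective(x: np.ndarray) -> float:
        val = engine.nll(_expand(x))
        return val if math.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    starts = [_draw_start(rng, margin) for _ in range(config.n_starts)]
    if theta0 is not None:
        starts.insert(0, _reduce(np.asarray(theta0)))

    diagnostics, best = [], None
    for s, x0 in enumerate(starts):
        res = optimize.minimize(
            objective, x0, method="SLSQP", bounds=bounds,
            constraints=_constraints(margin),
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        ok = bool(res.success) and math.isfinite(res.fun)
        diagnostics.append(
            {"start": s, "x0": list(map(float, x0)), "nll": float(res.fun),
             "success": ok, "message": str(res.message), "nit": int(res.nit)}
        )
        if ok and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("no optimizer start converged", diagnostics)

    theta_hat = _expand(np.asarray(best.x))
    se, singular = fisher_standard_errors(
        theta_hat, data, initial, config, _engine=engine, return_flag=True
    )

    sink_total = int(
        data.records.loc[
            data.records["organ"].isin(config.topology.sinks), "count"
        ].sum()
    )
    rho_identifiable = sink_total > 0
    theta_dict = dict(zip(THETA_NAMES, map(float, theta_hat)))
    se_dict = dict(zip(THETA_NAMES, map(float, se)))
    if not rho_identifiable:
        # no cell ever reached a sink: the splitting probabilities are
        # structurally non-identifiable and must not be reported as estimates
        for k in ("rho_spl", "rho_il", "rho_mes"):
            theta_dict[k] = math.nan
            se_dict[k] = math.nan
    return FitResult(
        theta=theta_dict,
        se=se_dict,
        nll=float(best.fun),
        converged=True,
        n_starts=len(starts),
        start_diagnostics=diagnostics,
        singular_information=singular,
        rho_identifiable=rho_identifiable,
    )


# ---------------------------------------------------------------------------
# Fisher standard errors
# ---------------------------------------------------------------------------

def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 0.05)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            fp_p = f(x + ei + ej)
            fp_m = f(x + ei - ej)
            fm_p = f(x - ei + ej)
            fm_m = f(x - ei - ej)
            H[i, j] = H[j, i] = (fp_p - fp_m - fm_p + fm_m) / (4.0 * h[i] * h[j])
    return H


def fisher_standard_errors(
    theta_hat: Sequence[float],
    data: ObservedDataset,
    initial: PopulationState,
    config: InferenceConfig | None = None,
    *,
    _engine: LikelihoodEngine | None = None,
    return_flag: bool = False,
):
    """Standard errors from the observed Fisher information (numerical Hessian
    of the NLL at theta_hat on the reduced 9-parameter space).

    rho_mes = 1 - rho_spl - rho_il, so its standard error follows by the delta
    method: Var(rho_mes) = Var(rho_spl) + Var(rho_il) + 2 Cov(rho_spl, rho_il).
    A non-positive-definite Hessian falls back to the pseudo-inverse and raises
    the ``singular`` flag.
    """
    config = config or InferenceConfig()
    engine = _engine or LikelihoodEngine(data, initial, config)
    x = _reduce(np.asarray(theta_hat, dtype=float))

    def f(z):
        val = engine.nll(_expand(z))
        return val if math.isfinite(val) else 1e12

    H = _numerical_hessian(f, x)
    singular = False
    try:
        if np.linalg.cond(H) > 1e12:
            raise linalg.LinAlgError("ill-conditioned information matrix")
        cov = linalg.inv(H)
        if np.any(np.diag(cov) < 0):
            raise linalg.LinAlgError("negative variance")
    except linalg.LinAlgError:
        cov = linalg.pinvh(H)
        singular = True
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    se9 = np.sqrt(var)
    var_mes = var[7] + var[8] + 2.0 * cov[7, 8]
    se = np.append(se9, math.sqrt(var_mes) if var_mes >= 0 else math.nan)
    if return_flag:
        return se, singular
    return se


# ---------------------------------------------------------------------------
# Relative sensitivity
# ---------------------------------------------------------------------------

def relative_sensitivity(
    theta_hat: Sequence[float],
    data: ObservedDataset,
    initial: PopulationState,
    index: int,
    config: InferenceConfig | None = None,
    n_grid: int = 21,
    *,
    _engine: LikelihoodEngine | None = None,
    nll_function=None,
) -> SensitivityProfile:
    """Relative sensitivity S(theta_i) of the optimized cost to one coordinate:

        S = (|L(theta + d e_i) - L(theta)| / |L(theta)|) / (|d| / theta_i)

    evaluated on a symmetric grid d in [-0.1 theta_i, 0.1 theta_i] (the d = 0
    point, where S is 0/0, is excluded).  The perturbation is applied to the
    single coordinate as-is: perturbing one splitting probability deliberately
    leaves the rho simplex unnormalized unless
    ``config.renormalize_rho_in_sensitivity`` is set, in which case rho is
    rescaled to sum to one for comparison.

    ``nll_function`` substitutes an arbitrary cost (used by the unit toys).
    """
    config = config or InferenceConfig()
    theta_hat = np.asarray(theta_hat, dtype=float)
    if not (0 <= index < len(theta_hat)):
        raise IndexError(f"parameter index {index} outside 0..{len(theta_hat) - 1}")
    if nll_function is None:
        engine = _engine or LikelihoodEngine(
            data, initial, config, allow_unnormalized_rho=True
        )
        nll_function = engine.nll
    L0 = nll_function(theta_hat)
    if L0 == 0 or not math.isfinite(L0):
        raise ZeroDivisionError(
            f"relative sensitivity undefined: L(theta_hat) = {L0}"
        )
    ti = theta_hat[index]
    grid = np.linspace(-0.1 * ti, 0.1 * ti, n_grid)
    grid = grid[grid != 0.0]
    values = np.empty(len(grid))
    for k, d in enumerate(grid):
        theta = theta_hat.copy()
        theta[index] += d
        if config.renormalize_rho_in_sensitivity and index >= 7:
            rho = theta[7:10]
            theta[7:10] = rho / rho.sum()
        L = nll_function(theta)
        values[k] = (abs(L - L0) / abs(L0)) / (abs(d) / abs(ti))
    return SensitivityProfile(
        parameter=THETA_NAMES[index] if index < len(THETA_NAMES) else f"theta_{index}",
        delta_grid=grid,
        values=values,
    )


def scale_profile(
    theta: Sequence[float],
    data: ObservedDataset,
    initial: PopulationState,
    config: InferenceConfig | None = None,
    c_grid: Sequence[float] = (0.8, 0.9, 1.0, 1.1, 1.2),
) -> np.ndarray:
    """Diagnostic: NLL along the uniform scaling (gamma, delta, m) -> c (gamma,
    delta, m), the direction in which per-organ mean frequencies are invariant
    and identification relies on across-organ mass and the noise level."""
    config = config or InferenceConfig()
    engine = LikelihoodEngine(data, initial, config)
    theta = np.asarray(theta, dtype=float)
    out = np.empty(len(c_grid))
    for k, c in enumerate(c_grid):
        t = theta.copy()
        t[:7] *= c
        out[k] = engine.nll(t)
    return out
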