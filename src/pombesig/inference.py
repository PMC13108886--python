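"""Likelihood, bounded least-squares initialisation and Metropolis MCMC.

The fit compares model predictions ``M(i)`` against measured means ``D(i)``
with per-point uncertainties ``sigma(i)`` under a joint Gaussian likelihood

    L_total = prod_i (2 pi sigma_i^2)^(-1/2) exp(-(M_i - D_i)^2 / (2 sigma_i^2))

computed in log space. ``sigma`` is treated as a standard deviation; zero or
missing values are floored at a fraction of the per-observable maximum mean
so every record contributes a proper density.

The fitting protocol mirrors the two-stage scheme used for this network:
a bounded nonlinear least-squares initial guess inside the box
``0.1 <= k_i <= 10``, refined by a Metropolis chain whose proposals multiply
every parameter by ``exp(r)`` with ``r ~ Normal(0, 0.01^2)``, run for
100,000 steps in production, keeping the highest-likelihood visit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import ModelVariant, compile_genotype, compile_system
from .parameters import DEFAULT_BOX, N_PARAMS, PARAM_NAMES, ParameterSet
from .simulate import (
    FIT_SOLVER,
    OBSERVABLES,
    SimulationError,
    SolverConfig,
    observables,
    simulate_compiled,
)

__all__ = [
    "TimeCourseDataset",
    "McmcConfig",
    "McmcResult",
    "InitialFitResult",
    "log_likelihood",
    "initial_fit",
    "mcmc_fit",
    "fit_pipeline",
]

logger = logging.getLogger("pombesig")

DATASET_COLUMNS = ("genotype", "observable", "hour", "mean", "sd", "n")

#: Fraction of the per-observable maximum mean used to floor zero/missing SDs.
SD_FLOOR_FRACTION = 0.05


class TimeCourseDataset:
    """Tidy (genotype, observable, hour, mean, sd, n) measurement records.

    On construction, non-finite or non-positive SDs are floored at
    ``floor_frac * max(|mean|)`` per observable (the raw values are kept in
    the ``sd_raw`` column). Record order is irrelevant to the likelihood.
    """

    def __init__(self, records: pd.DataFrame, floor_frac: float = SD_FLOOR_FRACTION):
        df = pd.DataFrame(records).copy()
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        df = df[list(DATASET_COLUMNS)].reset_index(drop=True)
        df["hour"] = df["hour"].astype(float)
        df["mean"] = df["mean"].astype(float)
        df["sd_raw"] = df["sd"].astype(float)
        for obs, grp in df.groupby("observable"):
            floor = floor_frac * float(np.abs(grp["mean"]).max())
            if floor <= 0:
                floor = floor_frac  # degenerate all-zero panel
            sd = grp["sd_raw"].to_numpy(copy=True)
            bad = ~np.isfinite(sd) | (sd < floor)
            sd[bad] = floor
            df.loc[grp.index, "sd"] = sd
        bad_obs = set(df["observable"]) - set(OBSERVABLES)
        if bad_obs:
            raise ValueError(f"unknown observables in dataset: {sorted(bad_obs)}")
        for g in df["genotype"].unique():
            compile_genotype(g)  # raises on unresolvable labels
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.df["genotype"]))

    @classmethod
    def from_csv(cls, path, floor_frac: float = SD_FLOOR_FRACTION) -> "TimeCourseDataset":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # re-raise with file context
            raise ValueError(f"cannot parse dataset CSV {path}: {exc}") from exc
        return cls(df, floor_frac=floor_frac)

    def to_csv(self, path) -> None:
        self.df[list(DATASET_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


class _Evaluator:
    """Precompiled data → residual/likelihood machinery.

    Groups records by genotype so each likelihood evaluation costs one ODE
    solve per genotype.
    """

    def __init__(self, data: TimeCourseDataset, variant, solver: SolverConfig = FIT_SOLVER):
        self.variant = ModelVariant.coerce(variant)
        self.solver = solver
        df = data.df
        self.D = df["mean"].to_numpy()
        self.sigma = df["sd"].to_numpy()
        self.norm_const = float(np.sum(-0.5 * np.log(2 * np.pi * self.sigma**2)))
        self.groups = []
        for geno, grp in df.groupby("genotype", sort=False):
            hours = np.unique(grp["hour"].to_numpy())
            hour_pos = {h: i for i, h in enumerate(hours)}
            rows = grp.index.to_numpy()
            obs_idx = np.array([OBSERVABLES.index(o) for o in grp["observable"]])
            h_idx = np.array([hour_pos[h] for h in grp["hour"]])
            self.groups.append((compile_genotype(geno), hours, rows, obs_idx, h_idx))
        self.n_records = len(df)

    def model_values(self, params: ParameterSet) -> np.ndarray:
        """M(i) for every record, in record order. Raises SimulationError."""
        M = np.empty(self.n_records)
        for geno, hours, rows, obs_idx, h_idx in self.groups:
            system = compile_system(params, self.variant, geno)
            traj = simulate_compiled(system, hours, self.solver)
            series = np.stack([traj.state(o) for o in OBSERVABLES])  # (3, n_hours)
            M[rows] = series[obs_idx, h_idx]
        return M

    def residuals(self, params: ParameterSet) -> np.ndarray:
        return (self.model_values(params) - self.D) / self.sigma

    def loglike(self, params: ParameterSet) -> float:
        try:
            M = self.model_values(params)
        except SimulationError as exc:
            logger.warning("likelihood: %s; returning -inf", exc)
            return -np.inf
        return self.norm_const - 0.5 * float(np.sum(((M - self.D) / self.sigma) ** 2))


def log_likelihood(
    params: ParameterSet,
    variant,
    data: TimeCourseDataset,
    solver: SolverConfig = FIT_SOLVER,
) -> float:
    """Joint Gaussian log-likelihood of ``data`` under the model.

    Returns ``sum_i [-0.5 log(2 pi sigma_i^2) - (M_i - D_i)^2/(2 sigma_i^2)]``
    with ``M`` from simulation; ``-inf`` (with a logged warning) if the
    integrator fails. Invariant under record reordering.
    """
    return _Evaluator(data, variant, solver).loglike(params)


# ---------------------------------------------------------------------------
# Bounded least-squares initialisation
# ---------------------------------------------------------------------------

@dataclass
class InitialFitResult:
    """Outcome of the multi-start bounded least-squares initialisation."""

    params: ParameterSet
    cost: float                  # 0.5 * sum of squared scaled residuals
    converged: bool
    start_costs: list[float] = field(default_factory=list)


def initial_fit(
    data: TimeCourseDataset,
    variant,
    bounds: tuple[float, float] = DEFAULT_BOX,
    seed: int = 0,
    n_starts: int = 5,
    free_params: Optional[Sequence[str]] = None,
    base: Optional[ParameterSet] = None,
    solver: SolverConfig = FIT_SOLVER,
    max_nfev: Optional[int] = None,
    include_base_start: bool = True,
) -> InitialFitResult:
    """Bounded nonlinear least squares on the scaled residuals (M-D)/sigma.

    Runs a seeded multi-start (log-uniform starting points inside the box,
    plus ``base`` itself when ``include_base_start``) and returns the best
    fit. Parameters outside ``free_params`` stay at their ``base`` value.
    Optimisation is performed in log-parameter space, which respects
    positivity and matches the multiplicative geometry of the box.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("invalid bounds box")
    ev = _Evaluator(data, variant, solver)
    base = base or ParameterSet.ones()
    names = list(free_params) if free_params is not None else list(PARAM_NAMES)
    free_ix = np.array([PARAM_NAMES.index(n) for n in names])
    rng = np.random.default_rng(seed)

    base_vec = np.clip(base.to_vector(), lo, hi)

    def to_params(logx: np.ndarray) -> ParameterSet:
        v = base_vec.copy()
        v[free_ix] = np.exp(logx)
        return ParameterSet(v)

    def fun(logx: np.ndarray) -> np.ndarray:
        # clip so near-divergent parameter regions stay finite for the solver
        try:
            r = ev.residuals(to_params(logx))
        except SimulationError:
            return np.full(ev.n_records, 1e6)
        return np.clip(np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6), -1e6, 1e6)

    starts = []
    if include_base_start:
        starts.append(np.log(base_vec[free_ix]))
    while len(starts) < max(n_starts, 1):
        starts.append(rng.uniform(np.log(lo), np.log(hi), size=free_ix.size))

    best = None
    start_costs = []
    for x0 in starts[: max(n_starts, 1)]:
        res = least_squares(
            fun, x0, bounds=(np.log(lo), np.log(hi)), method="trf",
            max_nfev=max_nfev, x_scale=1.0,
        )
        start_costs.append(float(res.cost))
        if best is None or res.cost < best.cost:
            best = res
    converged = bool(best.status > 0)
    if not converged:
        logger.warning("initial_fit: optimizer did not converge (status %s); "
                       "returning best iterate", best.status)
    return InitialFitResult(to_params(best.x), float(best.cost), converged, start_costs)


# ---------------------------------------------------------------------------
# Metropolis MCMC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcConfig:
    """Metropolis settings.

    ``steps`` defaults to the production protocol (100,000); scaled-down
    chains are used in tests. ``proposal_sd`` is the SD of the normal ``r``
    in the multiplicative proposal ``k' = k * exp(r)``. With
    ``joint_update`` (default) all parameters move each step; otherwise one
    randomly chosen parameter moves per step. ``bounds``, when set, rejects
    proposals outside the box. ``jacobian_correction`` enables the exact
    Metropolis-Hastings ratio for the multiplicative proposal; by default
    the plain likelihood ratio is used, as in the printed protocol.
    """

    steps: int = 100_000
    proposal_sd: float = 0.01
    seed: int = 0
    joint_update: bool = True
    free_params: Optional[tuple[str, ...]] = None
    bounds: Optional[tuple[float, float]] = None
    jacobian_correction: bool = False
    log_every: int = 1000

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.proposal_sd < 0:
            raise ValueError("proposal sd must be >= 0")


@dataclass
class McmcResult:
    """Chain of parameter vectors with per-step log-likelihoods.

    ``chain`` has ``steps + 1`` rows (the start state first); ``best`` is
    the highest-likelihood visit.
    """

    chain: np.ndarray            # (steps+1, 29)
    loglik: np.ndarray           # (steps+1,)
    accepted: np.ndarray         # (steps,) bool
    best_params: ParameterSet
    best_loglik: float
    config: McmcConfig

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean()) if self.accepted.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.chain, columns=list(PARAM_NAMES))
        df.insert(0, "logL", self.loglik)
        df.insert(0, "step", np.arange(len(self.loglik)))
        acc = np.concatenate([[True], self.accepted]) if self.accepted.size else [True]
        df.insert(2, "accepted", acc)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def mcmc_fit(
    start: ParameterSet,
    data: Optional[TimeCourseDataset] = None,
    variant=None,
    config: McmcConfig = McmcConfig(),
    loglike: Optional[Callable[[ParameterSet], float]] = None,
    solver: SolverConfig = FIT_SOLVER,
) -> McmcResult:
    """Metropolis refinement around ``start``.

    Either ``data`` + ``variant`` (the joint Gaussian likelihood) or an
    explicit ``loglike`` callable must be given; the callable form is the
    test hook for sampler-correctness checks against analytic targets.

    Each step proposes ``k_i' = k_i * exp(r_i)`` with i.i.d.
    ``r_i ~ Normal(0, proposal_sd^2)`` over the free parameters; a proposal
    with higher likelihood is always accepted, otherwise it is accepted
    with probability ``exp(delta logL)``. Multiplicative proposals keep all
    parameters positive for every chain state.
    """
    if loglike is None:
        if data is None or variant is None:
            raise ValueError("mcmc_fit needs either data+variant or a loglike callable")
        ev = _Evaluator(data, variant, solver)
        loglike = ev.loglike

    rng = np.random.default_rng(config.seed)
    free_names = config.free_params or PARAM_NAMES
    free_ix = np.array([PARAM_NAMES.index(n) for n in free_names])

    x = start.to_vector()
    ll = float(loglike(ParameterSet(x)))
    steps = config.steps
    chain = np.empty((steps + 1, N_PARAMS))
    loglik = np.empty(steps + 1)
    accepted = np.zeros(steps, dtype=bool)
    chain[0] = x
    loglik[0] = ll
    best_x, best_ll = x.copy(), ll

    for step in range(1, steps + 1):
        if config.joint_update:
            r = rng.normal(0.0, config.proposal_sd, size=free_ix.size)
            prop = x.copy()
            prop[free_ix] = x[free_ix] * np.exp(r)
        else:
            j = free_ix[rng.integers(free_ix.size)]
            r = rng.normal(0.0, config.proposal_sd)
            prop = x.copy()
            prop[j] = x[j] * math.exp(r)

        if config.bounds is not None and (
            np.any(prop[free_ix] < config.bounds[0]) or np.any(prop[free_ix] > config.bounds[1])
        ):
            ll_prop = -np.inf
        else:
            ll_prop = float(loglike(ParameterSet(prop)))

        if not np.isfinite(ll_prop):
            accept = not np.isfinite(ll)  # -inf -> -inf moves are allowed
        else:
            delta = ll_prop - ll if np.isfinite(ll) else np.inf
            if config.jacobian_correction:
                delta += float(np.sum(np.log(prop[free_ix]) - np.log(x[free_ix])))
            accept = delta >= 0 or rng.random() < math.exp(delta)
        if accept:
            x, ll = prop, ll_prop
            accepted[step - 1] = True
        chain[step] = x
        loglik[step] = ll
        if ll > best_ll:
            best_x, best_ll = x.copy(), ll
        if config.log_every and step % config.log_every == 0:
            logger.info("mcmc step %d/%d logL=%.4f best=%.4f acc=%.3f",
                        step, steps, ll, best_ll, accepted[:step].mean())

    return McmcResult(chain, loglik, accepted, ParameterSet(best_x), best_ll, config)


def fit_pipeline(
    data: TimeCourseDataset,
    variant,
    config: McmcConfig = McmcConfig(),
    init_kwargs: Optional[dict] = None,
    solver: SolverConfig = FIT_SOLVER,
) -> McmcResult:
    """Least-squares initial guess followed by Metropolis refinement.

    Deterministic given ``config.seed`` (the initialisation derives its own
    seed from it). The best-of-chain always includes the start, so the best
    log-likelihood is at least that of the initial guess.
    """
    init_kwargs = dict(init_kwargs or {})
    init_kwargs.setdefault("seed", config.seed)
    init_kwargs.setdefault("solver", solver)
    init = initial_fit(data, variant, **init_kwargs)
    logger.info("initial_fit cost=%.4f converged=%s", init.cost, init.converged)
    return mcmc_fit(init.params, data, variant, config, solver=solver)
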