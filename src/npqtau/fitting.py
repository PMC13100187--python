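"""Stepwise fitting of the quenching kinetics to lifetime snapshots.

The objective is the plain least-squares misfit over all snapshots and
datasets,

    δ²(θ) = Σ_datasets Σ_i (τ_exp(t_i) − τ_model(t_i, θ))²,

fitted directly in the lifetime domain.  Parameters are estimated
stepwise across genotypes of increasing complexity: the PsbS/VDE-less
double mutant isolates photoinhibition, the PsbS-less single mutant
adds qZ and the xanthophyll cycle, the VDE-less mutant adds the
violaxanthin and lutein qE channels, and the lutein-free and
ZEP-reduced mutants complete the Ant/Zea qE channels and the
lutein-free binding set; finally only the wild type's initial
violaxanthin pool is fitted.  Earlier-stage parameters stay frozen
during later stages, with an optional joint refinement pass at the end.
Rates are optimized in log10 space.  Each stage runs a seeded
population-based global search (differential evolution) followed by
bounded least-squares refinement; confidence intervals come from a
residual-resampling bootstrap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, least_squares, minimize

from .kinetics import EquilibriumError, SimulationError, initial_state, simulate
from .lifetime import DarkQuenchingError, k_rnr_from_dark, lifetime_series
from .light import parse_light_sequence
from .parameters import (
    KINETIC_NAMES,
    QUENCHING_NAMES,
    GenotypeSpec,
    KineticParameters,
    QuenchingRates,
    UnknownParameterError,
    apply_genotype,
)

#: Residual magnitude (ns) substituted per point when a simulation fails,
#: keeping the optimizer objective finite.
PENALTY_RESIDUAL = 1e3


@dataclass
class Dataset:
    """One genotype × light-sequence snapshot series with uncertainties."""

    genotype: str
    sequence: str  # sequence string, e.g. "5HL-10D-5HL"
    times: np.ndarray  # s (dark snapshots at t <= 0)
    tau: np.ndarray  # ns
    se: np.ndarray  # ns
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (self.times.shape == self.tau.shape == self.se.shape):
            raise ValueError("times/tau/se must have equal length")
        if np.any(self.se <= 0):
            raise ValueError("snapshot SE must be positive")
        if np.any(self.tau <= 0):
            raise ValueError("lifetimes must be positive")

    @property
    def key(self) -> str:
        return f"{self.genotype}:{self.sequence}"


@dataclass
class Stage:
    """One fitting stage: which genotypes constrain which free parameters."""

    name: str
    genotypes: tuple[str, ...]
    free: tuple[str, ...]


@dataclass
class StagePlan:
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for st in self.stages:
            if not st.free:
                raise ValueError(f"stage {st.name!r} frees no parameters")
            dup = seen & set(st.free)
            if dup:
                raise ValueError(
                    f"parameters {sorted(dup)} freed in more than one stage"
                )
            seen |= set(st.free)

    @property
    def all_free(self) -> tuple[str, ...]:
        return tuple(n for st in self.stages for n in st.free)


def default_stage_plan() -> StagePlan:
    """The stepwise protocol over the five training genotypes.

    Each dataset mainly constrains its own stage's parameters: the
    qI-only double mutant first, then the xanthophyll cycle and qZ from
    the PsbS-less mutant, the violaxanthin/lutein qE channels (and V
    binding) from the VDE-less mutant, and the Ant/Zea channels, their
    binding, and the lutein-free binding set from *lut2* and *zep2*;
    finally only the wild type's initial violaxanthin pool.
    """
    # kappa_qI is NOT fitted: alpha_qI is a dimensionless damaged fraction
    # that stays << 1 on the 20-minute timescale, so lifetime data only
    # constrain the product kappa_qI * k_qI; kappa_qI is therefore a fixed
    # scale convention (the model's photoinhibition-rate ceiling) and the
    # accumulation rates absorb the kinetics.
    return StagePlan(stages=(
        Stage("qI", ("npq4npq1",),
              ("k_qI_HL", "k_qI_laser")),
        Stage("qZ+VAZ", ("npq4",),
              ("k_va", "k_az", "k_za", "k_av", "kappa_qZ")),
        Stage("qE_V+qE_L", ("npq1",),
              ("k_pvf", "k_pvb", "k_qvf", "k_qvb", "kappa_QV",
               "k_qlf", "k_qlb", "kappa_QL")),
        Stage("qE_A+qE_Z+lut2", ("lut2", "zep2"),
              ("k_qaf", "k_qab", "kappa_QA", "k_qzf", "k_qzb", "kappa_QZ",
               "k_paf", "k_pab", "k_pzf", "k_pzb",
               "k_pvf_star", "k_pvb_star", "k_paf_star", "k_pab_star",
               "k_pzf_star", "k_pzb_star")),
        Stage("WT_V0", ("WT",), ("V_0_WT",)),
    ))


@dataclass
class FitConfig:
    """Optimizer sizes, tolerances and seeds for one fit."""

    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    de_popsize: int = 6  # DE population multiplier (popsize × dim individuals)
    de_maxiter: int = 20
    n_starts: int = 1  # extra seeded least-squares starts besides DE's best
    n_refine_cycles: int = 2  # max block-coordinate sweeps on the joint objective
    refine_global: bool = True  # allow global re-search in stalled sweeps
    n_restarts: int = 1  # independent protocol restarts (best final fit wins)
    # least_squares max_nfev counts trust-region iterations (finite-
    # difference Jacobian evaluations are extra), so these are iteration caps
    ls_max_nfev: int | None = 80
    refine_ls_max_nfev: int | None = None  # cap for block sweeps (default: ls cap)
    joint_max_nfev: int = 200
    joint_refine: bool = True
    weighted: bool = False  # 1/SE² weighting (off: plain least squares)
    rtol: float = 1e-6  # ODE tolerances during fitting
    atol: float = 1e-9

    @classmethod
    def fast(cls, seed: int = 0) -> "FitConfig":
        """Reduced search sizes that still close a zero-noise refit."""
        return cls(seed=seed, de_popsize=5, de_maxiter=12, n_starts=0,
                   n_refine_cycles=6, refine_global=True, n_restarts=2,
                   ls_max_nfev=250, joint_max_nfev=1500)

    @classmethod
    def recovery(cls, seed: int = 0) -> "FitConfig":
        """Cheaper settings for noisy-data fits (noise floors the
        attainable precision, so deep polishing is wasted)."""
        return cls(seed=seed, de_popsize=4, de_maxiter=10, n_starts=0,
                   refine_global=False, n_refine_cycles=1, n_restarts=1,
                   ls_max_nfev=30, refine_ls_max_nfev=10, joint_max_nfev=40,
                   rtol=1e-4, atol=1e-7)


# Bounds encode the known timescales of each process class within the
# 20-minute measurement window: xanthophyll interconversion over tens of
# seconds to tens of minutes, rapidly equilibrating antenna binding,
# quencher activation over tens of seconds to many minutes, and slow
# photoinhibition.  They are deliberately generous (≥3 decades) but not
# unbounded.
_DEFAULT_BOUNDS: list[tuple[tuple[str, ...], tuple[float, float]]] = [
    (("k_qI_HL", "k_qI_laser"), (1e-8, 1e-3)),
    (("kappa_qI",), (0.1, 20.0)),
    (("kappa_QV", "kappa_QA", "kappa_QZ", "kappa_QL"), (1e-3, 2.0)),
    (("kappa_qZ",), (1e-3, 1.0)),
    (("k_va", "k_az"), (1e-4, 0.1)),
    (("k_za", "k_av"), (1e-5, 0.05)),
    (("k_pvf", "k_paf", "k_pzf", "k_pvb", "k_pab", "k_pzb",
      "k_pvf_star", "k_paf_star", "k_pzf_star",
      "k_pvb_star", "k_pab_star", "k_pzb_star"), (1e-3, 1.0)),
    (("k_qvf", "k_qaf", "k_qzf", "k_qlf"), (1e-5, 0.5)),
    (("k_qvb", "k_qab", "k_qzb", "k_qlb"), (1e-4, 0.5)),
]


def default_bounds(name: str) -> tuple[float, float]:
    for names, b in _DEFAULT_BOUNDS:
        if name in names:
            return b
    if name.startswith("V_0_"):
        return (1.0, 100.0)
    return (1e-6, 50.0)  # fallback for unclassified rates


def _is_log(name: str) -> bool:
    return not name.startswith("V_0_")


def _to_internal(name: str, value: float) -> float:
    return np.log10(value) if _is_log(name) else value


def _from_internal(name: str, x: float) -> float:
    return 10.0 ** x if _is_log(name) else x


# ---------------------------------------------------------------------------
# model evaluation


def _split_theta(theta: dict[str, float]):
    kin_d, q_d, v0 = {}, {}, {}
    for name, value in theta.items():
        if name in KINETIC_NAMES:
            kin_d[name] = value
        elif name in QUENCHING_NAMES:
            q_d[name] = value
        elif name.startswith("V_0_"):
            v0[name[len("V_0_"):]] = value
        else:
            raise UnknownParameterError(f"unknown fit parameter {name!r}")
    return kin_d, q_d, v0


class ModelEvaluator:
    """Evaluates model lifetimes for datasets under a parameter vector.

    Owns the base parameter set, the genotype registry and per-dataset
    caches (parsed light profiles, clamped simulation grids).
    """

    def __init__(self, base_kinetic: KineticParameters,
                 base_quenching: QuenchingRates,
                 registry: dict[str, GenotypeSpec],
                 rtol: float = 1e-6, atol: float = 1e-9):
        self.base_kinetic = base_kinetic
        self.base_quenching = base_quenching
        self.registry = registry
        self.rtol = rtol
        self.atol = atol
        self._lights: dict[str, object] = {}

    def _light(self, seq: str):
        if seq not in self._lights:
            self._lights[seq] = parse_light_sequence(seq)
        return self._lights[seq]

    def tau_model(self, ds: Dataset, theta: dict[str, float]) -> np.ndarray:
        """Model τ at the dataset's snapshot times (t ≤ 0 clamps to dark)."""
        kin_d, q_d, v0 = _split_theta(theta)
        kin = dataclasses.replace(self.base_kinetic, **kin_d)
        q = dataclasses.replace(self.base_quenching, **q_d)
        g = self.registry[ds.genotype]
        if ds.genotype in v0:
            g = g.with_pigment("V_0", v0[ds.genotype])
        params = apply_genotype(kin, g)
        s0 = initial_state(g, params)
        q.k_rnr = k_rnr_from_dark(g.tau_dark0, s0, q)
        light = self._light(ds.sequence)
        clamped = np.clip(ds.times, 0.0, light.duration)
        grid = np.unique(clamped)
        traj = simulate(g, params, light, grid=grid,
                        rtol=self.rtol, atol=self.atol, y0=s0.to_vector())
        tau = lifetime_series(traj, q).tau
        return np.interp(clamped, grid, tau)

    def residuals(self, ds: Dataset, theta: dict[str, float],
                  weighted: bool = False) -> np.ndarray:
        try:
            model = self.tau_model(ds, theta)
        except (SimulationError, EquilibriumError, DarkQuenchingError,
                ValueError):
            return np.full(ds.times.size, PENALTY_RESIDUAL)
        r = model - ds.tau
        if weighted:
            r = r / ds.se
        return r


def objective_delta2(theta: dict[str, float], data: list[Dataset],
                     evaluator: ModelEvaluator,
                     weighted: bool = False) -> float:
    """δ²(θ): summed squared lifetime residuals over all datasets.

    Simulation failures contribute a large finite penalty per snapshot
    so the optimizer's running total stays defined.  Invariant to the
    ordering of ``data``.
    """
    total = 0.0
    for ds in data:
        r = evaluator.residuals(ds, theta, weighted=weighted)
        total += float(r @ r)
    return total


def per_dataset_rmsd(theta: dict[str, float], data: list[Dataset],
                     evaluator: ModelEvaluator) -> tuple[dict, dict]:
    """RMSD per dataset in the τ (ns) and 1/τ (ns⁻¹) domains."""
    rmsd_tau, rmsd_rate = {}, {}
    for ds in data:
        model = evaluator.tau_model(ds, theta)
        rmsd_tau[ds.key] = float(np.sqrt(np.mean((model - ds.tau) ** 2)))
        rmsd_rate[ds.key] = float(
            np.sqrt(np.mean((1.0 / model - 1.0 / ds.tau) ** 2)))
    return rmsd_tau, rmsd_rate


# ---------------------------------------------------------------------------
# optimizers


def global_then_local(objective, bounds: list[tuple[float, float]],
                      config: FitConfig | None = None,
                      x0: np.ndarray | None = None):
    """Seeded population-based global search, then local refinement.

    Differential evolution over the boxed space, polished with
    Nelder–Mead and then L-BFGS-B.  Deterministic for a fixed config
    seed.  Returns (x_best, f_best, trace) where trace records the
    best objective after each phase.
    """
    config = config or FitConfig()
    bounds = [tuple(b) for b in bounds]
    for lo, hi in bounds:
        if not np.isfinite(lo) or not np.isfinite(hi) or lo > hi:
            raise ValueError(f"invalid bounds ({lo}, {hi})")
    if all(lo == hi for lo, hi in bounds):
        x = np.array([lo for lo, _ in bounds])
        return x, float(objective(x)), [("collapsed", float(objective(x)))]

    trace = []
    result = differential_evolution(
        objective, bounds, seed=config.seed, maxiter=config.de_maxiter,
        popsize=config.de_popsize, init="sobol", tol=1e-8, polish=False,
        x0=x0,
    )
    if not np.isfinite(result.fun):
        raise RuntimeError("global search produced no finite objective")
    x, f = result.x, float(result.fun)
    trace.append(("differential_evolution", f))
    nm = minimize(objective, x, method="Nelder-Mead",
                  options={"maxfev": 200 * len(bounds), "fatol": 1e-12,
                           "xatol": 1e-10})
    if np.isfinite(nm.fun) and nm.fun <= f:
        x, f = np.clip(nm.x, [b[0] for b in bounds], [b[1] for b in bounds]), float(nm.fun)
    trace.append(("nelder_mead", f))
    lb = minimize(objective, x, method="L-BFGS-B", bounds=bounds)
    if np.isfinite(lb.fun) and lb.fun <= f:
        x, f = lb.x, float(lb.fun)
    trace.append(("l_bfgs_b", f))
    return x, f, trace


@dataclass
class FitResult:
    """Outcome of a stepwise fit."""

    theta: dict[str, float]
    kinetic: KineticParameters
    quenching: QuenchingRates
    v0: dict[str, float]
    delta2: float
    rmsd_tau: dict[str, float]
    rmsd_rate: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0
    n_penalized: int = 0
    stage_delta2: dict[str, float] = field(default_factory=dict)
    bootstrap_thetas: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ci.items():
            est = self.theta.get(name)
            if est is not None and not (lo <= est <= hi):
                raise ValueError(f"CI for {name} excludes the estimate")


def _internal_bounds(free: tuple[str, ...],
                     config: FitConfig) -> list[tuple[float, float]]:
    out = []
    for n in free:
        lo, hi = config.bounds.get(n, default_bounds(n))
        out.append((_to_internal(n, lo), _to_internal(n, hi)))
    return out


def _theta_from_x(free: tuple[str, ...], x: np.ndarray,
                  frozen: dict[str, float]) -> dict[str, float]:
    theta = dict(frozen)
    for n, xi in zip(free, x):
        theta[n] = _from_internal(n, float(xi))
    return theta


def _residual_vector(evaluator: ModelEvaluator, data: list[Dataset],
                     theta: dict[str, float], weighted: bool) -> np.ndarray:
    return np.concatenate([
        evaluator.residuals(ds, theta, weighted=weighted) for ds in data
    ])


def _stage_fit(evaluator: ModelEvaluator, data: list[Dataset],
               free: tuple[str, ...], frozen: dict[str, float],
               config: FitConfig, seed: int,
               x_start: np.ndarray | None = None,
               global_search: bool = True) -> tuple[dict[str, float], float]:
    """Optimize ``free`` parameters on ``data`` with the rest frozen.

    Internal coordinates are log10 for rates, linear for pools.  A small
    seeded differential-evolution pass locates the basin; bounded
    trust-region least squares refines it.  Returns the updated full
    theta and the stage δ².
    """
    int_bounds = _internal_bounds(free, config)
    lo = np.array([b[0] for b in int_bounds])
    hi = np.array([b[1] for b in int_bounds])

    def resid(x):
        return _residual_vector(
            evaluator, data, _theta_from_x(free, x, frozen), config.weighted)

    def scalar(x):
        r = resid(x)
        return float(r @ r)

    starts: list[np.ndarray] = []
    if x_start is not None:
        starts.append(np.clip(np.asarray(x_start, dtype=float), lo, hi))
    if global_search and config.de_maxiter > 0:
        de = differential_evolution(
            scalar, int_bounds, seed=seed, maxiter=config.de_maxiter,
            popsize=config.de_popsize, init="sobol", tol=1e-10, polish=False,
            x0=None if x_start is None else starts[0],
        )
        starts.append(de.x)
    rng = np.random.default_rng(seed + 1)
    for _ in range(config.n_starts):
        starts.append(lo + (hi - lo) * rng.random(len(free)))
    if not starts:
        starts.append(0.5 * (lo + hi))

    best_x, best_f = None, np.inf
    for x0 in starts:
        try:
            # diff_step well above the ODE-integration noise floor keeps
            # the finite-difference Jacobian meaningful
            ls = least_squares(
                resid, x0, bounds=(lo, hi), method="trf", x_scale="jac",
                diff_step=1e-3, xtol=3e-16, ftol=3e-16, gtol=1e-15,
                max_nfev=config.ls_max_nfev,
            )
        except Exception:
            continue
        f = float(2.0 * ls.cost)
        if f < best_f:
            best_x, best_f = ls.x, f
    if best_x is None:
        raise RuntimeError("all stage optimizations failed")
    return _theta_from_x(free, best_x, frozen), best_f


def training_datasets(data: list[Dataset],
                      genotypes: tuple[str, ...]) -> list[Dataset]:
    return [ds for ds in data if ds.genotype in genotypes]


def stepwise_fit(data: list[Dataset], plan: StagePlan | None = None,
                 config: FitConfig | None = None,
                 evaluator: ModelEvaluator | None = None,
                 base_kinetic: KineticParameters | None = None,
                 base_quenching: QuenchingRates | None = None,
                 registry: dict[str, GenotypeSpec] | None = None) -> FitResult:
    """Run the stepwise protocol and return the fitted parameter set.

    Stage parameters freeze in order; a final joint least-squares
    refinement over every freed parameter and all training datasets is
    on by default (the datasets were fitted in batches).  Deterministic
    for a fixed config seed.  Parameters not freed by any stage keep
    the values of the base kinetic/quenching set, which therefore acts
    as the structural scaffold (zeros stay zero; pool sizes stay put).
    """
    plan = plan or default_stage_plan()
    config = config or FitConfig()
    if evaluator is None:
        if base_kinetic is None or base_quenching is None or registry is None:
            raise ValueError("provide an evaluator or base parameters "
                             "+ registry")
        evaluator = ModelEvaluator(base_kinetic, base_quenching, registry,
                                   rtol=config.rtol, atol=config.atol)

    all_free = plan.all_free
    fit_data = training_datasets(
        data, tuple({g for st in plan.stages for g in st.genotypes}))
    noise_floor = float(sum(np.sum(ds.se ** 2) for ds in fit_data))

    def _one_protocol(seed: int) -> tuple[dict[str, float], dict[str, float], float]:
        # Neutralize every parameter any stage will fit: frozen values
        # seen by earlier stages are mid-bound placeholders, not the
        # base set's (possibly informative) values.  Structural
        # constants (zeros, pool sizes, anything no stage frees) still
        # come from the base set.
        theta: dict[str, float] = {}
        for n in all_free:
            lo, hi = _internal_bounds((n,), config)[0]
            theta[n] = _from_internal(n, 0.5 * (lo + hi))
        st_d2: dict[str, float] = {}
        for i, st in enumerate(plan.stages):
            stage_data = training_datasets(data, st.genotypes)
            if not stage_data:
                raise ValueError(f"no datasets for stage {st.name!r} "
                                 f"(genotypes {st.genotypes})")
            theta, f = _stage_fit(evaluator, stage_data, st.free, theta,
                                  config, seed=seed + 1000 * i)
            st_d2[st.name] = f
        f = objective_delta2(theta, fit_data, evaluator,
                             weighted=config.weighted)
        if config.joint_refine:
            # Joint refinement in batches: block-coordinate sweeps over
            # the stage blocks against ALL training datasets (stage-local
            # fits cannot pin directions that only cross-genotype data
            # constrain), each followed by a joint least-squares polish.
            # Cycles continue while the misfit sits above the noise floor
            # implied by the datasets' own SEs and still improves;
            # stalled cycles escalate to a warm global block re-search.
            joint_config = dataclasses.replace(
                config, ls_max_nfev=config.joint_max_nfev)
            sweep_config = dataclasses.replace(
                config,
                ls_max_nfev=config.refine_ls_max_nfev or config.ls_max_nfev)
            frozen_rest = {k: v for k, v in theta.items()
                           if k not in all_free}
            for cycle in range(max(config.n_refine_cycles, 0)):
                use_global = config.refine_global and cycle > 0
                for i, st in enumerate(plan.stages):
                    x_start = np.array(
                        [_to_internal(n, theta[n]) for n in st.free])
                    theta, _ = _stage_fit(
                        evaluator, fit_data, st.free, theta, sweep_config,
                        seed=seed + 7000 + 100 * cycle + i,
                        x_start=x_start, global_search=use_global)
                x_start = np.array(
                    [_to_internal(n, theta[n]) for n in all_free])
                theta, f_new = _stage_fit(
                    evaluator, fit_data, all_free, frozen_rest,
                    joint_config, seed=seed + 99 + cycle,
                    x_start=x_start, global_search=False)
                stalled = f_new > 0.98 * f
                f = f_new
                if stalled and cycle > 0:
                    break
            # The violaxanthin and lutein qE channels have near-identical
            # functional form in the VDE-less genotype, so block descent
            # can entrench a role swap between them.  If refinement
            # stalls above the noise floor, propose the explicitly
            # swapped channel assignment (a basin-hop move, as used for
            # label switching in mixture models) and keep the better fit.
            swap_pairs = (("k_qvf", "k_qlf"), ("k_qvb", "k_qlb"),
                          ("kappa_QV", "kappa_QL"))
            propose_swap = f > 2.0 * noise_floor or noise_floor > 0.01
            if propose_swap and all(
                    a in theta and b in theta for a, b in swap_pairs):
                theta_alt = dict(theta)
                for a, b in swap_pairs:
                    theta_alt[a], theta_alt[b] = theta[b], theta[a]
                for n in theta_alt:
                    lo, hi = config.bounds.get(n, default_bounds(n))
                    theta_alt[n] = min(max(theta_alt[n], lo), hi)
                f_alt = np.inf
                for cycle in range(2):
                    for i, st in enumerate(plan.stages):
                        x_start = np.array(
                            [_to_internal(n, theta_alt[n]) for n in st.free])
                        theta_alt, _ = _stage_fit(
                            evaluator, fit_data, st.free, theta_alt,
                            sweep_config, seed=seed + 8000 + 10 * cycle + i,
                            x_start=x_start, global_search=False)
                    x_start = np.array(
                        [_to_internal(n, theta_alt[n]) for n in all_free])
                    theta_alt, f_alt = _stage_fit(
                        evaluator, fit_data, all_free, frozen_rest,
                        joint_config, seed=seed + 98 + cycle,
                        x_start=x_start, global_search=False)
                    if f_alt < 2.0 * noise_floor:
                        break
                if f_alt < f:
                    theta, f = theta_alt, f_alt
        return theta, st_d2, f

    theta, stage_delta2, best_f = _one_protocol(config.seed)
    for r in range(1, max(config.n_restarts, 1)):
        if best_f < 0.9 * noise_floor:
            break  # clearly below the data's noise floor already
        theta_r, st_r, f_r = _one_protocol(config.seed + 555 * r)
        if f_r < best_f:
            theta, stage_delta2, best_f = theta_r, st_r, f_r

    delta2 = objective_delta2(theta, fit_data, evaluator,
                              weighted=config.weighted)
    rmsd_tau, rmsd_rate = per_dataset_rmsd(theta, fit_data, evaluator)
    kin_d, q_d, v0 = _split_theta(theta)
    return FitResult(
        theta=theta,
        kinetic=dataclasses.replace(evaluator.base_kinetic, **kin_d),
        quenching=dataclasses.replace(evaluator.base_quenching, **q_d),
        v0=v0,
        delta2=delta2,
        rmsd_tau=rmsd_tau,
        rmsd_rate=rmsd_rate,
        seed=config.seed,
        stage_delta2=stage_delta2,
    )


def bootstrap_ci(fit: FitResult, data: list[Dataset], n_boot: int,
                 seed: int, plan: StagePlan | None = None,
                 config: FitConfig | None = None,
                 evaluator: ModelEvaluator | None = None,
                 base_kinetic: KineticParameters | None = None,
                 base_quenching: QuenchingRates | None = None,
                 registry: dict[str, GenotypeSpec] | None = None,
                 max_nfev: int = 30,
                 joint_max_nfev: int = 20) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap 95% intervals per parameter.

    Per replicate, each dataset's residuals around the fitted model are
    resampled with replacement and added back to the model curve; the
    stepwise stages are then re-optimized (warm-started from the point
    estimate, local refinement only) on the resampled data, followed by
    a capped joint least-squares pass over all parameters and datasets
    so that cross-genotype (ridge) uncertainty is expressed.  Percentile
    2.5/97.5 intervals are attached to ``fit.ci``.  Replicates whose
    refit fails are dropped (with their count reported); more than 50%
    failures is an error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    plan = plan or default_stage_plan()
    config = config or FitConfig()
    if evaluator is None:
        if base_kinetic is None or base_quenching is None or registry is None:
            raise ValueError("provide an evaluator or base parameters "
                             "+ registry")
        evaluator = ModelEvaluator(base_kinetic, base_quenching, registry,
                                   rtol=config.rtol, atol=config.atol)
    boot_config = dataclasses.replace(config, de_maxiter=0, n_starts=0,
                                      ls_max_nfev=max_nfev)

    fit_data = training_datasets(
        data, tuple({g for st in plan.stages for g in st.genotypes}))
    models = {ds.key: evaluator.tau_model(ds, fit.theta) for ds in fit_data}
    residuals = {ds.key: ds.tau - models[ds.key] for ds in fit_data}

    rng = np.random.default_rng(seed)
    thetas: list[dict[str, float]] = []
    failures = 0
    for _ in range(n_boot):
        resampled = []
        for ds in fit_data:
            r = residuals[ds.key]
            idx = rng.integers(0, r.size, size=r.size)
            tau_new = np.clip(models[ds.key] + r[idx], 1e-3, None)
            resampled.append(dataclasses.replace(ds, tau=tau_new))
        try:
            theta_b: dict[str, float] = {}
            for i, st in enumerate(plan.stages):
                st_data = training_datasets(resampled, st.genotypes)
                x_start = np.array(
                    [_to_internal(n, fit.theta[n]) for n in st.free])
                theta_b, _ = _stage_fit(
                    evaluator, st_data, st.free, theta_b, boot_config,
                    seed=seed + i, x_start=x_start, global_search=False)
            all_free = plan.all_free
            x_start = np.array(
                [_to_internal(n, theta_b[n]) for n in all_free])
            theta_b, _ = _stage_fit(
                evaluator, resampled, all_free,
                {k: v for k, v in theta_b.items() if k not in all_free},
                dataclasses.replace(boot_config, ls_max_nfev=joint_max_nfev),
                seed=seed + 71, x_start=x_start, global_search=False)
            thetas.append(theta_b)
        except Exception:
            failures += 1
    if failures > 0.5 * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap refits failed")

    ci: dict[str, tuple[float, float]] = {}
    for name in plan.all_free:
        values = np.array([t[name] for t in thetas])
        lo, hi = np.percentile(values, [2.5, 97.5])
        est = fit.theta[name]
        ci[name] = (float(min(lo, est)), float(max(hi, est)))
    fit.ci = ci
    fit.bootstrap_thetas = thetas
    return ci
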