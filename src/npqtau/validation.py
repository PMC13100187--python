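"""End-to-end validation experiments on synthetic data.

These are the package's own checks that the full pipeline — generator,
simulator, observable, stepwise fitting, prediction — closes on data
whose generating parameters are known:

* pipeline closure: a zero-noise synthetic study refit by the stepwise
  protocol reaches a vanishing misfit;
* parameter recovery: at experimental-scale noise, estimates of the
  practically identifiable parameters carry bootstrap intervals that
  cover the generating values;
* additivity: parameters trained on the five training genotypes predict
  the held-out wild type and double mutants at the noise floor;
* integrator cross-checks: the adaptive solver against a fixed-step RK4
  reference, plus pool-conservation drift;
* decay round trip: photon-count histograms refit to the generating
  amplitude-weighted lifetime without bias.

Problem sizes (seed counts, bootstrap sizes, optimizer budgets) are the
reduced defaults documented in the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import _integrate
from .decay import fit_decay, gaussian_irf
from .fitting import (
    FitConfig,
    FitResult,
    ModelEvaluator,
    bootstrap_ci,
    default_stage_plan,
    stepwise_fit,
)
from .genotypes import HELD_OUT_GENOTYPES, TRAINING_GENOTYPES
from .kinetics import initial_state, simulate
from .light import STANDARD_SEQUENCES, TRAINING_SEQUENCES, parse_light_sequence
from .parameters import apply_genotype
from .predict import predict
from .synth import ScenarioSpec, default_truth, synth_decay_histograms, synth_snapshot_series

#: Genotypes whose data enter the stepwise fit (training five + WT,
#: whose series only pins the documented V_0_WT).
FIT_GENOTYPES = TRAINING_GENOTYPES + ("WT",)

#: Per-replicate lifetime noise (ns) emulating typical whole-leaf error bars.
EXPERIMENTAL_SD = 0.04
REPLICATES = 3


def truth_theta(names=None):
    """Generating values for every fit parameter."""
    kin, q, _ = default_truth()
    plan = default_stage_plan()
    names = names or plan.all_free
    out = {}
    for n in names:
        if n.startswith("V_0_"):
            out[n] = dict(default_truth()[2][n[len("V_0_"):]].initial_pigments)["V_0"]
        elif hasattr(kin, n):
            out[n] = getattr(kin, n)
        else:
            out[n] = getattr(q, n)
    return out


def training_scenario(seed: int, noise_sd: float) -> ScenarioSpec:
    return ScenarioSpec(seed=seed, genotypes=FIT_GENOTYPES,
                        sequences=TRAINING_SEQUENCES, noise_sd=noise_sd,
                        n_replicates=REPLICATES)


# ---------------------------------------------------------------------------
# pipeline closure


def run_closure(seed: int, rtol: float = 1e-6, atol: float = 1e-9):
    """Refit zero-noise synthetic data; returns (delta2, FitResult)."""
    kin, q, reg = default_truth()
    data = synth_snapshot_series(training_scenario(seed=1, noise_sd=0.0))
    ev = ModelEvaluator(kin, q, reg, rtol=rtol, atol=atol)
    fit = stepwise_fit(data, config=FitConfig.fast(seed=seed), evaluator=ev)
    return fit.delta2, fit


# ---------------------------------------------------------------------------
# parameter recovery


def identifiable_parameters(sd_decades: float = 0.5) -> tuple[str, ...]:
    """Practically identifiable fit parameters, from the Fisher
    information of the generating model at the study noise level.

    A parameter is identifiable when its asymptotic standard deviation
    in log10 space (linear parameters converted to relative scale) stays
    within ``sd_decades`` — i.e. its 95% confidence range spans less
    than ~two decades (the usual practical-identifiability cut-off).
    Computed from the model structure and noise model alone, before any
    fitting.
    """
    from .fitting import _residual_vector, _theta_from_x, _to_internal

    kin, q, reg = default_truth()
    data = synth_snapshot_series(training_scenario(seed=1,
                                                   noise_sd=EXPERIMENTAL_SD))
    ev = ModelEvaluator(kin, q, reg, rtol=1e-6, atol=1e-9)
    truth = truth_theta()
    names = tuple(truth)
    x_t = np.array([_to_internal(n, truth[n]) for n in names])
    se = np.concatenate([ds.se for ds in data])

    def resid(x):
        return _residual_vector(ev, data, _theta_from_x(names, x, {}), False)

    r0 = resid(x_t)
    h = 1e-3
    J = np.empty((r0.size, len(names)))
    for j in range(len(names)):
        xp = x_t.copy()
        xp[j] += h
        J[:, j] = (resid(xp) - r0) / h
    Jw = J / se[:, None]
    sd = np.sqrt(np.diag(np.linalg.pinv(Jw.T @ Jw)))
    sd_dec = np.array([
        s if n.startswith(("k_", "kappa_")) else s / (truth[n] * np.log(10))
        for n, s in zip(names, sd)
    ])
    return tuple(n for n, s in zip(names, sd_dec) if s <= sd_decades)


@dataclass
class RecoveryResult:
    identifiable: tuple[str, ...]
    per_seed: list[dict] = field(default_factory=list)
    fits: list[FitResult] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        covered = sum(r["covered"] for r in self.per_seed)
        total = sum(r["total"] for r in self.per_seed)
        return covered / total if total else float("nan")


def run_recovery(seeds, n_boot: int = 5) -> RecoveryResult:
    """Fit noisy replicates of the study and check bootstrap coverage
    of the identifiable parameters."""
    kin, q, reg = default_truth()
    ident = identifiable_parameters()
    truth = truth_theta()
    result = RecoveryResult(identifiable=ident)
    for seed in seeds:
        data = synth_snapshot_series(
            training_scenario(seed=seed, noise_sd=EXPERIMENTAL_SD))
        cfg = FitConfig.recovery(seed=seed)
        ev = ModelEvaluator(kin, q, reg, rtol=cfg.rtol, atol=cfg.atol)
        fit = stepwise_fit(data, config=cfg, evaluator=ev)
        ci = bootstrap_ci(fit, data, n_boot=n_boot, seed=seed + 10_000,
                          config=cfg, evaluator=ev,
                          max_nfev=10, joint_max_nfev=25)
        covered = [n for n in ident if ci[n][0] <= truth[n] <= ci[n][1]]
        result.per_seed.append({
            "seed": seed, "delta2": fit.delta2,
            "covered": len(covered), "total": len(ident),
            "missed": [n for n in ident if n not in covered],
        })
        result.fits.append(fit)
    return result


# ---------------------------------------------------------------------------
# additivity / held-out prediction


def run_additivity(fit: FitResult, data_seed: int = 2001) -> dict:
    """Predict held-out genotypes with a fit trained on the five
    training genotypes; report RMSD relative to the snapshot noise floor
    (the standard error of the reported snapshot means)."""
    kin, q, reg = default_truth()
    spec = ScenarioSpec(seed=data_seed, genotypes=HELD_OUT_GENOTYPES,
                        sequences=("5HL-10D-5HL",),
                        noise_sd=EXPERIMENTAL_SD, n_replicates=REPLICATES)
    held_out = synth_snapshot_series(spec)
    noise_floor = EXPERIMENTAL_SD / np.sqrt(REPLICATES)
    out = {"noise_floor_ns": noise_floor, "per_genotype": {}}
    for ds in held_out:
        pred = predict(reg[ds.genotype], ds.sequence, fit, observed=ds,
                       rtol=1e-6, atol=1e-9)
        out["per_genotype"][ds.genotype] = {
            "rmsd_ns": pred.rmsd_tau,
            "rmsd_over_floor": pred.rmsd_tau / noise_floor,
        }
    out["max_rmsd_over_floor"] = max(
        v["rmsd_over_floor"] for v in out["per_genotype"].values())
    return out


# ---------------------------------------------------------------------------
# integrator oracle


@njit(cache=True)
def _rk4_phase(y, t0, t1, par, u, laser, dt):
    n = y.shape[0]
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    tmp = np.empty(n)
    t = t0
    while t < t1 - 1e-12:
        h = min(dt, t1 - t)
        _integrate.rhs(y, par, u, laser, k1)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * h * k1[i]
        _integrate.rhs(tmp, par, u, laser, k2)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * h * k2[i]
        _integrate.rhs(tmp, par, u, laser, k3)
        for i in range(n):
            tmp[i] = y[i] + h * k3[i]
        _integrate.rhs(tmp, par, u, laser, k4)
        for i in range(n):
            y[i] += h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        t += h
    return y


def rk4_reference(genotype, params, light, grid, dt: float = 1e-3):
    """Fixed-step classical RK4 solution at the grid times (oracle)."""
    par = _integrate.pack_params(params)
    y = initial_state(genotype, params).to_vector()
    edges = light.boundaries
    u_phases = [1.0 if lab == "HL" else 0.0 for lab, _ in light.phases]
    laser = 1.0 if light.laser_on else 0.0
    out = np.empty((len(grid), y.size))
    checkpoints = sorted(set(float(t) for t in grid) | set(edges))
    state = {}
    t_prev = 0.0
    for t in checkpoints:
        if t > t_prev:
            # integrate piecewise through any phase boundaries in (t_prev, t)
            seg = t_prev
            for (u, lo, hi) in zip(u_phases, edges[:-1], edges[1:]):
                a, b = max(seg, lo), min(t, hi)
                if b > a:
                    y = _rk4_phase(y, a, b, par, u, laser, dt)
                    seg = b
        state[t] = y.copy()
        t_prev = t
    for i, t in enumerate(grid):
        out[i] = state[float(t)]
    return out


def run_oracle_checks(dt: float = 1e-3, rtol: float = 1e-8,
                      atol: float = 1e-11) -> dict:
    """Adaptive vs RK4 agreement and conservation drift, all default
    genotypes × the three standard sequences."""
    kin, _, reg = default_truth()
    grid = np.arange(0.0, 1201.0, 120.0)
    max_rel = 0.0
    max_drift = 0.0
    n_cases = 0
    for gname, g in reg.items():
        p = apply_genotype(kin, g)
        for seq in STANDARD_SEQUENCES:
            light = parse_light_sequence(seq)
            traj = simulate(g, p, light, grid=grid, rtol=rtol, atol=atol)
            ref = rk4_reference(g, p, light, grid, dt=dt)
            scale = np.maximum(np.abs(ref), 1e-6)
            max_rel = max(max_rel,
                          float(np.max(np.abs(traj.states - ref) / scale)))
            max_drift = max(max_drift, traj.conservation_drift)
            n_cases += 1
    return {"max_rel_dev": max_rel, "max_conservation_drift": max_drift,
            "n_cases": n_cases}


# ---------------------------------------------------------------------------
# decay round trip


def run_decay_roundtrip(seed: int, n_replicates: int = 50,
                        counts_total: int = 100_000) -> dict:
    """Synthesize Poisson decay histograms and refit; reports the mean
    relative bias of the recovered amplitude-weighted lifetime."""
    comps = ((0.6, 0.4), (0.4, 1.8))
    errs = []
    for i in range(n_replicates):
        h, info = synth_decay_histograms(comps, counts_total=counts_total,
                                         seed=seed + i, bin_width_ps=4.0,
                                         window_ps=14_000.0)
        irf = gaussian_irf(h.bin_times)
        fit = fit_decay(h, irf)
        errs.append(fit.tau_avg / info["tau_avg"] - 1.0)
    errs = np.array(errs)
    return {"bias": float(errs.mean()), "spread": float(errs.std(ddof=1)),
            "n": n_replicates}


# ---------------------------------------------------------------------------
# qualitative orderings


def run_qualitative_checks() -> dict:
    """Effectiveness ordering, decomposition timing and dark-relaxation
    ordering under the default parameter set."""
    from .lifetime import decompose, k_rnr_from_dark, quenching_effectiveness

    kin, q, reg = default_truth()
    qeff = {X: quenching_effectiveness(kin, q, X)
            for X in ("QV", "QA", "QZ", "QL", "qZ")}

    g = reg["WT"]
    p = apply_genotype(kin, g)
    qq = q.copy()
    qq.k_rnr = k_rnr_from_dark(g.tau_dark0, initial_state(g, p), qq)
    light = parse_light_sequence("20HL")
    grid = np.arange(0.0, 1201.0, 5.0)
    dec = decompose(simulate(g, p, light, grid=grid), qq)

    def at(minute):
        i = int(np.searchsorted(grid, minute * 60.0))
        return {k: float(v[i]) for k, v in dec.components.items()}

    zea = {m: at(m)["qE_Z"] + at(m)["qZ"] for m in (1, 3, 5, 20)}
    lut_ant = {m: at(m)["qE_L"] + at(m)["qE_A"] for m in (1, 3, 5, 20)}
    others = {m: sum(at(m).values()) - lut_ant[m] for m in (1, 3, 5, 20)}

    # dark relaxation: fraction of each qE component left 1 min into dark
    light2 = parse_light_sequence("5HL-10D-5HL")
    grid2 = np.arange(0.0, 1201.0, 5.0)
    dec2 = decompose(simulate(g, p, light2, grid=grid2), qq)
    i_dark, i_1min = np.searchsorted(grid2, [300.0, 360.0])
    frac_left = {
        k: float(dec2.components[k][i_1min]
                 / max(dec2.components[k][i_dark], 1e-12))
        for k in ("qE_V", "qE_A", "qE_Z", "qE_L")
    }
    return {"qeff": qeff, "zea": zea, "lut_ant": lut_ant, "others": others,
            "dark_fraction_left": frac_left}
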