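"""Phenotype prediction: held-out genotypes and overexpression scans.

A fitted parameter set transfers across genotypes without refitting —
each mutation only zeroes or scales the rates its lesion removes, and
double mutants combine their parents' modifications — so wild-type and
double-mutant lifetime kinetics are predicted by composing genotype
specs and simulating (only a genotype's initial violaxanthin pool may
be supplied separately, mirroring pigment measurements).  Enzyme
overexpression is modeled by linearly scaling the corresponding rate
constants: VDE scales de-epoxidation, ZEP scales epoxidation, PsbS
scales the forward activation of every quencher including lutein's.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .fitting import Dataset, FitResult
from .genotypes import compose_double_mutant, get_genotype  # noqa: F401  (API)
from .kinetics import initial_state, simulate
from .lifetime import (
    Decomposition,
    LifetimeSeries,
    decompose,
    k_rnr_from_dark,
    lifetime_series,
)
from .light import parse_light_sequence
from .parameters import GenotypeSpec, KineticParameters, QuenchingRates, apply_genotype


@dataclass(frozen=True)
class OverexpressionSpec:
    """Expression multipliers relative to wild type (1.0 = WT)."""

    vde_factor: float = 1.0
    zep_factor: float = 1.0
    psbs_factor: float = 1.0

    def __post_init__(self) -> None:
        for f in (self.vde_factor, self.zep_factor, self.psbs_factor):
            if not np.isfinite(f) or f < 0:
                raise ValueError(f"expression factor {f} must be finite, >= 0")


@dataclass
class Prediction:
    """Simulated lifetimes + decomposition for one genotype × sequence."""

    genotype: str
    sequence: str
    series: LifetimeSeries
    decomposition: Decomposition
    rmsd_tau: float | None = None  # ns, vs observed series if provided
    rmsd_rate: float | None = None  # ns^-1


def predict(g: GenotypeSpec, sequence: str, fit: FitResult,
            observed: Dataset | None = None,
            v0_override: float | None = None,
            grid: np.ndarray | None = None,
            rtol: float = 1e-8, atol: float = 1e-11) -> Prediction:
    """Simulate a genotype under a sequence with fitted parameters.

    No refitting happens here: the fitted rates are applied through the
    genotype's declarative modifications.  A documented per-genotype
    initial violaxanthin pool may be supplied (``v0_override``, or a
    fitted value stored in ``fit.v0``).  When an observed snapshot
    series is given, RMSD against it is reported in both τ and 1/τ
    domains.
    """
    if v0_override is None:
        v0_override = fit.v0.get(g.name)
    if v0_override is not None:
        g = g.with_pigment("V_0", v0_override)
    light = parse_light_sequence(sequence)
    params = apply_genotype(fit.kinetic, g)
    s0 = initial_state(g, params)
    q = fit.quenching.copy()
    q.k_rnr = k_rnr_from_dark(g.tau_dark0, s0, q)

    if grid is None and observed is not None:
        grid = np.unique(np.clip(observed.times, 0.0, light.duration))
    traj = simulate(g, params, light, grid=grid, rtol=rtol, atol=atol,
                    y0=s0.to_vector())
    series = lifetime_series(traj, q, genotype=g.name)
    decomp = decompose(traj, q, genotype=g.name)

    rmsd_tau = rmsd_rate = None
    if observed is not None:
        clamped = np.clip(observed.times, 0.0, light.duration)
        model = np.interp(clamped, traj.times, series.tau)
        rmsd_tau = float(np.sqrt(np.mean((model - observed.tau) ** 2)))
        rmsd_rate = float(
            np.sqrt(np.mean((1.0 / model - 1.0 / observed.tau) ** 2)))
    return Prediction(genotype=g.name, sequence=sequence, series=series,
                      decomposition=decomp, rmsd_tau=rmsd_tau,
                      rmsd_rate=rmsd_rate)


def apply_overexpression(params: KineticParameters,
                         spec: OverexpressionSpec) -> KineticParameters:
    """Scale rate constants linearly with expression factors."""
    return dataclasses.replace(
        params,
        k_va=params.k_va * spec.vde_factor,
        k_az=params.k_az * spec.vde_factor,
        k_za=params.k_za * spec.zep_factor,
        k_av=params.k_av * spec.zep_factor,
        k_qvf=params.k_qvf * spec.psbs_factor,
        k_qaf=params.k_qaf * spec.psbs_factor,
        k_qzf=params.k_qzf * spec.psbs_factor,
        k_qlf=params.k_qlf * spec.psbs_factor,
    )


def overexpression_scan(spec: OverexpressionSpec, sequence: str,
                        fit: FitResult, wt: GenotypeSpec,
                        grid: np.ndarray | None = None,
                        rtol: float = 1e-8,
                        atol: float = 1e-11) -> Prediction:
    """Predict lifetimes for a VDE/ZEP/PsbS overexpression construct.

    Simulates wild-type baseline pigments with the scaled rate set;
    all factors at 1.0 reproduces the WT prediction exactly.
    """
    v0 = fit.v0.get(wt.name)
    if v0 is not None:
        wt = wt.with_pigment("V_0", v0)
    light = parse_light_sequence(sequence)
    params = apply_overexpression(apply_genotype(fit.kinetic, wt), spec)
    s0 = initial_state(wt, params)
    q = fit.quenching.copy()
    q.k_rnr = k_rnr_from_dark(wt.tau_dark0, s0, q)
    traj = simulate(wt, params, light, grid=grid, rtol=rtol, atol=atol,
                    y0=s0.to_vector())
    name = (f"{wt.name}+VDEx{spec.vde_factor:g}"
            f"+ZEPx{spec.zep_factor:g}+PsbSx{spec.psbs_factor:g}")
    return Prediction(genotype=name, sequence=sequence,
                      series=lifetime_series(traj, q, genotype=name),
                      decomposition=decompose(traj, q, genotype=name))


def fit_result_from_truth(kinetic: KineticParameters,
                          quenching: QuenchingRates,
                          v0: dict[str, float] | None = None) -> FitResult:
    """Wrap a known parameter set as a FitResult (for simulation-only use)."""
    return FitResult(theta={}, kinetic=kinetic.copy(),
                     quenching=quenching.copy(), v0=v0 or {},
                     delta2=float("nan"), rmsd_tau={}, rmsd_rate={})
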