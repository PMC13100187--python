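"""Stern–Volmer mapping from kinetic states to fluorescence lifetimes.

The amplitude-weighted chlorophyll-a fluorescence lifetime is the
reciprocal of a sum of decay channels,

    1/τ_F = k_rnr + Σ_X κ_QX·[QX] + κ_qZ·[Z] + κ_qI·α_qI,

where k_rnr collects all radiative and non-radiative decay not tied to
a modeled quencher and is anchored per genotype to the dark-acclimated
lifetime τ_dark(0).  Free zeaxanthin quenches light-independently (qZ);
activated complexes QV/QA/QZ/QL carry the PsbS-dependent qE components;
α_qI carries photoinhibition.  The same linear channels additively
decompose 1/τ into qE_V, qE_A, qE_Z, qE_L, qZ and qI contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import SpeciesState, Trajectory
from .light import LightProfile
from .parameters import KineticParameters, QuenchingRates

COMPONENTS = ("qE_V", "qE_A", "qE_Z", "qE_L", "qZ", "qI")


class DarkQuenchingError(ValueError):
    """Dark-state quenchers over-explain the measured dark lifetime."""


def k_rnr_from_dark(tau_dark0: float, s0: SpeciesState,
                    q: QuenchingRates) -> float:
    """Back out k_rnr (ns⁻¹) from the initial dark lifetime.

    Dark-acclimated states can already quench (constitutive free Zea in
    ZEP-deficient genotypes, carried-over α_qI), so those channels are
    subtracted rather than assuming a quencher-free dark state.
    """
    if not tau_dark0 > 0:
        raise ValueError("tau_dark0 must be positive")
    dark_quenching = (
        q.kappa_qZ * s0.Z
        + q.kappa_QV * s0.QV + q.kappa_QA * s0.QA
        + q.kappa_QZ * s0.QZ + q.kappa_QL * s0.QL
        + q.kappa_qI * s0.alpha_qI
    )
    k_rnr = 1.0 / tau_dark0 - dark_quenching
    if not k_rnr > 0:
        raise DarkQuenchingError(
            f"dark quenchers ({dark_quenching:.4f} ns^-1) over-explain "
            f"1/tau_dark(0) = {1.0 / tau_dark0:.4f} ns^-1"
        )
    return k_rnr


def total_quenching(s: SpeciesState, q: QuenchingRates) -> float:
    """Σ κ_QX·[QX] + κ_qZ·[Z] + κ_qI·α_qI in ns⁻¹."""
    return (
        q.kappa_QV * s.QV + q.kappa_QA * s.QA + q.kappa_QZ * s.QZ
        + q.kappa_QL * s.QL + q.kappa_qZ * s.Z + q.kappa_qI * s.alpha_qI
    )


def lifetime_from_state(s: SpeciesState, q: QuenchingRates) -> float:
    """τ_F (ns) of a single state; requires q.k_rnr to be set."""
    if q.k_rnr is None:
        raise ValueError("QuenchingRates.k_rnr is unset; derive it with "
                         "k_rnr_from_dark first")
    return 1.0 / (q.k_rnr + total_quenching(s, q))


@dataclass
class LifetimeSeries:
    """Amplitude-weighted lifetimes along a light sequence."""

    times: np.ndarray  # s
    tau: np.ndarray  # ns
    genotype: str = ""
    sequence: LightProfile | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.times.shape != self.tau.shape:
            raise ValueError("times and tau must have equal length")
        if np.any(self.tau <= 0):
            raise ValueError("lifetimes must be positive")


def lifetime_series(traj: Trajectory, q: QuenchingRates,
                    genotype: str = "") -> LifetimeSeries:
    """Apply the Stern–Volmer map pointwise along a trajectory."""
    if q.k_rnr is None:
        raise ValueError("QuenchingRates.k_rnr is unset")
    rate = q.k_rnr + (
        q.kappa_QV * traj.species("QV") + q.kappa_QA * traj.species("QA")
        + q.kappa_QZ * traj.species("QZ") + q.kappa_QL * traj.species("QL")
        + q.kappa_qZ * traj.species("Z") + q.kappa_qI * traj.species("alpha_qI")
    )
    return LifetimeSeries(times=traj.times, tau=1.0 / rate,
                          genotype=genotype, sequence=traj.light)


def npq_tau(series: LifetimeSeries, tau_dark0: float) -> np.ndarray:
    """Conventional NPQ_τ(t) = (τ_dark(0) − τ(t)) / τ(t).

    Provided for comparability with intensity-based NPQ literature only;
    the model is trained on lifetimes directly because NPQ_τ assumes
    zero initial quenching and turns nonlinear at strong quenching.
    """
    if not tau_dark0 > 0:
        raise ValueError("tau_dark0 must be positive")
    return (tau_dark0 - series.tau) / series.tau


@dataclass
class Decomposition:
    """Per-component contributions to 1/τ (ns⁻¹) along a trajectory.

    Exact additivity holds by construction:
    k_rnr + Σ components = 1/τ at every time point.
    """

    times: np.ndarray
    components: dict[str, np.ndarray]
    k_rnr: float
    genotype: str = ""
    metadata: dict = field(default_factory=dict)

    def total_rate(self) -> np.ndarray:
        return self.k_rnr + sum(self.components.values())

    def tau(self) -> np.ndarray:
        return 1.0 / self.total_rate()


def decompose(traj: Trajectory, q: QuenchingRates,
              genotype: str = "") -> Decomposition:
    """Split 1/τ − k_rnr into qE_V/qE_A/qE_Z/qE_L/qZ/qI channels."""
    if q.k_rnr is None:
        raise ValueError("QuenchingRates.k_rnr is unset")
    comps = {
        "qE_V": q.kappa_QV * traj.species("QV"),
        "qE_A": q.kappa_QA * traj.species("QA"),
        "qE_Z": q.kappa_QZ * traj.species("QZ"),
        "qE_L": q.kappa_QL * traj.species("QL"),
        "qZ": q.kappa_qZ * traj.species("Z"),
        "qI": q.kappa_qI * traj.species("alpha_qI"),
    }
    return Decomposition(times=traj.times, components=comps, k_rnr=q.k_rnr,
                         genotype=genotype,
                         metadata={"qZ_effectiveness_convention": "kappa_qZ"})


_QEFF_SPECIES = ("QV", "QA", "QZ", "QL", "qZ")


def quenching_effectiveness(params: KineticParameters, q: QuenchingRates,
                            X: str) -> float:
    """Per-molecule quenching effectiveness Q_eff of one species.

    Q_eff = (binding fraction) × (max activated fraction) × κ_QX, i.e.
    k_pxf/(k_pxf+k_pxb) · k_qxf/(k_qxf+k_qxb) · κ_QX.  Lutein is always
    antenna-bound, so its binding fraction is 1.  For the qZ channel the
    effectiveness is κ_qZ itself (free zeaxanthin quenches without
    binding or activation; convention recorded in output metadata).
    """
    if X not in _QEFF_SPECIES:
        raise ValueError(f"unknown species {X!r}; expected one of {_QEFF_SPECIES}")
    if X == "qZ":
        return q.kappa_qZ
    tag = X[1].lower()  # v/a/z/l
    kqf = getattr(params, f"k_q{tag}f")
    kqb = getattr(params, f"k_q{tag}b")
    if kqf + kqb == 0:
        raise ZeroDivisionError(f"activation rates for {X} are both zero")
    act = kqf / (kqf + kqb)
    if X == "QL":
        bind = 1.0
    else:
        kpf = getattr(params, f"k_p{tag}f")
        kpb = getattr(params, f"k_p{tag}b")
        if kpf + kpb == 0:
            raise ZeroDivisionError(f"binding rates for {X} are both zero")
        bind = kpf / (kpf + kpb)
    kappa = getattr(q, f"kappa_{X}")
    return bind * act * kappa
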