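"""The light-driven quenching ODE system and its integration.

Thirteen chemical species drive the model: free violaxanthin (V),
antheraxanthin (A) and zeaxanthin (Z); their antenna-bound complexes
PV/PA/PZ and the always-bound lutein complex PL; the light-activated
quenchers QV/QA/QZ/QL; and the VDE/ZEP enzymes, carried as degenerate
activity scalars.  A phenomenological photoinhibited fraction α_qI
completes the state.  De-epoxidation and quencher activation are gated
by the binary high-light indicator u(t); epoxidation runs regardless of
light; α_qI accumulates in high light and, more slowly, under the
detection laser, with no recovery on the 20-minute timescale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _integrate
from ._integrate import NSTATE, pack_params
from .light import LightProfile
from .parameters import GenotypeSpec, KineticParameters

_VEC_FIELDS = ("V", "A", "Z", "PV", "PA", "PZ", "PL",
               "QV", "QA", "QZ", "QL", "alpha_qI")


@dataclass
class SpeciesState:
    """Concentrations (mmol/mol Chl) of the model species at one instant."""

    V: float = 0.0
    A: float = 0.0
    Z: float = 0.0
    PV: float = 0.0
    PA: float = 0.0
    PZ: float = 0.0
    PL: float = 0.0
    QV: float = 0.0
    QA: float = 0.0
    QZ: float = 0.0
    QL: float = 0.0
    VDE_act: float = 1.0
    ZEP_act: float = 1.0
    alpha_qI: float = 0.0

    def __post_init__(self) -> None:
        for name in _VEC_FIELDS:
            if getattr(self, name) < -1e-12:
                raise ValueError(f"negative concentration {name}")
        if not 0.0 <= self.alpha_qI <= 1.0 + 1e-12:
            raise ValueError("alpha_qI must lie in [0, 1]")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _VEC_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray, VDE_act: float = 1.0,
                    ZEP_act: float = 1.0) -> "SpeciesState":
        d = {n: float(max(v, 0.0)) for n, v in zip(_VEC_FIELDS, y)}
        d["alpha_qI"] = float(min(max(y[-1], 0.0), 1.0))
        return cls(VDE_act=VDE_act, ZEP_act=ZEP_act, **d)

    @property
    def vaz_total(self) -> float:
        """Conserved VAZ pool: free + bound + activated V/A/Z."""
        return (self.V + self.A + self.Z + self.PV + self.PA + self.PZ
                + self.QV + self.QA + self.QZ)

    @property
    def lut_total(self) -> float:
        """Conserved lutein pool: PL + QL."""
        return self.PL + self.QL

    def copy(self) -> "SpeciesState":
        return dataclasses.replace(self)


def derivatives(s: SpeciesState, u: int, laser: int,
                params: KineticParameters) -> SpeciesState:
    """Pure-Python mass-action derivatives (reference implementation).

    Mirrors the compiled RHS in ``_integrate``; the two are checked
    against each other in the test suite.  Returns a SpeciesState whose
    fields hold d/dt values (enzyme scalars are constant).
    """
    p = params
    vde = u * p.VDE_act
    zep = p.ZEP_act
    f_va = p.k_va * vde * s.V
    f_az = p.k_az * vde * s.A
    f_za = p.k_za * zep * s.Z
    f_av = p.k_av * zep * s.A
    p_free = max(p.P_tot - s.PV - s.PA - s.PZ, 0.0)
    b_v = p.k_pvf * s.V * p_free - p.k_pvb * s.PV
    b_a = p.k_paf * s.A * p_free - p.k_pab * s.PA
    b_z = p.k_pzf * s.Z * p_free - p.k_pzb * s.PZ
    q_v = p.k_qvf * u * s.PV - p.k_qvb * s.QV
    q_a = p.k_qaf * u * s.PA - p.k_qab * s.QA
    q_z = p.k_qzf * u * s.PZ - p.k_qzb * s.QZ
    q_l = p.k_qlf * u * s.PL - p.k_qlb * s.QL
    out = SpeciesState.__new__(SpeciesState)
    out.V = -f_va + f_av - b_v
    out.A = f_va - f_az + f_za - f_av - b_a
    out.Z = f_az - f_za - b_z
    out.PV = b_v - q_v
    out.PA = b_a - q_a
    out.PZ = b_z - q_z
    out.PL = -q_l
    out.QV = q_v
    out.QA = q_a
    out.QZ = q_z
    out.QL = q_l
    out.VDE_act = 0.0
    out.ZEP_act = 0.0
    out.alpha_qI = (p.k_qI_HL * u + p.k_qI_laser * laser) * (1.0 - s.alpha_qI)
    return out


class EquilibriumError(RuntimeError):
    """Dark binding-equilibrium solve failed to converge."""


def binding_equilibrium(totals: dict[str, float],
                        params: KineticParameters) -> dict[str, float]:
    """Partition total V/A/Z pools into free and bound at equilibrium.

    Solves for the free antenna sites p such that each pigment satisfies
    detailed balance k_pxf·X·p = k_pxb·PX under the shared site budget
    P_tot.  Returns free and bound concentrations.
    """
    kf = {"V": params.k_pvf, "A": params.k_paf, "Z": params.k_pzf}
    kb = {"V": params.k_pvb, "A": params.k_pab, "Z": params.k_pzb}

    def bound(x: str, p: float) -> float:
        tot = totals[x]
        num = kf[x] * p
        den = kb[x] + num
        if den == 0.0:  # no binding kinetics at all
            return 0.0
        return tot * num / den

    P_tot = params.P_tot

    def g(p: float) -> float:
        return p + sum(bound(x, p) for x in "VAZ") - P_tot

    if P_tot == 0.0 or all(kf[x] == 0.0 for x in "VAZ"):
        p_free = P_tot
    else:
        try:
            p_free = brentq(g, 0.0, P_tot, xtol=1e-14, rtol=1e-14, maxiter=200)
        except (ValueError, RuntimeError) as exc:
            raise EquilibriumError(
                f"binding equilibrium failed: residual at bounds "
                f"g(0)={g(0.0):.3e}, g(P_tot)={g(P_tot):.3e}"
            ) from exc
    out = {"p_free": p_free}
    for x in "VAZ":
        out[f"P{x}"] = bound(x, p_free)
        out[x] = totals[x] - out[f"P{x}"]
    return out


def initial_state(g: GenotypeSpec, params: KineticParameters) -> SpeciesState:
    """Dark-acclimated state: quenchers off, binding at equilibrium.

    All QX are zero (activation is light-gated), the V/A/Z pools from
    the genotype's pigment table are partitioned between free and bound
    forms at the binding equilibrium, lutein is fully bound (PL = L_tot)
    and α_qI starts at zero.
    """
    pig = g.pigments
    totals = {"V": pig["V_0"], "A": pig["A_0"], "Z": pig["Z_0"]}
    eq = binding_equilibrium(totals, params)
    return SpeciesState(
        V=eq["V"], A=eq["A"], Z=eq["Z"],
        PV=eq["PV"], PA=eq["PA"], PZ=eq["PZ"],
        PL=params.L_tot,
        VDE_act=params.VDE_act, ZEP_act=params.ZEP_act,
    )


@dataclass
class Trajectory:
    """Solution of the kinetic system on an output time grid."""

    times: np.ndarray  # s, strictly increasing
    states: np.ndarray  # (n_times, 12) in _VEC_FIELDS order
    light: LightProfile

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, NSTATE):
            raise ValueError("states shape mismatch")

    def species(self, name: str) -> np.ndarray:
        """Time series of one species, by field name."""
        return self.states[:, _VEC_FIELDS.index(name)]

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState.from_vector(self.states[i])

    @property
    def conservation_drift(self) -> float:
        """Max relative drift of the VAZ and lutein pools."""
        vaz = self.states[:, 0:6].sum(axis=1) + self.states[:, 7:10].sum(axis=1)
        lut = self.states[:, 6] + self.states[:, 10]
        drift = 0.0
        for pool in (vaz, lut):
            if pool[0] > 0:
                drift = max(drift, float(np.max(np.abs(pool - pool[0])) / pool[0]))
        return drift


class SimulationError(RuntimeError):
    """ODE integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


def simulate(
    g: GenotypeSpec,
    params: KineticParameters,
    light: LightProfile,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-11,
    method: str = "rk45",
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the genotype's kinetics over a light sequence.

    ``grid`` defaults to a 1-s output grid over the full sequence and
    must lie within [0, duration].  Integration restarts at every phase
    boundary (event-exact binary light switching).  ``method`` selects
    the compiled adaptive RK45 backend (default) or scipy's ``lsoda``.
    Genotype modifications are expected to be applied to ``params``
    already (see :func:`npqtau.parameters.apply_genotype`).
    """
    duration = light.duration
    if grid is None:
        grid = np.arange(0.0, duration + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")
    if grid[0] < -1e-9 or grid[-1] > duration + 1e-9:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside light duration [0, {duration}]"
        )

    if y0 is None:
        y0 = initial_state(g, params).to_vector()
    par = pack_params(params)
    edges = light.boundaries
    u_phases = [1.0 if label == "HL" else 0.0 for label, _ in light.phases]
    laser = 1.0 if light.laser_on else 0.0

    if method == "rk45":
        try:
            states = _integrate.integrate_sequence(
                y0, par, edges, u_phases, laser, grid, rtol=rtol, atol=atol
            )
        except ValueError as exc:
            raise SimulationError(str(exc)) from exc
    elif method == "lsoda":
        states = np.empty((grid.size, NSTATE))
        y = np.array(y0, dtype=float)
        out = np.empty(NSTATE)

        for k, (u, lo, hi) in enumerate(zip(u_phases, edges[:-1], edges[1:])):
            mask = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
            inner = np.clip(grid[mask], lo, hi)
            has_end = inner.size > 0 and inner[-1] >= hi - 1e-12
            t_eval = inner if has_end else np.append(inner, hi)

            def f(t, yv, _u=u):
                _integrate.rhs(yv, par, _u, laser, out)
                return out.copy()

            sol = solve_ivp(f, (lo, hi), y, method="LSODA", t_eval=t_eval,
                            rtol=rtol, atol=atol)
            if not sol.success:
                raise SimulationError(
                    f"LSODA failed in phase {k}: {sol.message}",
                    last_time=float(sol.t[-1]) if sol.t.size else lo,
                )
            states[mask] = sol.y.T if has_end else sol.y.T[:-1]
            y = sol.y[:, -1]
    else:
        raise ValueError(f"unknown integration method {method!r}")

    return Trajectory(times=grid, states=states, light=light)
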