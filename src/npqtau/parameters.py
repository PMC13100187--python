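"""Kinetic rate parameters and their serialization.

Units used throughout the model: time in s, pigment concentrations in
mmol/mol Chl, fluorescence lifetimes in ns, quenching contributions to
1/τ in ns⁻¹.  Parameter files declare this unit system explicitly in a
``units`` block so files from other conventions are rejected rather than
silently misread.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

#: Canonical unit declaration for parameter files.
UNITS = {
    "time": "s",
    "concentration": "mmol/mol Chl",
    "lifetime": "ns",
    "quenching_rate_constant": "(mmol/mol Chl)^-1 ns^-1",
}


@dataclass
class KineticParameters:
    """All rate constants and pool sizes of the quenching kinetics.

    The xanthophyll cycle is V ⇌ A ⇌ Z: de-epoxidation (``k_va``,
    ``k_az``, VDE, light-gated) and epoxidation (``k_za``, ``k_av``,
    ZEP, light-independent).  Free xanthophylls bind antenna sites
    (X + P ⇌ PX, ``k_pxf``/``k_pxb``) and bound complexes activate to
    quenchers in light (PX ⇌ QX, ``k_qxf``/``k_qxb``); lutein is always
    bound (PL ⇌ QL).  ``alpha_qI`` (photoinhibited fraction) accumulates
    at ``k_qI_HL`` in high light and ``k_qI_laser`` under the detection
    laser alone.  The ``*_star`` set is the alternate antenna-binding
    parameterization used by lutein-free genotypes, whose destabilized
    LHCII trimers bind V/A/Z with different affinities and roughly half
    the sites.
    """

    # VAZ cycle (s^-1); de-epoxidation is light-gated, epoxidation is not
    k_va: float = 0.0
    k_az: float = 0.0
    k_za: float = 0.0
    k_av: float = 0.0
    # antenna binding, free X + P <-> PX ((mmol/mol Chl)^-1 s^-1 fwd, s^-1 bwd)
    k_pvf: float = 0.0
    k_pvb: float = 0.0
    k_paf: float = 0.0
    k_pab: float = 0.0
    k_pzf: float = 0.0
    k_pzb: float = 0.0
    # quencher activation, PX <-> QX (s^-1); forward is light-gated (PsbS)
    k_qvf: float = 0.0
    k_qvb: float = 0.0
    k_qaf: float = 0.0
    k_qab: float = 0.0
    k_qzf: float = 0.0
    k_qzb: float = 0.0
    k_qlf: float = 0.0
    k_qlb: float = 0.0
    # pool sizes (mmol/mol Chl)
    P_tot: float = 0.0
    L_tot: float = 0.0
    # photoinhibition accumulation (s^-1)
    k_qI_HL: float = 0.0
    k_qI_laser: float = 0.0
    # lutein-free (starred) antenna-binding set
    k_pvf_star: float = 0.0
    k_pvb_star: float = 0.0
    k_paf_star: float = 0.0
    k_pab_star: float = 0.0
    k_pzf_star: float = 0.0
    k_pzb_star: float = 0.0
    P_tot_star: float = 0.0
    # enzyme activity scalars (degenerate, always 1 by default; extension
    # point for explicit enzyme-state dynamics)
    VDE_act: float = 1.0
    ZEP_act: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"negative rate/pool {f.name}={v}")

    def copy(self) -> "KineticParameters":
        return dataclasses.replace(self)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


@dataclass
class QuenchingRates:
    """Stern–Volmer quenching rate constants mapping states to 1/τ.

    ``kappa_QX`` act on activated quencher concentrations [QX]
    ((mmol/mol Chl)⁻¹ ns⁻¹), ``kappa_qZ`` on free zeaxanthin, and
    ``kappa_qI`` (ns⁻¹) on the dimensionless photoinhibited fraction
    α_qI.  ``k_rnr`` (ns⁻¹) collects all other radiative/non-radiative
    decay; it is genotype-specific and derived from the dark-acclimated
    lifetime rather than fitted (see ``lifetime.k_rnr_from_dark``).
    """

    kappa_QV: float = 0.0
    kappa_QA: float = 0.0
    kappa_QZ: float = 0.0
    kappa_QL: float = 0.0
    kappa_qZ: float = 0.0
    kappa_qI: float = 0.0
    k_rnr: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and v < 0:
                raise ValueError(f"negative quenching constant {f.name}={v}")

    def copy(self) -> "QuenchingRates":
        return dataclasses.replace(self)

    def as_dict(self) -> dict[str, float | None]:
        return {
            f.name: (None if getattr(self, f.name) is None else float(getattr(self, f.name)))
            for f in fields(self)
        }


KINETIC_NAMES = tuple(f.name for f in fields(KineticParameters))
QUENCHING_NAMES = tuple(f.name for f in fields(QuenchingRates) if f.name != "k_rnr")


class UnknownParameterError(KeyError):
    """A genotype or fit references a parameter name that does not exist."""


def save_parameters(
    path: str | Path, kinetic: KineticParameters, quenching: QuenchingRates | None = None
) -> None:
    """Write a flat JSON parameter file with a units declaration."""
    doc: dict = {"units": UNITS, "kinetic": kinetic.as_dict()}
    if quenching is not None:
        doc["quenching"] = quenching.as_dict()
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_parameters(path: str | Path) -> tuple[KineticParameters, QuenchingRates | None]:
    """Read a parameter file, checking its declared unit system."""
    doc = json.loads(Path(path).read_text())
    units = doc.get("units")
    if units != UNITS:
        raise ValueError(
            f"parameter file {path} declares units {units!r}; expected {UNITS!r}"
        )
    unknown = set(doc["kinetic"]) - set(KINETIC_NAMES)
    if unknown:
        raise UnknownParameterError(f"unknown kinetic parameters {sorted(unknown)}")
    kin = KineticParameters(**doc["kinetic"])
    q = None
    if "quenching" in doc:
        q = QuenchingRates(**doc["quenching"])
    return kin, q


# ---------------------------------------------------------------------------
# genotype modifications


@dataclass(frozen=True)
class GenotypeSpec:
    """Declarative description of what a mutation changes.

    ``zeroed_rates`` are set to 0, ``scaled_rates`` multiplied by their
    factor, and ``use_starred_PX`` substitutes the lutein-free antenna
    binding set.  ``initial_pigments`` holds the dark-acclimated total
    pools (V_0/A_0/Z_0/L_0, mmol/mol Chl) and ``tau_dark0`` the
    dark-acclimated amplitude-weighted lifetime (ns) that anchors
    k_rnr for this genotype.
    """

    name: str
    zeroed_rates: tuple[str, ...] = ()
    scaled_rates: tuple[tuple[str, float], ...] = ()
    use_starred_PX: bool = False
    initial_pigments: tuple[tuple[str, float], ...] = ()
    tau_dark0: float = 2.0

    def __post_init__(self) -> None:
        for name in self.zeroed_rates:
            if name not in KINETIC_NAMES:
                raise UnknownParameterError(f"unknown zeroed rate {name!r}")
        for name, factor in self.scaled_rates:
            if name not in KINETIC_NAMES:
                raise UnknownParameterError(f"unknown scaled rate {name!r}")
            if not factor > 0:
                raise ValueError(f"non-positive scale factor {factor} for {name!r}")
        for key, value in self.initial_pigments:
            if key not in ("V_0", "A_0", "Z_0", "L_0"):
                raise UnknownParameterError(f"unknown pigment key {key!r}")
            if value < 0:
                raise ValueError(f"negative pigment {key}={value}")
        if not self.tau_dark0 > 0:
            raise ValueError("tau_dark0 must be positive")

    @property
    def pigments(self) -> dict[str, float]:
        d = {"V_0": 0.0, "A_0": 0.0, "Z_0": 0.0, "L_0": 0.0}
        d.update(dict(self.initial_pigments))
        return d

    @property
    def scales(self) -> dict[str, float]:
        return dict(self.scaled_rates)

    def with_pigment(self, key: str, value: float) -> "GenotypeSpec":
        pig = self.pigments
        pig[key] = value
        return dataclasses.replace(self, initial_pigments=tuple(sorted(pig.items())))


_STARRED_SUBS = {
    "k_pvf": "k_pvf_star",
    "k_pvb": "k_pvb_star",
    "k_paf": "k_paf_star",
    "k_pab": "k_pab_star",
    "k_pzf": "k_pzf_star",
    "k_pzb": "k_pzb_star",
    "P_tot": "P_tot_star",
}


def apply_genotype(base: KineticParameters, g: GenotypeSpec) -> KineticParameters:
    """Return a copy of ``base`` with the genotype's modifications applied.

    Starred substitution happens first, then zeroing, then scaling; a
    scale requested on a zeroed rate is ignored with a warning (zero
    wins).  ``L_tot`` is taken from the genotype's L_0 pool so that
    lutein-free genotypes carry no lutein regardless of the base set.
    The base parameters are never mutated.
    """
    out = base.copy()
    if g.use_starred_PX:
        for plain, star in _STARRED_SUBS.items():
            setattr(out, plain, getattr(base, star))
    out.L_tot = g.pigments["L_0"]
    for name in g.zeroed_rates:
        setattr(out, name, 0.0)
    for name, factor in g.scaled_rates:
        if name in g.zeroed_rates:
            warnings.warn(
                f"genotype {g.name}: scaling zeroed rate {name!r}; zero wins",
                stacklevel=2,
            )
            continue
        setattr(out, name, getattr(out, name) * factor)
    return out
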