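"""The genotype registry and genotype composition.

Ships declarative specs for the wild type and the nine NPQ mutants of
*N. benthamiana* studied here (Table-style phenotypes: *npq4* lacks
PsbS and hence all qE; *npq1* lacks VDE and hence Ant/Zea; *lut2* lacks
lutein and has destabilized antenna binding; *zep2* has reduced ZEP and
constitutive dark zeaxanthin; double mutants combine their parents).
Pigment pools and dark lifetimes are the registry's dark-acclimated
defaults; measured HPLC values can override them per analysis.
"""

from __future__ import annotations

import dataclasses

from .parameters import GenotypeSpec

#: Forward activation rates zeroed when PsbS is absent (no qE of any kind).
_PSBS_RATES = ("k_qvf", "k_qaf", "k_qzf", "k_qlf")
#: De-epoxidation rates zeroed when VDE is absent.
_VDE_RATES = ("k_va", "k_az")
#: Residual ZEP activity when the minor ZEP paralog is knocked out.
ZEP2_RESIDUAL = 0.15


def _spec(name, zeroed=(), scaled=(), starred=False, V=28.0, A=0.0, Z=0.0,
          L=110.0, tau0=2.0) -> GenotypeSpec:
    return GenotypeSpec(
        name=name,
        zeroed_rates=tuple(zeroed),
        scaled_rates=tuple(scaled),
        use_starred_PX=starred,
        initial_pigments=(("A_0", A), ("L_0", L), ("V_0", V), ("Z_0", Z)),
        tau_dark0=tau0,
    )


def _single_mutants() -> dict[str, GenotypeSpec]:
    return {
        "WT": _spec("WT"),
        "npq4": _spec("npq4", zeroed=_PSBS_RATES),
        "npq1": _spec("npq1", zeroed=_VDE_RATES, V=30.0, tau0=2.05),
        "lut2": _spec("lut2", starred=True, V=45.0, L=0.0, tau0=1.95),
        "zep2": _spec(
            "zep2",
            scaled=(("k_za", ZEP2_RESIDUAL), ("k_av", ZEP2_RESIDUAL)),
            V=15.0, A=3.0, Z=10.0, tau0=1.35,
        ),
    }


def compose_double_mutant(a: GenotypeSpec, b: GenotypeSpec) -> GenotypeSpec:
    """Combine two genotypes: union of zeroed rates, product of scale
    factors, OR of the starred-binding flag.

    Initial pigments follow the inheritance rules: a lutein-free parent
    sets L_0 = 0 and contributes its expanded VAZ pool size; a
    ZEP-reduced parent's dark Ant/Zea fractions persist; otherwise
    pools come from whichever parent has the larger VAZ pool.  The dark
    lifetime inherits the more-quenched (shorter-lived) parent.
    """
    zeroed = tuple(sorted(set(a.zeroed_rates) | set(b.zeroed_rates)))
    scales: dict[str, float] = dict(a.scaled_rates)
    for name, factor in b.scaled_rates:
        scales[name] = scales.get(name, 1.0) * factor
    scaled = tuple(sorted((n, f) for n, f in scales.items() if n not in zeroed))

    pa, pb = a.pigments, b.pigments
    vaz_a = pa["V_0"] + pa["A_0"] + pa["Z_0"]
    vaz_b = pb["V_0"] + pb["A_0"] + pb["Z_0"]
    vaz_total = max(vaz_a, vaz_b)
    # dark Ant/Zea fractions persist from a ZEP-reduced parent
    donor = None
    if pa["A_0"] + pa["Z_0"] > 0:
        donor = (pa, vaz_a)
    if pb["A_0"] + pb["Z_0"] > pa["A_0"] + pa["Z_0"]:
        donor = (pb, vaz_b)
    if donor is not None and donor[1] > 0:
        dp, dvaz = donor
        A0 = vaz_total * dp["A_0"] / dvaz
        Z0 = vaz_total * dp["Z_0"] / dvaz
    else:
        A0, Z0 = 0.0, 0.0
    V0 = vaz_total - A0 - Z0
    L0 = 0.0 if (pa["L_0"] == 0.0 or pb["L_0"] == 0.0) else max(pa["L_0"], pb["L_0"])

    return GenotypeSpec(
        name=a.name + b.name if a.name != "WT" else b.name,
        zeroed_rates=zeroed,
        scaled_rates=scaled,
        use_starred_PX=a.use_starred_PX or b.use_starred_PX,
        initial_pigments=(("A_0", A0), ("L_0", L0), ("V_0", V0), ("Z_0", Z0)),
        tau_dark0=min(a.tau_dark0, b.tau_dark0),
    )


def default_registry() -> dict[str, GenotypeSpec]:
    """WT, the four single mutants, and the five studied double mutants."""
    reg = _single_mutants()
    for pa, pb in [
        ("npq4", "npq1"),
        ("npq1", "lut2"),
        ("npq4", "lut2"),
        ("npq4", "zep2"),
        ("zep2", "lut2"),
    ]:
        g = compose_double_mutant(reg[pa], reg[pb])
        g = dataclasses.replace(g, name=pa + pb)
        reg[g.name] = g
    return reg


def get_genotype(registry: dict[str, GenotypeSpec], name: str) -> GenotypeSpec:
    """Case-insensitive registry lookup."""
    for key, g in registry.items():
        if key.lower() == name.lower():
            return g
    raise KeyError(f"unknown genotype {name!r}; known: {sorted(registry)}")


#: The five genotypes whose data train the model, in fitting order.
TRAINING_GENOTYPES = ("npq4npq1", "npq4", "npq1", "lut2", "zep2")
#: Held-out genotypes predicted without refitting (V_0 aside for WT).
HELD_OUT_GENOTYPES = ("WT", "npq1lut2", "npq4lut2", "npq4zep2", "zep2lut2")
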