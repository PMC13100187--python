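# npqtau

Kinetic modeling of non-photochemical quenching (NPQ) in land plants,
observed through the chlorophyll-a fluorescence lifetime.

Plants dissipate excess absorbed light as heat through several
overlapping photoprotection processes — PsbS/xanthophyll-dependent qE,
zeaxanthin-dependent qZ, and slow photoinhibition qI — whose kinetics
are hard to separate in vivo.  `npqtau` implements a lifetime-based
kinetic model that disentangles them: a mass-action ODE system for the
xanthophyll (VAZ) cycle, antenna binding, and light-driven quencher
activation is mapped to the amplitude-weighted fluorescence lifetime
τ_F through a Stern–Volmer relation

    1/τ_F(t) = k_rnr + Σ_X κ_QX·[QX](t) + κ_qZ·[Z](t) + κ_qI·α_qI(t),

with X ∈ {V, A, Z, L} (violaxanthin, antheraxanthin, zeaxanthin,
lutein).  Model parameters are fitted stepwise across NPQ mutants of
*Nicotiana benthamiana* (each mutant isolating a subset of channels),
quenching is decomposed additively into qE_V/qE_A/qE_Z/qE_L/qZ/qI
contributions, and the fitted rates predict held-out double-mutant and
enzyme-overexpression phenotypes without refitting.  A synthetic-data
module generates the full study design — 83-snapshot lifetime series
per genotype × light sequence, raw TCSPC photon-count histograms with a
37-ps IRF, and HPLC-style pigment tables — from known ground-truth
parameters, so the entire pipeline is testable end to end.

The package is aimed at photosynthesis researchers who want to fit or
simulate lifetime-based NPQ kinetics, and at methodologists interested
in stepwise parameter estimation for sloppy biochemical models.

## Worked example

Simulate the wild type under a light–dark–light sequence and decompose
its quenching:

```python
import numpy as np
from npqtau import (default_truth, parse_light_sequence, simulate,
                    initial_state, k_rnr_from_dark, lifetime_series,
                    decompose, apply_genotype)

kin, q, reg = default_truth()
wt = reg["WT"]
params = apply_genotype(kin, wt)
light = parse_light_sequence("5HL-10D-5HL")   # 5 min HL, 10 min dark, 5 min HL

q = q.copy()
q.k_rnr = k_rnr_from_dark(wt.tau_dark0, initial_state(wt, params), q)
traj = simulate(wt, params, light)
tau = lifetime_series(traj, q)
dec = decompose(traj, q)

for t in (0, 300, 900, 1200):
    i = int(t)
    comps = {k: round(float(v[i]), 3) for k, v in dec.components.items()}
    print(f"t={t:>4d}s  tau={tau.tau[i]:.3f} ns  {comps}")
```

prints

```
t=   0s  tau=2.000 ns  {'qE_V': 0.0, 'qE_A': 0.0, 'qE_Z': 0.0, 'qE_L': 0.0, 'qZ': 0.0, 'qI': 0.0}
t= 300s  tau=0.626 ns  {'qE_V': 0.006, 'qE_A': 0.009, 'qE_Z': 0.209, 'qE_L': 0.429, 'qZ': 0.404, 'qI': 0.04}
t= 900s  tau=1.272 ns  {'qE_V': 0.001, 'qE_A': 0.0, 'qE_Z': 0.001, 'qE_L': 0.0, 'qZ': 0.234, 'qI': 0.05}
t=1200s  tau=0.561 ns  {'qE_V': 0.001, 'qE_A': 0.004, 'qE_Z': 0.257, 'qE_L': 0.429, 'qZ': 0.5, 'qI': 0.09}
```

Read: the dark-acclimated lifetime is 2.0 ns (no quenchers).  After
5 min of high light τ has dropped to 0.63 ns, with lutein qE (0.43
ns⁻¹) and zeaxanthin (qE_Z + qZ ≈ 0.61 ns⁻¹) carrying most of the
added decay rate.  Ten minutes of darkness switch the PsbS-dependent
channels off (qE_L and qE_Z are gone) while free-zeaxanthin qZ decays
only through the slow epoxidase, so recovery is partial (1.27 ns);
re-illumination then re-quenches faster than the first exposure because
zeaxanthin is already formed.  Photoinhibition (qI) creeps up
monotonically throughout.

The same operations are exposed on the command line:

```sh
npqtau synthesize --out data/ --seed 1 --genotypes all
npqtau fit --data data/snapshots.csv --out fit/ --seed 1
npqtau decompose --genotype WT --sequence 20HL --out dec/
npqtau scan --zep 5 --psbs 2 --sequence 5HL-10D-5HL --out scan/
```

## Layout

- `npqtau.light` — actinic light sequences (`"5HL-10D-5HL"` grammar)
- `npqtau.kinetics` — the ODE system, dark equilibrium, simulation
- `npqtau.lifetime` — Stern–Volmer observable, NPQ_τ, decomposition,
  per-molecule effectiveness
- `npqtau.decay` — TCSPC histograms, IRF reconvolution, snapshot timeline
- `npqtau.fitting` — stepwise protocol, global+local search, bootstrap
- `npqtau.synth` — synthetic study generator and default parameter set
- `npqtau.predict` — double-mutant composition, held-out prediction,
  overexpression scans
- `npqtau.validation` — end-to-end validation experiments
- `npqtau.cli` — the `npqtau` command
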