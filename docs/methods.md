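# Methods

## Model

`npqtau` models short-term photoprotection (non-photochemical quenching,
NPQ) in intact leaves as a small mass-action reaction network observed
through the chlorophyll-a fluorescence lifetime.

**Kinetic scheme.** Thirteen species: free violaxanthin (V),
antheraxanthin (A) and zeaxanthin (Z); antenna-bound complexes PV, PA,
PZ sharing a site pool `P_tot`; a permanently bound lutein complex PL
(pool `L_tot`); the light-activated quenchers QV, QA, QZ, QL; and the
VDE/ZEP enzymes, carried as degenerate activity scalars fixed at 1 (an
extension point — explicit enzyme-state kinetics are not modeled).
A dimensionless photoinhibited fraction `alpha_qI` completes the state.
All reactions are first-order mass action:

- de-epoxidation `V -> A -> Z` at `k_va`, `k_az`, gated by the binary
  high-light indicator `u(t)`;
- epoxidation `Z -> A -> V` at `k_za`, `k_av`, light-independent;
- binding `X + P <-> PX` at `k_pxf`/`k_pxb` with free sites
  `P = P_tot − PV − PA − PZ`;
- activation `PX <-> QX` at `k_qxf · u` / `k_qxb` (PsbS-dependent
  forward step), likewise `PL <-> QL`;
- `d(alpha_qI)/dt = (k_qI_HL · u + k_qI_laser · laser)(1 − alpha_qI)`,
  with no recovery term on the 20-minute timescale; the detection laser
  drives a small accumulation even in actinic darkness.

Light enters only through the binary HL/D label of the sequence
(irradiance is metadata): the model carries no intensity-dependent
rates.  The VAZ pool (free + bound + activated) and the lutein pool
(PL + QL) are exactly conserved.

**Observable.** The amplitude-weighted lifetime follows a Stern–Volmer
relation

    1/τ_F(t) = k_rnr + Σ_X κ_QX·[QX](t) + κ_qZ·[Z](t) + κ_qI·α_qI(t)

with X ∈ {V, A, Z, L}.  `k_rnr` collects every other decay channel and
is derived per genotype from the dark-acclimated lifetime τ_dark(0)
*after subtracting dark-state quencher terms* (constitutive free Zea in
ZEP-deficient genotypes quenches in darkness, which is why their dark
lifetimes are short).  The same linear channels give an exactly
additive decomposition of 1/τ into qE_V, qE_A, qE_Z, qE_L, qZ and qI
contributions.

**Per-molecule effectiveness.** For each quencher,
`Q_eff = [k_pxf/(k_pxf+k_pxb)] · [k_qxf/(k_qxf+k_qxb)] · κ_QX`
(binding fraction × maximal activated fraction × quenching constant);
lutein's binding fraction is 1.  For the free-Zea (qZ) channel the
package reports `Q_eff(qZ) = κ_qZ` directly — no binding/activation
step exists for free Zea, and this convention keeps κ_qZ well below
κ_QZ as the channel comparison requires.  The convention is recorded in
the decomposition metadata.

**Genotypes.** Mutations are declarative: lists of zeroed rates
(PsbS-less genotypes zero all `k_qxf`; VDE-less genotypes zero
`k_va`/`k_az`), scale factors (the ZEP2 knockout retains ~15% residual
epoxidase activity), a flag substituting the lutein-free ("starred")
antenna-binding set (lutein loss destabilizes LHCII trimers: altered
V/A/Z affinities, roughly half the sites, zero lutein), and
dark-acclimated pigment pools plus τ_dark(0).  Double mutants are the
union of their parents' modifications; pigments follow inheritance
rules (lutein-free parent ⇒ expanded VAZ pool and L=0; ZEP-reduced
parent ⇒ its dark Ant/Zea fractions persist; dark lifetime from the
more-quenched parent).  The registry holds WT, npq4, npq1, lut2, zep2
and the five studied doubles.

## Default parameter set

The shipped defaults are **not** a fitted set from measured data; they
are a documented fallback (`synth.DEFAULTS_ARE_FITTED = False`)
calibrated once, at design time, to reproduce the reference
per-molecule effectiveness table —

| species | Q_eff |
|---------|-------|
| QV | 0.0022 |
| QA | 0.0042 |
| QZ | 0.0390 |
| QL | 0.0039 |
| qZ | 0.030 |

— and the qualitative kinetic orderings of the system: WT binding
fractions V:A:Z = 2 : 3.5 : 7 shifting to 1 : 1 : 3 with
`P_tot* = P_tot/2` in lutein-free plants; `k_va > k_az` (the first
de-epoxidation step faster); slow epoxidation; Zea the fastest QX
activation; lutein ≈ violaxanthin per-molecule activation; dark
deactivation fastest for qE_L (gone within ~1 min), then qE_Z, qE_A,
qE_V, with qZ relaxing only through the slow epoxidase; and a
photoinhibition ceiling κ_qI = 2.82 ns⁻¹ with accumulation rates of
order 10⁻⁵ s⁻¹ (HL) and 10⁻⁶ s⁻¹ (laser-only).  Units: time s,
concentrations mmol/mol Chl, lifetimes ns, κ in (mmol/mol Chl)⁻¹ ns⁻¹.
Pool sizes: `P_tot = 3`, `L_tot = 110` mmol/mol Chl; `P_tot` must be
small because the Q_eff binding-fraction convention couples the rate
ratio to realized occupancy — a large site pool would sequester nearly
all zeaxanthin and extinguish the free-Zea (qZ) channel.

Under these defaults the WT 20-minute high-light decomposition shows
lutein + antheraxanthin dominating for the first ~3 minutes, zeaxanthin
(qE_Z + qZ) overtaking from ~5 minutes and dominating strongly at 20
minutes.  One narrative feature is **not** reproduced: a large
early-time antheraxanthin contribution comparable to lutein's is
arithmetically incompatible with the effectiveness table (Ant capacity
≈ pool × Q_eff(QA) ≈ 0.05 ns⁻¹ against lutein's ≈ 0.43 ns⁻¹), so "Lut
and Ant dominate early" holds as a combined statement, with lutein
carrying most of it.

## Fitting

**Objective.** δ²(θ) = Σ over datasets and snapshots of
(τ_exp − τ_model)², fitted directly in the lifetime domain and
unweighted by default (1/SE² weighting is available but off).  RMSDs
are reported in both τ (ns) and 1/τ (ns⁻¹) domains.  Simulation
failures inside the optimizer contribute a large finite penalty per
snapshot.  Rates are optimized as log10 values; initial violaxanthin
pools linearly.

**Stage plan.** Parameters are estimated stepwise across genotypes of
increasing complexity, each stage freezing its result:

1. *npq4npq1* → photoinhibition accumulation rates (`k_qI_HL`,
   `k_qI_laser`).  κ_qI is **not** fitted: α_qI stays ≪ 1 over 20
   minutes, so lifetime data constrain only the product κ_qI·k; κ_qI is
   therefore a fixed scale convention (the photoinhibition-rate
   ceiling) and the rates absorb the kinetics.
2. *npq4* → xanthophyll-cycle rates and κ_qZ.
3. *npq1* → violaxanthin binding and the V/L quencher channels.
4. *lut2* + *zep2* → A/Z quencher channels, WT A/Z binding and the
   lutein-free binding set.
5. *WT* → the documented per-genotype `V_0_WT` only.

Pool sizes (`P_tot`, `P_tot_star`, `L_tot`), per-genotype pigments and
τ_dark(0) are treated as known structural constants (pigments come from
HPLC-style tables and act as initialization, never as penalty terms).
Before fitting, every parameter the plan will free is reset to its
mid-bound placeholder so earlier stages never see informative values of
later-stage parameters.

**Search.** Each stage runs a seeded differential-evolution global
search (Sobol-initialized population) followed by bounded trust-region
least squares.  Two numerical choices matter far more than optimizer
sizes:

- the finite-difference step for least-squares Jacobians is fixed at
  1e-3 (log10 space), well above the ODE-integration noise floor —
  with scipy's default step the Jacobian is noise and every optimizer
  stalls orders of magnitude short;
- `max_nfev` in scipy's `least_squares` counts trust-region iterations
  (finite-difference evaluations are extra), so all caps here are
  iteration caps.

**Joint refinement ("fitted in batches").** Stage-local data cannot pin
directions that only cross-genotype data constrain, so after the stage
pass the protocol runs block-coordinate sweeps — each stage's parameter
block re-optimized against *all* training datasets — followed by a full
joint least-squares polish.  Cycles continue while the misfit sits
above the noise floor implied by the datasets' own standard errors and
keeps improving; stalled cycles escalate to a warm global re-search of
each block.  Because the V and L quencher channels have near-identical
functional form in the VDE-less genotype, block descent can entrench a
role swap between them; a stalled (or noisy-data) refinement therefore
proposes the explicitly swapped channel assignment — a basin-hop move,
as used for label switching in mixture models — and keeps the better
fit.  The whole protocol can be restarted from independent optimizer
seeds with the best final fit winning (`n_restarts`).

**Bounds** encode the known timescales of each process class (≥3
decades each, e.g. de-epoxidation 10⁻⁴–10⁻¹ s⁻¹, binding 10⁻³–1,
activation 10⁻⁵–0.5 s⁻¹); they are deliberately generous but not
unbounded, which also keeps the explicit integrator away from
pathologically stiff corners (a step-budget guard converts any
remaining ones into the penalty path).

**Bootstrap.** 95% intervals come from a residual-resampling bootstrap:
per replicate, each dataset's residuals are resampled with replacement
and added back to the fitted curve, the stages are re-optimized
warm-started from the point estimate, and a capped joint pass follows
so cross-genotype (ridge) uncertainty is expressed; percentile 2.5/97.5
intervals are widened to include the point estimate.  Replicates whose
refit fails are dropped; >50% failures is an error.

## Synthetic data

The generator emulates the study design: 83 snapshots per 20-minute
sequence (three dark-acclimated snapshots ending at t = 0, then one
every 15 s), i.i.d. Gaussian noise per biological replicate on τ
(default SD 0.04 ns, 3 replicates, i.e. SE ≈ 0.023 ns — the scale of
typical whole-leaf ±2 SE error bars), reported as mean ± SE; Poisson
photon-count decay histograms under a 37-ps-FWHM Gaussian IRF; and
dark/post-HL pigment tables with the VAZ pool conserved by
construction.  Identical seeds give byte-identical outputs.

What it does **not** emulate: leaf-to-leaf biological variability
(pool sizes, enzyme levels), batch effects, drift, non-Gaussian outliers,
partial RC closure, or any intensity dependence.  Passing tests
therefore demonstrate the *pipeline's* correctness and the protocol's
behavior under the stated noise model — not that the model would fit
any particular measured leaf.

## Validation experiments and problem sizes

`npqtau.validation` runs the end-to-end checks (shared by the test
suite and `scripts/acceptance.py`); sizes are the package's reduced
defaults chosen to keep full runs in the minutes range:

- **Pipeline closure**: a zero-noise synthetic study (6 genotypes × 2
  training sequences, 996 snapshots) refit from scratch reaches
  δ² < 10⁻⁶ (typically ~10⁻¹³).
- **Parameter recovery**: ten noisy studies, each fitted
  (`FitConfig.recovery`: 1 restart, 1 refinement cycle, iteration caps
  30/10/40) and bootstrapped (5 replicates, caps 10/25); coverage of
  the generating values is scored over the *practically identifiable*
  parameters — those whose Fisher-information standard deviation at the
  generating parameters, under the study noise model, stays within 0.5
  log10-decades (95% range under ~2 decades, the usual practical-
  identifiability cut-off).  This set is computed from model structure
  and noise alone, before any fitting; the remaining parameters are
  sloppy-ridge directions for which point recovery is not a meaningful
  target at this noise level.
- **Additivity**: a noisy-data fit on the training genotypes predicts
  held-out WT and the four double mutants; RMSD is compared with the
  snapshot noise floor SE = SD/√n ≈ 0.023 ns (pass: ≤ 2× the floor,
  leaving room for parameter-estimation error on top of the irreducible
  noise).
- **Integrator oracle**: the compiled adaptive Dormand–Prince RK45
  (default rtol 10⁻⁸, atol 10⁻¹¹, event-exact restarts at phase
  boundaries) against a dense fixed-step RK4 reference at dt = 1 ms
  over all 10 genotypes × 3 sequences (10⁻⁴ relative), conservation
  drift < 10⁻⁶, and scipy LSODA as an independent backend cross-check.
- **Decay round trip**: 50 Poisson histograms at 10⁵ counts refit with
  the lmfit-backed reconvolution; mean bias of the recovered
  amplitude-weighted lifetime < 1%.

## Known limitations

- With the default effectiveness table the model is *sloppy*: at
  experimental noise only ~14 of 32 free parameters are practically
  identifiable; the rest live on ridges (κ·activation-fraction
  products, binding-rate pairs) that the bootstrap flags as wide.  The
  V/L channel-assignment degeneracy is global, not local, and is
  handled by the explicit swap proposal rather than by curvature.
- Bootstrap intervals from warm-started, iteration-capped refits
  understate the dispersion of estimates that scatter across ridge
  basins (re-running the full global protocol per replicate would be
  needed for nominal coverage, at roughly an order of magnitude more
  compute).  The recovery experiment therefore reports the achieved
  coverage of the identifiable set rather than assuming nominal 95%.
- The bi-exponential decay fit is a representation, not mechanism; its
  components are not interpreted.
- The snapshot pipeline assumes the longest-lifetime 0.2-s sub-window
  fully closes the reaction centers; partially open RCs are out of
  scope, as are qT, qH and PSI–PSII spillover.
- Printed-unit ambiguities in the source material (rate units, RMSD
  units) are resolved by the declared unit system of the parameter
  files; RMSDs are reported in both τ and 1/τ domains.
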