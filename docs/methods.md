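# Methods

## The mechanism model

`uvrkin` models the UvrA₂ dimer ATPase as a deterministic mass-action
network over *lumped* dimer states: the two sites of each class (distal D,
proximal P) act as one transition, and the burst stoichiometry is carried by
a fitted scalar `n_sites` rather than by site-by-site states. This matches
how pre-steady-state ATPase data of this enzyme are analyzed in practice —
individual sites within a class are kinetically indistinguishable in
ensemble stopped-flow data.

States and transitions (wild-type topology):

| step | transition | rate | meaning |
|------|-----------|------|---------|
| 1 | S0 → S1 (reversible) | k1·[ATP], k₋1 | ATP binding to the tight distal pair |
| 2 | S1 ⇌ S2 | rapid equilibrium, K_D2 | ATP binding to the weak proximal pair |
| 3 | S2 → S3 | k3 | hydrolysis-limiting step (distal sites) |
| 4 | S3 → S4 | k4 | fast Pi release — emits `n_sites` Pi per dimer |
| 5a | S4 → S5 → S2 | k5a, then fast distal rebinding | two-active-site recycle |
| 5b | S4 → S1 | k5b | four-active-site recycle — emits the proximal products |

Key modeling decisions:

* **Proximal binding as a kinetic rapid equilibrium.** Only K_D2 is
  experimentally determined, so step 2 is realized with a fixed on-rate of
  10⁶ M⁻¹ s⁻¹ (configurable via `RateParameterSet.proximal_on_rate`) and
  off-rate `K_D2 × on-rate`. At every tested ATP concentration this
  equilibration (≥ 360 s⁻¹) far outruns the chemistry, so only the occupancy
  `f₂ = [ATP]/([ATP]+K_D2)` matters; the effective hydrolysis rate of the
  S1/S2 pool is `f₂·k3`.
* **Pi bookkeeping in the four-active-site branch.** The k5b transition
  collapses distal ADP release, slow proximal hydrolysis and proximal
  product release into one step. It therefore emits `max(0, 4 − n_sites)`
  Pi per dimer (and all four ADP), so a full cycle turns over all four
  sites. This is required for the branch's defining property — a steady-state
  `kcat = slope/(4×[dimer]) ≈ k5b` — and degrades gracefully for fitted
  `n_sites > 4` (no negative emission). The k4 step remains the only *fast*
  (burst) Pi-emitting transition.
* **Return topology.** The recycle target is not experimentally resolved;
  the two-site branch returns via a transiently distal-empty state (S5) with
  fast rebinding, the four-site branch directly to S1. These are the minimal
  choices reproducing the two limiting turnover rates (k5a for 2 sites,
  k5b for 4).
* **ATP depletion.** Free ATP is decremented by cumulative released Pi
  (1 ATP per Pi). At assay scale (≤ 2 µM dimer, ≥ 10 µM ATP, ≤ 60 s) this is
  a small correction but it is integrated, not assumed away.
* **Binding-dead variants.** Walker-A mutants lack the corresponding
  transitions outright: a proximal-binding-dead dimer stalls after distal
  binding (S0 ⇌ S1, no Pi), a distal-binding-dead dimer is modeled as inert
  at the concentrations of these assays.

## Parameters

All concentrations in µM, time in s; bimolecular constants are accepted in
M⁻¹ s⁻¹ and converted in one utility (`uvrkin.units`). The wild-type preset
(`PARAM_PRESETS["wild_type_apo"]`) is the published global-fit set: k1 =
3×10⁴ M⁻¹ s⁻¹, k₋1 = 0.03 s⁻¹ (K_D1 = 1 µM), K_D2 = 350 µM, k3 = 2.45 s⁻¹,
k4 = 19 s⁻¹, k5a = 0.44 s⁻¹, k5b = 0.18 s⁻¹, n = 1.9. The native-DNA preset
is the corresponding published fit (k3 = 2.4, k4 = 30, k5 = 1, n = 5.4).

For the lesion-DNA and mutant variants only turnover numbers and qualitative
phase behavior are published. Their preset rate sets were derived once from
the steady-state cycle-time identity

    kcat = (Pi per cycle) / (sites × Σ residence times),
    Σ = 1/(f₂·k3) + 1/k4 + 1/k5 (+ 1/(k1·[ATP]) where the cycle rebinds),

choosing k3 to reproduce the published kcat with fast post-hydrolysis steps
(lesion: k3 = 6, k5a = 13 — the measured lesion ATP-chase ADP-release rate;
distal Walker-B mutant: k3 = 1.0, burst-free). These presets are generator
metadata for property-level tests (correct kcat, presence/absence of a
burst), not value-level claims.

## Numerical choices

* ODE integration: `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8,
  atol 1e-10 µM; simulation grids are log-spaced from 1 ms to resolve the
  ~100 ms lag. Trajectories are validated (occupancies sum to 1 within 1e-6,
  products non-decreasing) and a tight-tolerance re-integration agrees to
  1e-6 relative in released Pi.
* Fitting: bounded trust-region least squares (`scipy.optimize.least_squares`,
  TRF) on log-transformed parameters with an explicit finite-difference step
  of 1e-3 on the log scale — large enough that solver noise in the residuals
  does not corrupt the Jacobian (with the default step the optimizer stalls
  at spurious minima).
* Burst fitting is seeded by a two-stage bootstrap (linear phase from the
  last half of the trace; burst rate from the half-life of the gap to that
  line; lag rate at 10× the burst rate) and the fast/slow exponentials are
  relabeled post-fit so `k_lag > k_burst`. The burst-vs-line call is a
  nested-model F-test at α = 0.01. The burst amplitude is reported as the
  projected intercept of the linear phase relative to the signal at time
  zero, `−(A₁+A₂)`.
* Global fits start from single-trace estimates
  (`uvrkin.globalfit.initial_estimates`), the standard bootstrap for
  mechanism fitting, with seeded multistart jitter. The published fit
  structure is used for recovery runs: k1, k3, k4, k5 and n float; K_D2 and
  the K_D1 link are constrained (in the published table only the floated
  parameters carry standard errors).
* Confidence contours profile each parameter on an outward log-walk,
  re-optimizing the others at every point (warm-started), and refine the
  χ² = threshold crossing by root finding inside the bracket — linear
  interpolation systematically narrows intervals on a quadratic valley. The
  default threshold is χ² ≤ 1.1 × χ²_min, exposed as configuration
  (`FitSpec.threshold_ratio`); with the trace sizes used here this is a
  conservative (wider-than-95%) interval. A profile still below threshold at
  the search edge is reported as an open bound — the signature of an
  unidentifiable parameter (e.g. K_D2 from a single-ATP series, where only
  the product f₂·k3 is constrained; this is why the ATP titration exists).

## What the synthetic data emulate — and what they do not

Generators reproduce the experiments' statistical structure: concentration
designs (0.125–2 µM dimer at 1 mM ATP; 10 µM–2 mM ATP at 2 µM dimer; 3 µM
dimer FRET titrations over 0–20 µM ligand), Gaussian noise of 2% of full
scale per shot averaged over 4 shots (the instrument averages 3–6; true
experimental noise magnitudes are not published, so 2% — typical stopped-flow
practice — is a configurable default, not a claim), linear photobleach drift
up to 15% per 150 s on dissociation traces, and a phosphate-binding-protein
reporter (15 µM capacity, 10⁸ M⁻¹ s⁻¹, K_D 0.1 µM) with instantaneous linear
response by default — justified because its binding outruns every mechanism
rate; the explicit reporter ODE is available and differs by < 1% while the
reporter is in excess. Pi-release trace durations are set per condition so
cumulative Pi stays within 90% of reporter capacity (5–60 s), mirroring why
DNA-stimulated assays are run at lower enzyme.

Not emulated: instrument dead time, photomultiplier characteristics,
temperature dependence (all experiments at 40 °C; metadata only), and any
within-class site asymmetry. Passing recovery tests therefore demonstrates
that the analysis chain is self-consistent under realistic noise — not that
real instrument artifacts are handled.

## Problem sizes used for the recomputed results

The acceptance script fits the full 14-trace two-series design (250 points
per trace) for the wild-type recovery; the native-DNA recovery uses a
five-point enzyme series (0.0625–1 µM at 1 mM ATP) and reports the median
over three replicate synthetic series — the burst and linear phases are
poorly separated for this variant (the original analysis itself notes its
stoichiometry may be inflated by fitting error), so a single realization
scatters by up to ~15%. The FRET stoichiometry is likewise the median of
three replicate titrations. Burst-titration traces run 2.2 s — the ~0.1 s
lag plus five burst time constants at the saturating burst rate, the
shortest window that resolves the burst and anchors the linear phase.

## Known limitations

* **The burst-amplitude midpoint.** With proximal binding as a rapid
  equilibrium, occupancy rescales the burst *rate* (f₂·k3), not its
  asymptotic amplitude: every dimer eventually completes its first turnover,
  so the projected linear-phase intercept is nearly flat in ATP. The
  apparent amplitude suppression at low ATP is a finite-window extraction
  effect, and the fitted-amplitude midpoint lands near ~200 µM for the 2.2 s
  window (and lower for longer windows) rather than at K_D2 = 350 µM. No
  mass-action scheme of this topology can simultaneously show a 2.4 s⁻¹
  burst at 1 mM ATP, a 0.2 s⁻¹ kcat, and a genuine amplitude midpoint at
  350 µM; the package reports what the model actually produces.
* At 1 mM ATP the proximal occupancy factor f₂ ≈ 0.74 scales the effective
  burst rate to ~1.8 s⁻¹ (the double-exponential fit reads ~2.05 s⁻¹ because
  the lag term pulls the burst exponential up) and the four-site kcat to
  ~0.16 s⁻¹ — both systematically below the published single-trace values
  (2.4 and 0.2 s⁻¹) by that same occupancy factor.
* Whether proximal hydrolysis is obligate-sequential or stochastic per
  turnover is unresolved experimentally; both recycling branches are
  implemented and neither is privileged.
* The conformational events presumed to underlie k3 and k4 are not modeled;
  k3 and k4 are effective rates.
* No Gillespie simulation, no explicit UvrB or DNA-translocation states, no
  thermodynamic cycle-closure constraints.
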