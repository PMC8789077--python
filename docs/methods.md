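# Methods

`rnacat` analyses multiple-turnover RNA cleavage by bulge–loop inducing
peptidyl-oligonucleotide conjugates.  This note records the models, the
conventions and defaults, the numerical choices, and the limits of what the
package's synthetic-data studies can show about real data.

## Assay reduction

**Fluorescence.**  The FRET de-quenching readout is normalised per time point
as `extent(t) = 100·(raw − background)/(ref − background)`, where
`background` is the matched untreated-target series and `ref` the RNase-A
fully-cleaved control of the same substrate.  The normalisation is invariant
to affine rescaling of the fluorescence unit applied jointly to all three
signals.  Values outside [0, 100] (possible under noise) are clipped, and the
clipping is both logged and flagged in the returned object — never silent.
Product concentration is `extent/100 · [S]₀` and amounts follow from
`nmol = µM · µl / 1000`; turnover is cleaved nmol per conjugate nmol,
reported at full precision with a companion value rounded to one decimal, the
convention of published turnover tables.

**Gels.**  Band-intensity tables are normalised lane-internally: the
denominator is the total *assigned* signal of the lane (intact + all product
bands), which cancels loading variation.  Unassigned smear is excluded from
the denominator and its fraction can be inspected separately.  Products are
attributed to the single site of the band's identity; secondary cleavage of
long products is not re-attributed, so per-site values are operationally
"band fractions".  The bulge-vs-ex-bulge pathway analysis compares
finite-difference rates located at interval midpoints; the takeover point is
the first interval where the bulge rate matches or exceeds the ex-bulge rate
(ties resolve to the earlier index), with the crossing time interpolated
linearly between midpoints and the ex-bulge extent read off at that time.

## Progress-curve model

Product accumulation is fitted per condition with

    [P](t) = v₀/η · (1 − e^(−ηt))

with initial velocity v₀ (µM/h) and non-linearity factor η (1/h); η → 0
recovers the linear law v₀t, η > 0 a decelerating and η < 0 an accelerating
reaction.  Numerically the model is evaluated as `v₀·t·φ(ηt)` with
φ(x) = (1 − e^(−x))/x computed through `expm1`, switching to the series
1 − x/2 for |x| < 1e-8 to avoid cancellation; d[P]/dt at t = 0 equals v₀ for
every η.  Fitting uses bounded trust-region least squares with η ∈ [−1, 1]
1/h and a multi-start over η ∈ {−0.05, 0, 0.02, 0.05, 0.1}.  Standard errors
come from the Gauss–Newton curvature; on 5-point designs they are indicative
only (the classification into activation/linear/deceleration uses a
configurable z-threshold, default 2).  The comparison estimator `linear_v0`
is the origin-constrained OLS slope over the first K non-zero times (default
K = 2); a free-intercept variant is available.  An all-zero curve returns
v₀ = 0 with η flagged undefined rather than an arbitrary number.

## The turnover model

The core model explains the "atypical parabolic" kinetics by superimposing
rapid binding equilibria on slow catalysis:

* substrate self-association, either *hairpin* (unimolecular; `Ks` is the
  dimensionless unfolded/folded ratio, available fraction `Ks/(1+Ks)`) or
  *duplex* (bimolecular; `Ks` in µM, free monomer solves
  `S + 2S²/Ks = S_tot`).  Hairpin is the substrate default (intramolecular
  folds form fast and are stable), duplex the conjugate default (imperfect
  conjugate–conjugate dimers);
* conjugate self-association (`Kc`), the inactive reservoir; activation is
  not a separate rate process but emerges from competition — tight full-site
  binding (`Kcs`) depletes free conjugate and pulls the self-complex apart;
* catalyst–ligand equilibria: full binding `C + S ⇌ CS_full` (`Kcs`, the
  cleavable Michaelis complex), partial binding `C + S ⇌ CS_part` (`Kss` ≥
  `Kcs`, the model's premise that full binding is at least as tight), product
  binding `C + P ⇌ CP` (`Kp`, default `Kss`: fragments bind like
  partially-bound substrate), and a second partial substrate onto an occupied
  catalyst, `CS_part + S ⇌ CS₂` (`Kds`);
* kinetics: `d[P]/dt = k_cat·[CS_full]` and irreversible inactivation
  `d[C_inact]/dt = k_inact·[CS₂]` — first order in the double-occupied pool,
  the simplest law with the double-occupancy dependence; there is no
  reactivation path.

All binding steps are assumed to equilibrate instantaneously relative to
catalysis (quasi-steady state; k_cat ≤ ~1 h⁻¹ versus hybridisation times of
seconds to minutes), so the speciation is re-solved from the conserved totals
at every integration stage.  Each cleavage removes one substrate and releases
ν product fragments into the `Kp` pool (default ν = 2, the two half-site
fragments of a single cut; configurable).  Units are µM and hours throughout;
conversions happen only at I/O boundaries.  Any interaction is switched off
by setting its dissociation constant to infinity.

**Speciation solver.**  Unknowns are the free substrate and conjugate
monomers (free product is analytic given free conjugate).  The primary
solver is a damped 2×2 Newton iteration on the conservation residuals
(analytic Jacobian, Cramer solve, step halving to keep the pools positive),
converged to a relative residual of 1e-12; a nested Brent-bisection fallback
covers pathological parameter corners, and non-convergence raises with the
last residual rather than returning silently.  Warm starts from the previous
integration stage make the per-stage cost a few Newton steps.

**Integration.**  Classical fixed-step RK4 on (P, C_inact) with step ≤ 0.1 h
by default; the state is clamped to the physical ranges and a conservation
check (≤ 1e-4 relative) aborts with diagnostics if the speciation ever
drifts.  Halving the step changes P(96 h) by far less than 0.1% in the
regimes shipped as presets (asserted in the tests), which is why the fitting
routines may use coarser steps (0.25–0.5 h) for speed.

**Michaelis–Menten reduction and pool conventions.**  With self-association,
partial/double binding and product binding off and trace catalyst, the
simulator collapses to textbook single-substrate MM kinetics with K_m = K_CS
(verified against an independent ODE oracle).  More generally, the identity

    v₀ = k_cat · [C]_a · [S]_a / (K_CS + [S]_a)

holds *exactly* when [S]_a is the free available substrate and [C]_a the
productive catalyst pool — free active conjugate plus the cleavable complex.
Catalyst occupied partially, doubly or by product is active but not
productive, and counting it in [C]_a biases the MM stage low.
`velocity_profile` therefore reports the productive-pool definitions to the
MM stage and the broader "total minus self-complexed" pools
(`S_nonself0`/`C_nonself0`) alongside for comparison.

## Inference

`fit_mm` fits v₀ = k_cat·c·s/(K_m + s) across conditions (≥ 3 conditions
spanning ≥ 4-fold in s; a flat design is rejected as rank-deficient).
`fit_uncompetitive` adds uncompetitive product inhibition,
v = k_cat·c·s/(K_m + s(1 + p/K_i)), which depresses apparent V_max and K_m
together; with p ≡ 0 the K_i is unidentifiable and the fit reduces to
`fit_mm` with the K_i flagged absent.

`fit_full_model` follows an approximate-then-refine workflow: per-condition
v₀ estimates from the progress fits are regressed through the MM stage at the
initial equilibrium parameters to seed k_cat (and K_CS when floated); a
bounded trust-region least squares then refines all floated parameters
jointly against the observed [P](t) in µM (uniform weights, optional
per-point SDs), with log10 parameterisation, dissociation constants bounded
to [1e-3, 1e4] µM and rates to [1e-3, 10] 1/h, and seeded multi-starts
(default 8) around the data-driven initial value.  Trial points violating
K_CS ≤ K_SS are rejected by a large-residual barrier.  The result carries
curvature-based standard errors, the per-start objective values and a
start-to-start dispersion per parameter, and the MM stage re-run at the
fitted equilibrium — the package's phenomenological (k_cat, K_m) estimate.

**Identifiability.**  On the standard sparse design (five 5-point curves) the
full-curve objective is nearly flat along the k_cat/K_CS ridge whenever the
catalyst is far from saturation — the regime the presets deliberately occupy.
Joint (k_cat, K_CS) estimates from noisy data then inherit noise-scale
excursions along the ridge; the dispersion diagnostics make this visible
rather than hiding it.  The package's recovery study therefore conditions on
the availability constants (they define the study regime), floats k_cat
mechanistically and reads K_m off the MM stage; `scripts/acceptance.py`
reports the resulting medians.  Noiseless data identify all floated
parameters exactly, which separates estimator bias from noise-driven
dispersion.

## Synthetic data

The generator emulates the study design: 5 µM conjugate, substrate at
{2, 5, 10, 20, 30}-fold excess (10–150 µM) in 100 µl, sampled at
0/24/48/72/96 h.  Fluorescence is produced by inverting the assay
normalisation (`raw = background + (P/S₀)·(ref − background)`, with the
reference scaling as background + 100·S₀ fluorescence units) and applying
multiplicative Gaussian noise with an additive floor — a plate-reader-like
heteroscedastic error model, declared rather than matched to any published
error analysis.  Background and reference controls are treated as noiseless.
Gel fixtures and binding titrations invert exactly through their analysis
stages at zero noise.  All randomness flows from one recorded seed and
regeneration is byte-identical.

What the generator does *not* emulate: pipetting/temperature drift and
plate-edge effects, secondary cleavage re-attribution on gels, smeared
unassigned gel signal, cooperative or multi-site binding, substrate
aggregation at high concentration, and any kinetics of strand exchange
(activation is equilibrium competition, not toehold-mediated displacement).
Passing recovery tests therefore demonstrates estimator correctness under
the declared model, not robustness to every real-world artefact.

### Presets

* `paper-like` — k_cat = 0.8 h⁻¹, K_m = K_CS = 22 µM and K_i = 20 µM at the
  midpoints of the published ranges; K_SS = K_P = 44 µM (twice K_CS, keeping
  the premise), K_ds = 200 µM; hairpin K_s = 1 (half the substrate
  available); duplex K_c = 0.062 µM, chosen once so that ~10% of the
  conjugate is in the active pool at 2-fold excess — the partially-active
  regime the kinetic analysis describes.  Inactivation off.
* `activation-demo` — double occupancy tight (√(K_SS·K_ds) ≈ 0.6 µM, below
  the 2-fold-excess available substrate), product binding and inactivation
  off: the catalyst starts above its occupancy optimum, so velocity rises as
  substrate is consumed and the fitted η at 2-fold excess is negative.
* `inactivation-demo` — double-occupancy optimum √(K_SS·K_ds) = 30 µM
  between the available substrate at 10- and 20-fold excess, with
  k_inact = 0.2 h⁻¹: initial velocity rises then falls across the excess
  series, progress decelerates (η > 0) at ≥ 10-fold excess, and the 96-h
  turnover at 30-fold drops below that at 10-fold.

The two demonstration regimes are separate because, under equilibrium
speciation, a rising rate during progress at 2-fold excess requires the
occupancy optimum to sit *below* the 2-fold available substrate, while the
rise-then-fall of v₀ peaking at 10–20-fold requires it to sit *above* — one
parameter set cannot show both.  The presets are regime choices for
demonstrations and recovery studies, not fitted constants: the raw data
behind the published estimates were never deposited.

## Duplex screen and mass arithmetic

The off-target screen scores the DNA probe against every target window
(1-nt step) with the published RNA/DNA-hybrid nearest-neighbor set as
shipped with Biopython (Sugimoto et al. 1995), 1 M NaCl reference state, no
salt correction: the output ranks windows comparatively.  Only Watson–Crick
matched stacks contribute (U ≡ T); mismatched steps add nothing, so a window
with zero complementarity carries only the destabilising initiation term.
The two-state Tm uses a configurable total strand concentration (default
1 µM, CT/4 convention, self-complementarity ignored); hybrids with no net
favourable enthalpy report Tm = NaN and are never flagged stable.  Note the
per-window scores are not symmetric under reversing the target sequence —
hybrid NN parameters are strand-asymmetric — although the window *positions*
mirror exactly.

Average masses use IUPAC standard atomic weights at 4 decimals; printed MWs
are matched after rounding with ±1 Da tolerance (published values are
rounded and the isotope-table vintage is unstated).  Adducts supported:
[M+H]⁺, [M+Na]⁺, [M+Na+H]⁺, singly charged.

## Known limitations

* The supplementary numerical model and fitted equilibrium constants of the
  original study are unpublished; all functional forms follow the main-text
  description and every constant is a free parameter.  Projections such as
  "~10% initially active conjugate" are regime choices here, not fits.
* No stochastic (Gillespie) simulation and no explicit strand-displacement
  kinetics; activation/inactivation enter only through equilibria and the
  first-order inactivation law.
* Gel analysis starts from band-intensity tables; image processing is out of
  scope.
* The uncompetitive form is the only product-inhibition model implemented;
  no model comparison across inhibition mechanisms is offered.
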