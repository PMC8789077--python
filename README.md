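# rnacat

Multiple-turnover RNA cleavage kinetics for catalytic peptidyl-oligonucleotide
conjugates.

Bulge–loop inducing peptidyl-oligonucleotide conjugates are metal-free
artificial ribonucleases: an antisense DNA recognition motif hybridises
sequence-specifically to a target RNA, forces a single-stranded bulge–loop out
of the hybrid, and covalently attached arginine-rich peptides cleave the
exposed backbone.  When the cleavage fragments are short enough to dissociate,
one conjugate molecule can destroy many RNA copies — the "bind, cleave and
leave" cycle.  Demonstrating and quantifying that turnover requires a chain of
quantitative steps, and `rnacat` implements all of them as a tested Python
library:

- **`rnacat.chem` / `rnacat.duplex`** — conjugate QC: average masses and MALDI
  adduct m/z from Hill formulas; a sliding-window nearest-neighbor
  duplex-stability screen (RNA/DNA hybrid parameters) for off-target binding.
- **`rnacat.binding`** — gel-shift (EMSA) association constants, both the
  closed form K<sub>a</sub> = α / ([BC]₀(1−α)(1−α·[tRNA]₀/[BC]₀)) and exact
  1:1 isotherm curve fits.
- **`rnacat.quantify`** — reduction of FRET de-quenching fluorescence
  (normalised between untreated background and an RNase-A 100% control) and
  gel densitometry tables to cleavage extents, product concentrations, and
  turnover numbers (molecules cleaved per conjugate).
- **`rnacat.progress`** — non-linear progress-curve fits
  [P](t) = v₀/η·(1 − e^(−ηt)), yielding the initial velocity v₀ and the
  non-linearity factor η (negative = accelerating/activation, positive =
  decelerating/inactivation).
- **`rnacat.model`** — the core contribution: a coupled-equilibrium model in
  which substrate and conjugate self-association (K_s, K_c) limit the
  *available* substrate [S]_a and *active* conjugate [C]_a, the catalyst binds
  substrate fully (K_CS, the cleavable complex), partially (K_SS), doubly
  (K_ds) and binds product fragments (K_P), cleavage proceeds at k_cat from
  the full complex, and double occupancy drives irreversible inactivation
  (k_inact).  Binding is treated as instantaneously equilibrated relative to
  catalysis (quasi-steady state), and the reaction is integrated forward with
  the speciation re-solved at every step.
- **`rnacat.infer`** — Michaelis–Menten estimation on available substrate and
  active conjugate (V_max = [C]_a·k_cat), uncompetitive product inhibition
  v = k_cat·c·s/(K_m + s(1 + p/K_i)), and a nested full-model fit
  (approximate by the MM stage, refine by bounded multi-start least squares).
- **`rnacat.synth`** — synthetic raw data with known ground truth for every
  stage (plate-reader series, gel lane tables, binding titrations), used by
  the test suite's recovery studies.

## Worked example

`examples/` contains one short script per capability.  Recovering kinetic
constants from a noisy simulated experiment
(`python examples/07_full_inference.py`):

```
truth:     k_cat = 0.8 1/h, Kcs(=Km) = 22.0 uM
mechanistic fit: k_cat = 0.776 +/- 0.006 1/h  (rss 12.62)
MM stage:  k_cat = 0.755 1/h, Km = 19.9 uM
start-to-start dispersion: {'k_cat': 5.05e-10}
```

A five-condition assay (5 µM conjugate, substrate at 2–30-fold excess,
sampled 0–96 h) was simulated at 5% multiplicative noise from the preset with
k_cat = 0.8 h⁻¹ and K_m = 22 µM; the fit recovers the turnover number within
3% and the Michaelis constant within 10%.  Turnover numbers recomputed from a
published quantification table (`python examples/04_turnover_table.py`):

```
conjugate     BC5-L-b  BC5-L-bb  BC5-a
substrate_uM
10                1.2       2.0    1.2
25                3.6       4.0    3.0
50                5.0       6.6    5.8
100               5.6       5.4    6.4
150               3.2       5.6    3.6
```

Every value above 1 is genuine catalytic turnover; the rise-then-fall with
substrate excess is the signature of catalyst inactivation at high substrate
load, which the forward model reproduces (`examples/06_simulate_turnover.py`).

A thin CLI mirrors the library (`rnacat mass`, `rnacat scan`,
`rnacat binding fit`, `rnacat quantify ...`, `rnacat kinetics fit-progress`,
`rnacat model simulate`, `rnacat infer ...`, `rnacat synth ...`,
`rnacat pipeline`).

## Documentation

`docs/methods.md` describes the model, its assumptions, the parameter
conventions and defaults, what the synthetic-data generator does and does not
emulate, and the documented identifiability limits of fitting a rich
equilibrium model to sparse 5-point progress curves.
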