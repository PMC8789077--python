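"""Full-model inference: recover kinetic constants from noisy curves.

Generates one noisy (5% cv) standard-design experiment from the
paper-like preset (k_cat = 0.8 1/h, Km = 22 uM), then refines k_cat by
fitting the forward model to all five progress curves and reads the
phenomenological (k_cat, Km) off the Michaelis-Menten stage.
"""

from rnacat import KineticParams, NoiseSpec, fit_full_model, generate_assay
from rnacat.presets import paper_like, standard_conditions

eq, kin = paper_like()
conditions = standard_conditions()
fixture = generate_assay(eq, kin, noise=NoiseSpec(0.05, seed=2024))

result = fit_full_model(
    fixture.progress_curves(), conditions,
    init_eq=eq, init_kin=KineticParams(k_cat=0.3, Km=22.0, Ki=20.0),
    float_params=("k_cat",), n_starts=2, seed=1, max_step=0.5,
)

print(f"truth:     k_cat = {kin.k_cat} 1/h, Kcs(=Km) = {eq.Kcs} uM")
print(f"mechanistic fit: k_cat = {result.params['k_cat']:.3f} "
      f"+/- {result.param_se['k_cat']:.3f} 1/h  (rss {result.rss:.2f})")
print(f"MM stage:  k_cat = {result.kinetic.k_cat:.3f} 1/h, "
      f"Km = {result.kinetic.Km:.1f} uM")
print(f"start-to-start dispersion: {dict(result.start_dispersion)}")
print("\nThe MM-stage constants are the better-identified summary on this"
      "\nsparse 5-point design; dispersion near zero means all seeded"
      "\nstarts agreed.")
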