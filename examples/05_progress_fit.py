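"""Non-linear progress-curve fits of product time courses.

Simulates the standard assay design from the inactivation-enabled
demonstration preset, reduces the fluorescence to product
concentrations, and fits [P](t) = v0/eta (1 - e^(-eta t)) per
condition.  Positive eta marks decelerating progress, negative eta
accelerating progress.
"""

from rnacat import NoiseSpec, classify_nonlinearity, fit_progress, generate_assay
from rnacat.presets import inactivation_demo

eq, kin = inactivation_demo()
fixture = generate_assay(eq, kin, noise=NoiseSpec(0.03, seed=42))

print("condition     v0 (uM/h)   eta (1/h)   linear v0   class")
for curve in fixture.progress_curves():
    f = fit_progress(curve)
    print(f"{curve.condition_id:12s} {f.v0:9.3f}  {f.eta:+10.4f}  "
          f"{f.linear_v0:9.3f}   {classify_nonlinearity(f)}")

print("\nv0 peaks at intermediate excess and eta is positive at high"
      "\nexcess: the catalyst is progressively inactivated while it is"
      "\ndoubly occupied by partially-bound substrate.")
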