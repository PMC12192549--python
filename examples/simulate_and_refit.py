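"""Parameter recovery: refit the reference regression on a synthetic cohort.

Generates 20,000 subjects whose THV lies on the published reference plane
plus 72.4 mL Gaussian noise (no disease-related shift), then refits the
regression by ordinary least squares.  The fitted coefficients should land
within sampling error of the generating truth (456, -221, -335) and the
fitted 95% half-width near 142 mL.
"""

import numpy as np

from thvnorm import default_config, fit_reference_model, generate_cohort, mosteller_bsa

cfg = default_config(n=20_000, seed=11)
cfg = cfg.model_copy(
    update={
        "risk_shift": {
            s: {c: {"low": 0.0, "high": 0.0} for c in ("normal", "overweight", "obese")}
            for s in ("F", "M")
        }
    }
)
records = generate_cohort(cfg)

h = np.array([r.height for r in records])
w = np.array([r.weight for r in records])
d = h - mosteller_bsa(h, w)
thv = np.array([r.thv_measured for r in records])

m = fit_reference_model(np.column_stack([h, d, thv]))
print(f"n = {m.n_fit}")
print(f"height coefficient: {m.coef_height:7.1f} mL/m   (truth 456)")
print(f"h-BSA coefficient:  {m.coef_d:7.1f} mL        (truth -221)")
print(f"intercept:          {m.intercept:7.1f} mL      (truth -335)")
print(f"95% half-width:     {m.half_width:7.1f} mL     (truth 142)")
print(f"multiple R:         {m.r_multiple:7.2f}")
print(
    "\nEach coefficient sits within a few standard errors of the value used "
    "to generate the cohort; the half-width recovers the noise scale."
)
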