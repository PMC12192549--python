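"""Repeatability of THV measurements: Bland-Altman limits and ICC.

Simulates 125 subjects measured twice by the same reader with a small
systematic offset (-1.7 mL) and 16 mL repeat noise, then summarizes
agreement: mean difference, 95% limits of agreement, intraclass correlation
(two-way random, absolute agreement, single measure) and Pearson r.
"""

import numpy as np

from thvnorm import agreement_stats

rng = np.random.default_rng(125)
truth = rng.normal(500, 90, size=125)
first = truth + rng.normal(-1.7, 16, size=125)

s = agreement_stats(np.column_stack([first, truth]))
print(f"n pairs:          {s.n}")
print(f"mean difference:  {s.mean_difference:6.1f} mL  ({s.mean_difference_pct:.1f}%)")
print(f"limits of agreement: [{s.loa_lower:.1f}, {s.loa_upper:.1f}] mL")
print(f"ICC:              {s.icc:.3f}   ({s.icc_model})")
print(f"Pearson r:        {s.pearson_r:.3f}")
print(
    "\nAn ICC near 1 with limits of agreement within ~7% of a typical THV "
    "indicates the measurement noise is small against the 142 mL band used "
    "for classification."
)
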