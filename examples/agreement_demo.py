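"""The agreement layer on a hand-made paired sample.

Two 'scanners' measure the same 12 subjects; scanner B adds a small offset
and noise. Shows the normality-gated comparison, ICC(2,1) with 95% CI, and
Bland-Altman bias with limits of agreement.
"""

import numpy as np

import cardiodti as cd

rng = np.random.default_rng(0)
truth = rng.normal(0.30, 0.05, 12)  # e.g. per-subject FA
a = truth + rng.normal(0, 0.01, 12)
b = truth + 0.01 + rng.normal(0, 0.01, 12)

s = cd.PairedSample(a, b, name="FA", units="")
r = cd.agreement_analysis(s)

print(f"condition A: {r.mean_a:.4f} +/- {r.sd_a:.4f}")
print(f"condition B: {r.mean_b:.4f} +/- {r.sd_b:.4f}")
print(f"normality p (A, B): {r.normality_a.p:.3f}, {r.normality_b.p:.3f}")
print(f"comparison: {r.comparison.test}, p = {r.comparison.p:.4f}")
print(f"ICC(2,1): {r.icc.value:.3f} (95% CI {r.icc.ci_low:.3f}, {r.icc.ci_high:.3f})")
print(f"Bland-Altman bias: {r.bland_altman.bias:.4f} "
      f"(LoA {r.bland_altman.loa_low:.4f}, {r.bland_altman.loa_high:.4f})")
print("-> the constant -0.01 offset appears as the Bland-Altman bias and")
print("   depresses the absolute-agreement ICC even when correlation is high.")
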