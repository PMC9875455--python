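"""A small end-to-end two-scanner comparison study.

Six phantom hearts, two conditions emulating 1.5 T (SNR 15) and 3.0 T
(SNR 20), shells b=200 and b=1000. Prints the comparison and ICC tables.
No true condition effect is simulated, so comparisons are expected to be
non-significant at the ~5% false-positive level, and scalar-index agreement
should be better at the higher b-value, where per-scan estimation noise is
smaller relative to between-heart variation.
"""

import cardiodti as cd

cfg = cd.StudyConfig(
    n_hearts=6,
    shells=(200.0, 1000.0),
    conditions=(cd.Condition("1.5T", snr=15.0), cd.Condition("3.0T", snr=20.0)),
    seed=3,
)
res = cd.run_study(cfg)

print("comparison (mean +/- SD per condition, test, p):")
print(res.comparison_table.round(4).to_string(index=False))
print()
print("ICC(2,1) with 95% CI:")
print(res.icc_table.round(3).to_string(index=False))
print()
print("-> no true scanner effect was simulated, so p-values are mostly > 0.05")
print("   (with 12 tests on 6 hearts the occasional ~5%-level false positive")
print("   is expected); ICC(MD) and ICC(FA) improve markedly from b=200 to")
print("   b=1000, the low-b agreement degradation the full 18-heart study")
print("   reproduces systematically.")
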