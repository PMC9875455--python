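"""Observer-reproducibility experiment on perturbed myocardium ROIs.

Each phantom heart is analysed twice under independently perturbed masks
(random removal of boundary voxels, emulating ROI re-drawing). The
per-index ICC shows which indices are robust to ROI placement: voxelwise
scalars (FA, MD) barely move, while the HA transmural gradient — which
depends on the estimated wall depth — is the most boundary-sensitive.
"""

import cardiodti as cd

cfg = cd.StudyConfig(n_hearts=10, observer_radius=1, seed=8)
table = cd.run_reproducibility(cfg)
print(table.round(4).to_string(index=False))
print()
print("-> ICC near 1 for FA/MD; lower for depth-dependent angle summaries.")
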