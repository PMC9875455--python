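# Methods

## Signal model and phantom

The simulator uses the monoexponential Stejskal–Tanner model: for a voxel
with diffusion tensor D (mm²/s), b-value b (s/mm²) and unit gradient g, the
noiseless magnitude signal is S = S₀·exp(−b·gᵀDg), and S = S₀ for b = 0.
Rician noise is applied as |S + n₁ + i·n₂| with n₁, n₂ independent zero-mean
Gaussians of standard deviation σ = S₀/SNR, independently per voxel and
volume. SNR is defined against S₀ (the b=0 myocardial signal); SNR = ∞
yields the noiseless signal. No eddy-current, susceptibility, motion or
partial-volume effects are modelled, and the diffusion model is purely
Gaussian (no kurtosis): the phantom validates the estimation and statistics
chain, not image-quality physics.

The phantom is an annulus (inner radius 12 mm, outer 30 mm by default) on a
64×64 grid of 2×2×5 mm voxels, replicated over five short-axis slices —
ex-vivo tissue does not move, so slices are analytic copies and one mid
slice is analysed, mirroring single-slice reporting practice. The fiber
direction E1 lies in the local circumferential–longitudinal plane at helix
angle HA(d) = HA_endo + (HA_epi − HA_endo)·d with d the analytic transmural
depth (r − r_in)/(r_out − r_in); defaults +60°/−60° give a transmural
gradient of −120°/100% = −1.2 deg/%trans. E2 sits at a constant prescribed
sheetlet angle (default 35°) in the plane orthogonal to E1, measured from
the cross-fiber tangent axis toward radial. Eigenvalues default to
(0.95, 0.65, 0.50)×10⁻³ mm²/s, i.e. MD = 0.7×10⁻³ mm²/s and FA ≈ 0.316,
representative of formalin-fixed human myocardium; the tensor is
D = Σᵢ Lᵢ EᵢEᵢᵀ exactly, so ground truth is available per voxel.

The acquisition protocol defaults to shells b ∈ {200, 400, 600, 800, 1000}
s/mm² with 16 directions per shell and one b=0 volume. The direction set is
generated by a deterministic electrostatic-repulsion optimisation
(antipodally symmetric energy, fixed start, projected gradient descent) and
is always written explicitly to the bvec file, so fitting never assumes a
scheme. One b=0 per series is the mathematical minimum for the log-linear
fit; the count is configurable.

## Tensor estimation

Each shell is fitted independently together with the b=0 volume(s),
matching acquisitions performed as separate single-shell series. The
estimator is ordinary least squares on log-signals against the standard
b-matrix design row [1, −b·gx², −b·gy², −b·gz², −2b·gx·gy, −2b·gx·gz,
−2b·gy·gz]; noiseless data are recovered exactly (the system is consistent)
and the fit is a linear map, which keeps its noise behaviour analysable. A
weighted (WLS) second pass is available but off by default. Non-positive
signals are floored at half the voxel's smallest positive signal before the
log (keeps the fit defined without discarding voxels); voxels with no
positive signal are flagged invalid. Negative eigenvalues after
diagonalisation are clamped to zero and flagged rather than rejected, so
low-SNR maps remain computable; FA is computed after clamping and therefore
stays in [0, 1].

## Wall coordinates, depth and rings

Frames are built per slice in 2D with longitudinal = slice normal (+z),
radial = unit vector from the slice's mask centroid to the voxel, and
circumferential = longitudinal × radial (right-handed:
radial × circumferential = longitudinal). Transmural depth is
d_endo/(d_endo + d_epi), where the two distances are Euclidean distance
transforms to the cavity-facing and outer-facing background components;
because discrete distance transforms measure centre-to-centre distances,
half an in-plane voxel is subtracted from each side, which makes the
estimator match the analytic interface-to-interface depth to within a
voxel — without this correction the depth range compresses and the
recovered HA gradient overshoots by ~15%. Rings are five equal-width depth
bins, left-closed/right-open except the last; empty rings raise a warning
and the gradient regression proceeds on the remaining rings (≥ 2 required).

## Indices

MD = (L1+L2+L3)/3, FA = √(3/2)·‖L − MD‖/‖L‖ (0 for a zero tensor). Angles
treat eigenvectors as axes (sign-flip invariant, folded into [−90°, 90°]):
HA is the signed angle of E1's tangent-plane projection from
circumferential toward +longitudinal; TA the signed angle of E1's
short-axis-plane projection from circumferential toward +radial; E2A the
absolute angle (0–90°) of E2's projection onto the cross-myocyte plane
(spanned by radial and the tangent-plane axis orthogonal to the fiber
projection), measured from the tangent axis. These sign conventions are a
documented choice — the quantities are conventionally reported without a
fixed global sign — and configurable at the phantom level. Projections with
norm < 10⁻⁶ are flagged invalid (e.g. TA for a purely longitudinal E1).
Ring means use plain arithmetic means of the folded angles, not circular
statistics: folded HA stays well away from the ±90° wrap in practice, and
summaries elsewhere use plain means too. The HA transmural gradient is the
OLS slope of ring-mean HA against ring-centre depth (10, 30, 50, 70, 90
%trans) in degrees per %trans; regression against each ring's observed mean
depth is available via `gradient_abscissa="ring_mean_depth"`.

One known geometric effect: the voxelwise slice-mean of a symmetric ±60°
ramp is not 0 but ≈ −9°, because outer rings contain more voxels (the
area-weighted ramp mean is 60 − 120·E[depth] with E[depth] ≈ 0.57 for the
default radii). The ring-based gradient is unaffected; mean HA and the
gradient measure different things.

## Agreement statistics

Per index × b-value, the two conditions' per-heart summary values form a
paired sample. Normality is tested per condition with Shapiro–Wilk; if both
pass at α = 0.05 a paired Student's t-test is used, otherwise the Wilcoxon
signed-rank test (a paired design is assumed because the same hearts are
scanned under both conditions; an unpaired variant is available). ICC is
ICC(2,1) — two-way random effects, absolute agreement, single measurement —
computed from the two-way ANOVA mean squares,
(MS_R − MS_E)/(MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E)) with k = 2, with the
Shrout–Fleiss F-distribution 95% CI; absolute agreement is the appropriate
form for scanner interchangeability and may be negative. Bland–Altman
reports mean(A−B) ± 1.96·SD (n−1 denominator). No multiple-testing
correction is applied, consistent with how such comparison tables are
conventionally reported; p-values across the 6 indices × 5 shells grid
should be read accordingly. Identical inputs (A = B) are reported as
degenerate: ICC 1, p = 1.

## Study and reproducibility design

A study simulates `n_hearts` (default 18) phantoms whose parameters are
jittered uniformly around the defaults (eigenvalues ±15%, helix-surface
angles ±10°, sheetlet angle ±5°, radii ±2 mm), producing between-heart
spreads of the summary indices comparable to those seen across explanted
human hearts. Two conditions are emulated purely as SNR (and optionally
signal-scale) differences — defaults 15 vs 20 — because scalar DTI indices
should not depend on field strength except through noise. Seeds for
geometry and per-scan noise are drawn once, in fixed order, from the study
seed, so studies are byte-reproducible; a `shared_noise_seed` switch makes
the two conditions bit-identical for self-agreement checks.

Observer variability is emulated by perturbing the myocardium ROI: voxels
in the boundary band (an in-plane erosion of configurable radius, default
1 voxel) are dropped independently with probability 0.5. Only the
erosion side is perturbed — expanding the ROI would admit background (air)
voxels that a human observer would not include. The wall frame and depth
are recomputed per perturbed mask, so boundary-sensitive quantities (HA and
its gradient, which depend on the estimated depth normalisation) degrade
faster than voxelwise scalars — the qualitative ordering the
reproducibility experiment is designed to exhibit.

## Noise-floor behaviour

Two mechanisms tie estimation quality to b-value. First, the Rician floor
biases log-signals upward once the attenuated SNR is low, shrinking fitted
diffusivities at high b. Second — dominant at moderate SNR — the log of a
Rician variable is skewed, and the fit divides by b, so the *median* fitted
MD is inflated more at low b: at SNR 15 the pooled median MD falls
monotonically from ≈ 7.1×10⁻⁴ at b=200 to ≈ 7.0×10⁻⁴ mm²/s at b=1000. The
adjacent-shell differences are small (down to ~5×10⁻⁷ mm²/s), so the
monotonicity check pools ~120 replicate acquisitions of the 3 020-voxel
phantom (~1.8×10⁵ voxel fits per shell) to resolve them; this is a
problem-size choice of the validation, not of the method. The same
noise scaling (estimation error ∝ 1/b at fixed attenuation regime) makes
between-replicate ICC of MD systematically higher at b=1000 than b=200,
reproducing the low-b agreement degradation seen in paired-scanner tables.

## Numerical and degenerate-case choices

Eigenvector sign is never fixed; all angle maps fold to [−90°, 90°].
Isotropic (degenerate-eigenvalue) tensors have arbitrary eigenbases; the
scalar indices are basis-independent and the angle maps remain defined
(their values are then meaningless but bounded — FA ≈ 0 identifies such
voxels). The distance-transform depth requires an annulus with a cavity;
masks without one raise a geometry error. Constant vectors in the
statistical layer are flagged degenerate rather than erroring. Default
problem sizes (64×64×5 grid, 18 hearts, 16 directions) keep a full study at
a few seconds per heart-condition on one CPU.

## Limitations

Synthetic validation shows the chain is correct and calibrated under its
own assumptions; it cannot show robustness to EPI distortion, fixation
gradients, partial volume at the thin apex, papillary muscles, or
non-annular LV shapes. Observed index values on real data will also depend
on the scanner's actual (spatially varying) SNR, which the two-condition
emulation collapses into a single number.
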