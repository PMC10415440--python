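# Methods

## Signal model

A spoiled multi-echo gradient-echo acquisition samples each voxel at echo
times `TE_n = TE1 + (n-1)·ΔTE`.  The complex signal is modelled as

    I_n = exp(−R2*·TE_n) · exp(j·2π·Δf·TE_n) · [ PW + PF · Σ_p α_p·exp(j·2π·f_p·TE_n) ]

with complex water/fat amplitudes `PW`, `PF` (they share the receiver/excitation
phase), effective transverse relaxation `R2*` (1/s), off-resonance field map
`Δf` (Hz), and a multi-peak fat spectrum `(f_p, α_p)`, `Σ α_p = 1`.  The
proton density fat fraction is `PDFF = |PF| / (|PW| + |PF|)`; voxels with no
signal (`|PW| + |PF| = 0`) are defined as PDFF 0 and removed from the
validity mask so NaNs never propagate.

The fat spectrum is not hard-coded: a six-peak triglyceride model for liver
(ppm offsets −3.80, −3.40, −2.60, −1.94, −0.39, +0.60 relative to water;
relative amplitudes 0.087, 0.693, 0.128, 0.004, 0.039, 0.048) ships as a
YAML file inside the package and can be overridden by path.  ppm offsets
convert to Hz with f = γ̄·B0·ppm, γ̄ = 42.577478518 MHz/T, so the dominant
methylene peak sits at −217 Hz at 1.5 T.  Units are SI internally (s, Hz,
1/s); milliseconds are accepted only at CLI/config boundaries.

## Synthetic phantoms

No measured data ships with the package; a seeded generator emulates 2-D
abdominal slices: a body ellipse containing a handful of elliptical
compartments, each with constant fat fraction, constant R2* and its own
proton density, over a smooth low-order (quadratic) polynomial field map
with bounded amplitude.  Water and fat share a random per-slice initial
phase, so simulated inputs are genuinely complex.  Defaults, chosen once as
the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| fat-fraction range | 0.04–0.36 | hepatic range the method must cover |
| compartment R2* | 10–150 1/s | inside the [0, 200] 1/s label envelope |
| field-map amplitude | 150 Hz | abdominal-realistic at 1.5 T, within ±400 Hz |
| noise | complex Gaussian, SNR 50 | placeholder; in-vivo SNR is scanner-dependent |
| echo timing | TE1/ΔTE = 1.29/2.1 ms, 3 or 6 echoes | standard 1.5 T protocols |

Noise is circular complex Gaussian added to both quadratures (magnitude
therefore Rician), with σ = mean first-echo foreground magnitude / SNR.
What the phantoms deliberately lack: anatomy beyond ellipses, motion and
breathing artifacts, coil sensitivities, parallel-imaging undersampling and
T1 weighting.  Passing tests therefore demonstrate correctness of the
pipeline and learnability of the mapping under these idealised conditions,
not in-vivo accuracy.

Preprocessing mirrors a clinical pipeline: image resizing by centred
cropping of the 2-D DFT (scaled so mean intensity is preserved; the stated
operation is only "subsampling", so DC preservation is this package's
choice) and background masking by thresholding the mean all-echo magnitude
at 5% of its maximum (threshold value likewise this package's default).

## Classical voxel fit (reference method)

The reference water-fat separation is a voxel-independent VARPRO fit: for
fixed (Δf, R2*) the model is linear in (PW, PF), which are eliminated by
closed-form complex least squares; the remaining 2-D problem is searched by
a coarse grid over the field map (default 41 starts over ±400 Hz, 5 R2*
values over [0, 200] 1/s) followed by bounded trust-region refinement from
the best few distinct local minima of the residual profile.

Two numerical points matter.  First, for uniform echo spacing the model is
exactly periodic in Δf with period 1/ΔTE (≈ 476 Hz at ΔTE = 2.1 ms), so a
±400 Hz search range can contain two equally exact minima — the water-fat
swap.  Spatially regularised global methods (graph cuts) resolve this with
neighbourhood information; this voxel-independent fit instead breaks
near-ties toward the solution nearest zero off-resonance, which is exact
recovery whenever the true |Δf| is below half a period.  Second, magnitude
fitting would discard the phase that makes the problem well-posed; the fit
is complex throughout.  No spatial regularisation is applied — the fitter
is a desk-scale oracle, not a graph-cut reimplementation.

## Network architectures

Both networks are 2-D encoder–decoder CNNs over channel-packed complex
echoes (`[Re e1, Im e1, Re e2, …]`, so 6 channels for 3 echoes).  The
encoder is four blocks of (3×3 conv → ReLU → batch norm) ×2 — activation
before normalisation, kept in this order deliberately — with widths
72/144/288/576 at full scale and 2×2 max pooling between blocks, ending in
a bottleneck block of 1152 channels at 1/16 resolution (12×12 for 192×192
inputs).  Decoders mirror the encoder with kernel-2 stride-2 transposed
convolutions (the exact shape-inverse of the pooling), concatenation with
the equal-shape encoder feature, and the same conv blocks.

The multi-decoder variant (MDWF-Net) attaches three decoders to the shared
latent space: water/fat magnitudes (2 channels), R2*/200 (1 channel), and
Δf/400 (1 channel).  The field-map decoder applies a spatial self-attention
block immediately after its first upsampling (1/8 resolution): 1×1
convolutions form queries/keys at 1/8 channel width and full-width values,
attention weights are a row-softmax over all positions, and the output is
`x + γ·att(x)` with γ learned from 0 — the block starts as the identity.
The single-decoder U-Net comparator shares the encoder design and emits one
4-channel output through three activation-specific 1×1 heads.

Output activations are not dictated by the architecture description and are
implementation choices here: ReLU on water/fat (non-negative magnitudes),
sigmoid on normalised R2* (label range [0, 1]), linear on the signed
normalised field map.  Weights are He-uniform, seeded; attention head
count is 1 and decoder widths mirror the encoder, both unspecified details
resolved by the simplest choice.

## The numpy autodiff backend

The networks run on a small reverse-mode automatic-differentiation backend
written on numpy (`wfsep.tensor`): a taped `Tensor`, the dozen operations an
encoder–decoder CNN needs, He-uniform initialisation, and Adam.
Convolutions lower to im2col + GEMM so the arithmetic stays in BLAS; the
working precision is float32, switchable to float64 (the test suite
verifies every operation and the fully composed networks against central
finite differences in double precision).  One subtlety worth recording:
max-pooling backward must route the gradient to exactly one argmax per
window — after ReLU, tied maxima (equal zeros) are pervasive, and routing
to all ties silently inflates gradients of shift-type parameters.
Training is single-threaded deterministic: identical seeds reproduce
identical trajectories.

## Training

Labels are `[|PW|/s, |PF|/s, R2*/200, Δf/400]` with `s` the per-volume
maximum magnitude; R2* above 200 1/s is clipped with a logged count.  The
signed field map gives labels in [−1, 1]; an absolute-value variant is
selectable by flag but not default, since the sign carries physics.  Inputs
are divided by the 99th-percentile in-mask magnitude (an implementation
choice; some scaling is required and a percentile resists outliers).  Both
labels and inputs are masked by the all-echo magnitude threshold.  The loss
is the mean absolute error over in-mask pixels across all four channels.
Optimisation is Adam under a cosine-decay schedule
`lr(e) = lr0/2·(1 + cos(π e/E))`; the full-scale recipe is 120 epochs,
batch 32, lr0 5·10⁻⁴.  Train/validation splitting is phantom-level
(subject-level), never slice-level.

The **desk preset** is the reduced configuration every end-to-end test and
the acceptance script use: 64×64 phantoms, encoder widths [8, 16, 32, 64]
(bottleneck 128 at 4×4), 200 noiseless 3-echo slices (170/30 split),
15 epochs, batch 8, lr0 3·10⁻³.  Batch and learning rate are free
parameters of this preset; 15 epochs × ~21 steps is a short schedule for
which the full-scale learning rate is too conservative — 3·10⁻³ with batch
8 is the package's setting for this model size.  The preset exists so a
complete simulate → train → evaluate cycle runs on one CPU in minutes; it
is a learnability demonstration, not a reproduction of full-scale accuracy.

## Evaluation protocol

Agreement between two PDFF maps follows the standard imaging-biomarker
protocol: co-localised circular ROIs (two per subject), ROI mean and sample
(n−1) standard deviation, ordinary least squares of test on reference means
(free intercept, reported not forced), Bland-Altman bias with 1.96·STD
limits of agreement, and a one-way ANOVA over ROI standard deviations
(a blurring proxy) followed by Tukey-HSD pairwise comparisons at α = 0.05,
with both ROIs pooled.  Degenerate ANOVA inputs (all groups constant and
identical) return p = 1 flagged non-significant rather than NaN.  The
statistics are backed by scipy/statsmodels implementations; the test suite
cross-checks Tukey p-values against an independent implementation.

## Problem sizes

Default suites use 8×8–32×32 oracle fixtures, a 32×32 fit map, and the
desk training preset above; the acceptance script runs the same sizes plus
a 13-subject × 2-ROI agreement protocol with ROI-restricted 6-echo voxel
fits.  These sizes are the package's reduced-scale study conditions chosen
so the whole cycle stays in the minutes range on a single CPU.

## Known limitations

- The desk preset trains for roughly one-sixtieth of the full-scale
  optimisation budget and under-fits: its held-out PDFF error clears the
  learnability bound but is dominated by slice-average fat fraction rather
  than within-slice contrast, so the ROI agreement statistics the
  acceptance script reports (regression slope, R²) are weak at desk scale.
  They are reported as computed; full-scale agreement requires full-scale
  training.
- Voxel-independent fitting cannot resolve the swap ambiguity when the true
  |Δf| exceeds half the aliasing period; only spatial regularisation can.
- The phantoms' piecewise-constant compartments make the learning task
  easier than anatomy; reported desk-scale errors underestimate in-vivo ones.
- Network water/fat outputs are magnitudes in input-normalised units; the
  absolute scale is recovered only up to the input normalisation factor
  (PDFF, R2* and Δf are unaffected).
- 3-echo classical fits are near the identifiability margin; the package
  reports but does not assert their noiseless recovery quality.
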