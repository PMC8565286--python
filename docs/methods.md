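# Methods

This note records the models, conventions, and numerical choices behind
`qda`, in the order data flows through the package.

## Correlation rows and metric definitions

All metrics derive from one voxel's Pearson correlations with every other
in-mask voxel ("correlation row", self excluded). Time courses are centered
and scaled to unit norm once, so a correlation is a dot product; values are
clamped to [−1, 1] against rounding.

**CSI.** CSI_P is the mean of the strictly positive coefficients, CSI_N of
the strictly negative ones (a coefficient of exactly 0 belongs to neither —
strict inequalities). An empty part is undefined (NaN), not zero. The mixed
CSI is defined as the mean over *all* V−1 coefficients, Σ CC/(V−1); the
alternative reading CSI_P + CSI_N is recoverable from the parts, but the
all-coefficient mean is what the package reports as `csi`.

**CDI.** The row is binned into `n_bins` (default 200) even bins on [−1, 1],
left-closed/right-open with the last bin closed, so −1 and +1 both count and
0 is a bin edge (hence `n_bins` must be even). The kernel is evaluated at
bin centers and inner-producted with the counts — the practical form of the
histogram⊗kernel convolution when only the negative/positive split of the
zero-lag term is needed. Bins with negative centers form CDI_N, positive
centers CDI_P; the bin straddling 0⁺ (center +0.005) counts as positive,
which is immaterial because every kernel is ≈ 0 there. Normalizing by V−1
(default) makes CDI a density in [0, 1] invariant to mask size; raw weighted
counts are available via `normalize=False` / `--no-normalize`.

The binning error of CDI against the exact unbinned weighted sum is bounded
by half a bin width per coefficient (0.005 at 200 bins) and is far smaller
in aggregate; the acceptance script measures it.

**Kernels.** |x|^p for p = 1..4, sin²(πx/2), and the square well
1{|x| > τ} (default τ = 0.3), which reproduces classical thresholded degree
centrality. The signum kernel is provided as a counting kernel only: weighted
by sign(x), histogram counts give np and nn, not their means, so CSI is
computed from its own definition rather than through the kernel path.

**Degenerate voxels.** Zero-variance time courses cannot be correlated.
They are flagged during standardization; their own metrics are NaN and they
are excluded from every other voxel's row, from np/nn, and from the V−1
denominators, so remaining voxels behave exactly as if the degenerate ones
were outside the mask (a unit test asserts this equivalence).

**Streaming.** Rows are produced `block_size` seeds at a time
(matrix-matrix product against the full standardized matrix), histogrammed
with one flat bincount per block, and reduced immediately; the V×V matrix
never exists for V > block_size. Accumulation is float64; per-row reductions
make the result exactly independent of block size.

## Temporal preprocessing

Inputs are assumed motion-corrected and spatially registered upstream; the
package owns only the temporal stages, in fixed order despike → detrend →
nuisance regression → low-pass, with spatial smoothing applied to the 4D
volume beforehand.

- **Despiking** (optional): running-median baseline (window 5), robust SD =
  1.4826·MAD of the deviations, samples beyond `z_clip` (default 4) robust
  SDs clipped to the boundary. Chosen for being parameter-light and exactly
  testable; a flat series with one spike collapses the spike to baseline.
- **Detrending**: least-squares polynomial of order 0–3 on a Legendre basis
  over time rescaled to [−1, 1] (conditioning; order 0 = mean removal).
  Detrending doubles as the high-pass side of the effective band-pass — no
  separate high-pass filter is applied.
- **Nuisance regression**: OLS residual on [intercept | regressors]; any
  column count is accepted (the classical set is 14: six motion parameters,
  ventricle mean, and their first derivatives). Rank deficiency is an error
  that names the collinear columns.
- **Low-pass**: zero-phase (forward–backward) Butterworth of order 4,
  default cutoff 0.08 Hz; the cutoff must be below Nyquist = 1/(2·TR).
  Forward–backward filtering squares the magnitude response, giving ~0.7%
  stop-band leakage at 0.15 Hz with TR 2.5 s.
- **Smoothing**: Gaussian (FWHM default 4 mm, truncated at 3 SD) with
  weights renormalized over in-mask neighbors, so constants are preserved
  and no signal bleeds across the mask boundary. At FWHM ≤ ~0.25 voxel the
  kernel radius rounds to zero and the stage is the identity.

## Group inference

**Age regression.** Per voxel, OLS of the metric on [1, age, gender];
β is the age coefficient, t = β/SE, and the partial correlation of age
given gender is recovered as r = sign(t)·√(t²/(t²+df)), df = n−3. Voxels
undefined in any subject are undefined in all outputs. Numerically perfect
fits (residual variance at rounding level) yield t = ±1e10 (sign of β) or 0
when the slope itself is at rounding level.

**Cluster formation.** Positive clusters from {t ≥ t_crit}, negative from
{t ≤ −t_crit}, labeled under face (6-)connectivity — the most conservative
standard convention. Centers of mass are unweighted means of member-voxel
world coordinates.

**Permutation FWE.** The age column is permuted across subjects (gender
stays attached to its subject), the regression is refit, and both signs are
reclustered; the null statistic is the maximum over all clusters. Corrected
p-values use (1 + #{null ≥ obs})/(1 + n_perm), so the attainable floor is
1/(n_perm+1) and p = 0 is impossible. The default statistic is cluster
**extent**, with a tie-break: the max statistic is the lexicographic pair
(size, mass), mass being the sum of |t| over the cluster. The tie-break
matters because extent is a small integer at realistic thresholds; heavy
ties make the exact permutation p-value conservative (measured family-wise
rates near 0.02 instead of 0.05 in null simulations), while the continuous
mass component makes ties almost surely vanish and restores the nominal
level. Pure cluster mass is available via `statistic="mass"`.

**Companions.** The young/elderly verification uses a pooled-variance
two-sample t-test by default (Welch's statistic is available via
`equal_var=False`); subgroup intervals are
closed at both ends (an 18–30 young and 64–76 elderly split of a 227-row
cohort yields 124/76 with 27 excluded). Seed maps correlate the mean ROI
time course with every voxel; the group map is a one-sample t-test on
Fisher-z-transformed correlations (variance-stabilizing; not part of the
original two-step test but standard practice). The anti-correlation network
operation is implemented as the **conjunction** of both seed maps ≤ thr
(default −0.5): the literal product-map threshold cannot distinguish
mutual anti-correlation from mutual correlation, since the product of two
negative values is positive; the product map is emitted alongside for
inspection.

## Synthetic cohorts

Each network is a set of grid boxes whose member voxels share a latent
signal: white noise low-passed at 0.05 Hz (zero-phase Butterworth) and
scaled to unit variance — mimicking resting-state low-frequency
fluctuations. Member time courses are
(loading + age_slope·(age − age_mid))·latent(t) plus AR(1) noise
(φ = 0.3, marginal SD 1.0) plus white noise (SD 0.5). Anti-correlated
networks share one latent with opposite-sign loadings. A slope that would
flip the loading's sign inside the cohort age range is rejected. Ages are
uniform on 18–76 years by default; TR 2.5 s, 150 frames, 4 mm voxels.
Per-subject generators are seeded with (cohort seed, subject index), so any
subject is reproducible in isolation. An optional spatial smoothing of the
noise field (FWHM in mm, variance restored after filtering) adds the local
spatial correlation real BOLD has.

What the generator does **not** emulate: hemodynamic response convolution,
physiological (cardiac/respiratory) aliasing, motion artifacts, tissue
contrast, or realistic brain geometry. Passing tests therefore demonstrate
the correctness and calibration of the estimators and inference machinery
under a clean low-frequency-coupling model — not robustness to the full
artifact spectrum of scanner data.

## Simulation studies and problem sizes

Two study harnesses (`qda.experiments`) feed both the test suite and the
acceptance script; sizes were chosen to keep each run in the minutes range
on one CPU while leaving the statistical question intact.

- **Type-I calibration**: 100 independent null cohorts (no networks, so
  age is independent of the maps), 24 subjects, 60 frames, 12×12×8 grid,
  spatially smoothed noise (FWHM 8 mm on 4 mm voxels), 200 permutations,
  α = 0.05. Spatially correlated noise is deliberate: cluster-extent
  inference presupposes smooth statistic maps, and with voxel-wise
  independent noise the calibration would measure the discreteness of the
  extent statistic rather than the validity of the permutation test. The
  family-wise rejection rate is checked against the 95% binomial band
  around the nominal 0.05.
- **Planted recovery**: 20 cohorts of 40 subjects, 150 frames, one
  4×4×3-voxel network (≈4% of the grid) with loading 1.0 and age slope
  −0.015/year — the coupling roughly halves from the youngest to the oldest
  subject, a strong but realistic aging effect. A replicate counts as
  detected when an FWE-significant cluster overlaps the planted voxels with
  Jaccard ≥ 0.3; the sign of the detected cluster's mean β is checked
  against the planted decline.

## Known limitations

- Histogram bin membership at ±bin-edge values follows the numpy
  convention; coefficients landing exactly on an interior edge are assigned
  to the right bin, which can move a count by one bin relative to other
  binning conventions (sub-0.005 effect on CDI).
- The Welch df is reduced to a single integer (median over voxels) rather
  than a per-voxel map.
- `csi` (mixed) and `csi_p`/`csi_n` are computed from the same streamed
  rows; there is no option to weight by anatomical distance, parcellate by
  atlas, or apply global signal regression — the latter deliberately, as it
  reshapes the negative branch of the correlation histogram that CSI_N/CDI_N
  are designed to measure.
- Spatial registration, motion correction, and resampling are out of scope;
  all volumes must already share one grid.
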