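# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `aggsplit`: a pipeline that sizes red-blood-cell (RBC)
aggregates in brightfield images of a T-junction microchannel, locates the
flow split from velocity fields, and predicts which aggregate sizes each
daughter branch receives.

## Setting and coordinate frame

The channel is a T-junction of width W = 100 um and depth D = 40 um: a
parent branch feeds two opposing daughter branches of identical
cross-section. Frames are 1216 x 700 px at 0.65 um/px. Coordinates are
normalized by the width, x* = x/W and y* = y/W, with the origin at the
intersection of the parent and daughter axes; the parent branch width spans
x* in [-0.5, 0.5]. In image rasters, x* grows with column (toward the
right daughter) and y* grows upward; the parent lies below the junction.
Pixel centres carry the coordinates. The exact pixel of the junction origin
is a free parameter of `ChannelGeometry` because it depends on how a given
acquisition was framed.

At the reference operating point the parent mean velocity is U = 320 um/s,
giving a pseudo-shear U/D = 8 1/s — a moderate-to-low shear at which
aggregation persists. The flow ratio Q* = Q_D/Q_P equals the daughter-to-
parent mean-velocity ratio U_D/U_P because all branches share one
cross-section.

## Aggregate detection

Connected (aggregated) RBCs form continuous regions of similar intensity
bounded by steep edges, so aggregate size is measured as the area of
connected high-gradient structures. The stages:

1. **Pre-processing.** A monotone percentile stretch improves global
   contrast. The anchors default to (0, 99.8): the upper percentile guards
   against hot pixels; the lower anchor sits at the frame minimum because
   structure interiors occupy only a few percent of the channel area — any
   positive lower percentile can land inside (or above) their intensity
   range and clip them flat, after which the local-mean guard in stage 3
   marks them undefined and they are lost. A 2-D Gaussian-plus-offset
   surface fitted to the bright (background) pixels is divided out to
   correct uneven illumination.
2. **Local gradients.** In every 3 x 3 window, four intensity differences
   are formed between the opposite neighbour pairs (E-W, N-S, NE-SW,
   NW-SE), each divided by the pixel-pair distance dS: 1.30 um for the
   horizontal/vertical pairs (2 x 0.65 um) and 1.61 um for the diagonal
   pairs by default. (Geometrically the diagonal pair distance at this
   resolution is 2*sqrt(2)*0.65 = 1.84 um; 1.61 um is retained as the
   published operating value and the geometric value is available through
   `PipelineConfig.diag_ds_um`.) The gradient magnitude is the root mean
   square of the four quotients, which reduces to a Prewitt-style two-axis
   magnitude for axis-aligned edges and is isotropic to first order.
3. **Normalization.** Each magnitude is divided by the mean intensity of
   its 3 x 3 window (units: intensity fraction per um). This cancels
   smooth illumination and global exposure scale, and amplifies relative
   contrast inside strongly absorbing aggregates — the property that makes
   interiors detectable, not just outlines. Pixels whose local mean falls
   below eps = 1e-3 are undefined (the normalization has no meaning at
   zero intensity) and excluded from thresholding.
4. **Blur correction (optional).** A mean-contrast reference is built from
   a non-aggregating stack: the per-pixel coefficient of variation (3 x 3
   SD over mean) is taken per frame, reduced over frames by the per-pixel
   median (robust to sporadic cell passages in finite stacks), smoothed,
   and normalized by the median of the deep channel interior; values
   within 5% of 1 snap to exactly 1 so no correction leaks into unaffected
   regions. Gradients where the map is below 1 are divided by the map
   value. The division rule is the package default and pluggable — it
   restores contrast lost to mild local blur to first order, and is not
   claimed to be exact for strong blur.
5. **Calibrated threshold.** The binarization threshold is calibrated on a
   non-aggregating reference by bisection until the mean connected-
   structure area (after the noise rule) equals the characteristic RBC
   area Ac = 15 um^2, within 2%. Ac is a deliberately conservative
   single-cell area: a flat-side RBC projects ~45 um^2 and an edge-on cell
   ~10 um^2, but dense-suspension imaging rarely resolves complete flat
   cells. A calibration sanity check requires the resulting threshold to
   sit far (> 8x) above the median background gradient; a threshold inside
   the background-noise distribution means the reference contained no
   structures and calibration fails.
6. **Structure extraction.** Pixels above threshold inside the channel
   interior (channel mask eroded by 2 px, so wall edges never register)
   are grouped by 8-connectivity; components smaller than 20% of Ac
   (3 um^2) are discarded as noise. Each surviving component yields a
   record: pixel count, area A (um^2), normalized area A* = A/Ac,
   normalized centroid, branch label (parent / left / right / junction by
   rectangular masks on the centroid), and a border flag (structures
   touching the frame border are kept and flagged rather than dropped).

Detection is deterministic: identical stack and configuration give an
identical structure table.

### Accuracy scale

On synthetic ground truth the detected mean A* tracks the generator truth
to within a few percent at population level (50-frame stacks), and the
acceptance suite enforces the 15% error scale that inspection-based
validation of this class of edge detectors supports. Individual structures
carry larger errors (rasterization, threshold shaving and merging of
touching structures), so single-structure areas should be read as
order-of-magnitude; population statistics are the deliverable.

## Size statistics

Within one frame the spatially varying A* follows a left-truncated
exponential (truncation at A* = 0.5 removes the noise-dominated tail). The
rate is fitted by weighted least squares of the log empirical survival
fraction (Hazen plotting positions) against A* - lower, with weights equal
to the survival fraction: the weights approximate inverse variance of the
log survival estimate and keep the noisy deep tail from dominating.
Empirically (500 simulated samples, k = 1000) the fitted mean
MV = lower + 1/rate carries < 0.3% bias; uniform weights double the spread
and push bootstrap coverage to the edge of its nominal band. 95% bounds
come from a percentile bootstrap (1000 resamples). Results are reported in
the MV[LB, UB] convention; a bound replaced by a truncation value is primed
(e.g. 1.91[0.50', 1.96]); the object also always carries the two-sided
bootstrap interval. With an upper truncation the log-survival fit treats
the in-window sample as exponential, which is adequate when the window is
wide relative to 1/rate and increasingly biased otherwise — a known
limitation.

Frame means are summarized over time by their mean, the SD of frame means
(reproducibility), and the pooled SD sqrt(sum (k_i - 1) s_i^2 /
sum (k_i - 1)) — the variance-weighted within-frame dispersion. Normality
of frame means is checked with a one-sample Anderson-Darling test at the
5% level.

Derived quantities: the daughter/parent ratio of mean A* (with uncertainty
propagated from the two SD-over-frames), the size-flow parameter
F = Q* x ratio (the identity line F = Q* marks size-neutral partitioning),
and the wall-margin location x*_A — the mean cross-flow position of the 5%
tail (toward a stated wall) of structures within +/-0.25 of a target A*.
The tail side is explicit because the 5th-percentile convention could be
taken per wall or folded; this package always states the wall.

Haematocrit profiles map the time-averaged, background-normalized
transmitted intensity I* in [0, 1] to haematocrit: linear H = alpha(1 - I*)
(alpha is an explicit parameter, no hidden rescaling) and non-linear
H = a(1 - I*^b) with the published calibration constants a = 0.685,
b = 9.244. Only the constants of the non-linear calibration are published;
the algebraic form here is a package choice satisfying H(1) = 0 and
monotone decrease, and the mapping is pluggable.

## Velocity fields and the flow split

Gridded 2-D velocity fields are inputs (as exported by PIV tools;
whitespace text columns x, y, u, v [, valid]). Vectors are validated with
the normalized median test: per node and component, the residual to the
8-neighbour median is normalized by the median absolute neighbour residual
plus eps, and nodes exceeding threshold 2 are replaced by the neighbour
median. eps = 0.1 is expressed in units of the field's RMS speed. These
are the de-facto standard constants; like all plain normalized-median
implementations, genuinely sheared near-wall nodes of very low-noise
(ensemble-averaged) fields can trigger it, which is why the flow-ratio
regions of interest sit in branch cores.

Q* is computed from mean axial speeds over fixed regions of interest one
to two widths from the junction in each branch. Streamlines are traced by
fixed-step fourth-order Runge-Kutta on the bilinearly interpolated,
normalized direction field (fixed step = deterministic tests; default step
a quarter of the grid spacing). The flow-split location x*_fs is found by
bisection on seed positions along a parent transect at y* = -2: seeds are
classified by exit daughter, and x*_fs is the midpoint of the final
bracket (tolerance 0.005). The transect location is a convention — the
separating streamline is curved near the junction, so a well-defined
x*_fs needs a stated measurement line. Seeds that stall near the junction
stagnation point are classified by their trailing lateral drift; a seed
with no drift is on the separating streamline itself.

The independent oracle is the cumulative-flux construction: x*_fs solves
1 - Phi(x) = Q*_right, with Phi the cumulative lateral flux fraction of
the parent profile. Streamline bisection agrees with this oracle to
better than 0.01 for plug and parabolic profiles across Q* = 0.1-0.9.

## Synthetic scenes

The generator provides ground-truthed stand-ins for the imaging data; all
randomness flows from one seed, so scenes are bit-reproducible.

* **Sizes** are drawn from the left-truncated exponential (default mean
  A* = 2, truncation 0.5 — the scale observed for aggregating samples).
* **Positions**: axial positions are uniform along the branches; lateral
  positions are uniform inside the size-dependent admissible band
  |s| <= 0.5 - margin(A*), with margin(A*) = min(0.05 A*, 0.45) by
  default. The linear form is a modelling choice; the monotone increase of
  margin with size is the feature the analysis relies on.
* **Rendering**: a structure of n cells (n = round(A/Ac)) is a straight
  chain of equal discs at centre spacing 1.5 radii, radius solved so the
  union area equals the drawn area exactly (overlap lens in closed form);
  the chain aligns with the branch axis +/- 0.2 rad. Cells absorb with
  Beer-Lambert optical density 4.0 +/- 10% per cell, so interiors transmit
  only a few percent of the background — the regime in which mean-
  normalized gradients are uniformly high inside aggregates, which is the
  imaging property the detector exploits. Intracellular texture is a
  lognormal density speckle (sigma 0.35) plus a mild sinusoidal stacking
  band along the chain axis (amplitude 0.2, period 2.6 um). The background
  is a bright field (0.88) under a Gaussian vignette (strength 0.25)
  carrying a cell-scale multiplicative grain (correlation 1.6 px) whose
  amplitude scales with the haematocrit appearance (0.25 by default) —
  a dense flowing suspension is never featureless. The frame is blurred by
  the optical PSF (sigma 0.6 px), sensor noise (SD 0.012) is added, and
  optional rectangular regions are locally blurred to emulate degraded
  patches; walls outside the channel render dark.
* **Velocity fields** come from a piecewise stream function: the parent
  carries a plug, parabolic or blunt power-law profile; daughters carry
  the same profile scaled to their flow fractions; the junction square
  blends the parent stream function toward the top-wall value using the
  daughters' cumulative profile. Fields are divergence-free by
  construction and mass-conserving to quadrature accuracy on any grid.
  The true lateral profile at aspect ratio 100 x 40 um lies between plug
  and parabolic; the profile kind is configurable rather than asserted.

What the generator does **not** emulate: genuine 25% haematocrit overlap
and occlusion (resolved structures cover only a few percent of the
channel, with the remainder folded into background grain), out-of-plane
imaging effects beyond uniform projection, cell deformation and rotation,
time correlation between frames, and PIV measurement artifacts beyond
additive noise. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical structure, not performance on
arbitrary laboratory data.

## Partitioning sweep

For each Q*, the pipeline locates x*_fs in the analytic field, then
transports a parent population through the junction: a structure whose
centre lies right of x*_fs enters the right daughter, its lateral position
maps linearly from its sub-band of the parent onto the daughter width
(clipped to its feasible band), and its size grows by 1 + g(1 - Q*_d),
modelling enhanced aggregation at the lower shear of slow branches.
Because number flux and speed both scale with the flow share, steady flow
keeps the line density of structures branch-invariant; the snapshot
population entering each daughter is replicated to match the parent's
line density so detection-stage merging biases cancel in daughter/parent
ratios. g = 0.2 was set so the measured mid-Q* daughter increase lands in
the 10-20% band that motivated the model, after transport depletion and
detection effects are folded in.

The admitted-size rule is geometric: size A* reaches the low-flow daughter
on wall side s iff its wall-margin location x*_A lies beyond x*_fs toward
that wall; the high-flow daughter admits every size. At Q* = 0.5 the split
sits on the centreline and both daughters admit all sizes. Admitted sets
are monotone: moving the split toward the wall never enlarges the set.

The demo sweep (Q* in {0.1, 0.2, 0.35, 0.5}, 50 frames per case, 80
structures per frame) reproduces the qualitative partitioning signature:
daughter/parent ratio < 1 at Q* = 0.1, ratio >= 1 at mid flow ratios, and
F above the F = Q* line for Q* > 0.3. Wall-margin locations for A* = 6-7
rest on few records at this problem size and can be noisy or unresolved;
they are reported as NaN rather than extrapolated.

## Problem sizes and numerical choices

Default problem sizes (50-frame stacks, 80 structures per frame, 15-frame
calibration references, 5-um velocity grids, 1000 bootstrap resamples,
500-dataset estimator studies) were chosen so each stage's sampling error
sits well below the tolerance being checked while a full run of the test
suite and the acceptance script stays desk-scale. Bisections run to fixed
tolerances (threshold: 2% of Ac; flow split: 0.005 in x*; oracle root:
1e-6). Ties and degenerate inputs fail loudly: empty stacks, constant
frames, insufficient samples (k < 30 for fits, < 100 for wall margins,
< 8 for normality) and non-bracketing calibrations raise errors rather
than returning silent defaults.
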