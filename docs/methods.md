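# Methods

## The warping-crystal model

`birtrack` treats a stationary nanocrystal under the beam as a rigid lattice
whose *consensus orientation* changes with accumulated fluence D (e⁻ Å⁻²).
The orientation matrix convention throughout is: **columns are the
real-space cell vectors a, b, c in Å**, expressed in a right-handed lab
frame with the beam along +z. The reciprocal basis B = M⁻ᵀ is derived on
demand. This convention makes the per-cell-vector angular drift (how far a,
b and c have each moved from their initial directions) a direct column-wise
computation.

The synthetic trajectory composes three motions per frame i (frame-start
fluence Dᵢ = i·ΔD):

* **drift** — rotation by `drift_rate`·Dᵢ about a fixed lab-frame
  `drift_axis` (degrees per e⁻ Å⁻²);
* **jitter** — an independent small rotation per frame, angle
  |N(0, jitter_sd²)| about a uniformly random axis (a crude stand-in for
  frame-to-frame indexing scatter and unresolved mosaic motion);
* **quake** — a single abrupt rotation by `quake_angle` about `quake_axis`
  applied to every frame whose start fluence has reached `quake_fluence`.

Frame 0 is always the unrotated reference. The generator records the actual
net rotation of the last frame (`series.truth`), so recovery tests compare
against what was truly imposed, jitter included.

Consensus rotation is the primitive of the model: no attempt is made to
derive it from a local bend-angle field, because the mapping from local
lattice bending to the indexing consensus is not well constrained — the
simulator imposes the consensus motion directly and leaves multi-domain
mosaic substructure out of scope.

## Intensity decay law

Reflection intensities decay with dose as

  I(d, D) = I₀ · exp(−α·D / d²),

with d the d-spacing in Å and α ≥ 0 in Å² per e⁻ Å⁻². This two-parameter
form is the simplest monotone law in which fine spatial frequencies fade
first, the hallmark of radiolytic damage; it is a modelling choice, not a
measured physical law. It is self-checking: a log-linear fit of a
background-subtracted trace against D has slope −α/d², so α is recoverable
per reflection (`fit_decay_rates`). Because individual traces carry Poisson
counting noise of a few percent RMS, the combined estimate is the median
over all fitted traces; on the default rendered series (≈50 usable spots,
100 frames) it recovers α to ~1–2%.

Per-reflection base intensities I₀ are either supplied as a mapping
(h,k,l) → I₀ or drawn deterministically per reflection from a log-normal
(σ = 0.4) around a scalar mean, seeded by (model seed, h, k, l) so every
generator call is bit-reproducible.

## Rendering still patterns

A reflection is excited when its angular excitation error — the signed
distance of q = Bh from the Ewald sphere |q + k₀| = 1/λ, scaled by d into
an angle — is inside the mosaic rocking half-width (default 0.3°). The
rocking profile is triangular, max(0, 1 − |δ|/halfwidth): simple,
compactly supported, and linear near the flanks, which makes analytic
expectations easy in tests. Spots are drawn as 2-D Gaussians (σ = 1.2 px)
normalized to the integrated intensity, over a flat background with Poisson
noise; the beamstop disc is zeroed. The default wavelength is the
relativistic value for 200 kV (0.02508 Å), computed, stored on the
geometry, and never hard-coded elsewhere.

## Spot tracing

The detection image is built by smoothing each frame with a one-pixel
Gaussian and then taking the pixelwise maximum over frames (filter first,
then project — the order is a config choice and the filtered-first reading
is the default). Pixels above `threshold_factor` × background (1.25 by
default) are grouped into connected components; intensity-weighted
centroids are rounded to pixels (exact halves toward the lower index);
components closer than the mask radius are merged by single linkage.
Background "auto" is the median of the detection image outside the
beamstop — the median is robust because Bragg spots occupy a tiny fraction
of pixels. Note the multiplicative threshold presumes a background whose
relative Poisson noise is well below (threshold_factor − 1); the synthetic
fixtures therefore use backgrounds of ~100 counts, as on a real detector.

Integration sums counts in a diamond |Δr| + |Δc| ≤ R (2R² + 2R + 1 pixels;
1301 at the default R = 25). Overlapping diamonds assign each shared pixel
to the nearer center (ties to the lower spot id); masks clipped by the
detector edge are summed over the clipped region and flagged.

The summed trace takes the brightest ⌈20%⌉ of traces — brightness judged by
each trace's maximum wherever it occurs — sums them framewise and divides
by the maximum of the sum. Its finite-difference derivative with respect to
fluence is binned (default 0.1 e⁻ Å⁻², an order-of-magnitude choice giving
a handful of bins per typical 1–2 e⁻ Å⁻² series); by construction the
cumulative sum of derivative × Δfluence reconstructs the trace exactly, a
property tested to 1e-10. The per-bin SD of derivative values, averaged
across crystals, is the fluctuation metric: flat decay gives near-zero SD
in every bin, reorientation concentrates SD in the bins where it happens.

## Trace clustering

Traces are normalized to their own maxima and clustered by k-means on the
full normalized vectors (k = 5 default, 10 restarts, fixed seed; backed by
scikit-learn, whose empty-cluster relocation to farthest points is the
standard fix). The fluence of each trace's maximum is used only to
canonicalize labels — cluster 0 peaks earliest — so runs and seeds are
comparable. Clustering on the full trace rather than on the argmax alone
lets trace *shape* separate groups with similar peak times.

## Orientation-track cleaning

`point_group_rotations` returns the proper rotations of the lattice point
group in the crystal basis (integer matrices on h,k,l), obtained from
space-group tables via a point-group → representative-space-group map and
deduplication of rotation parts. Post-multiplying an orientation matrix by
such an op preserves the metric tensor SᵀGS = G exactly — these are
precisely the alternative indexing settings.

Disambiguation takes frame 0 as ground truth and, for each subsequent
frame, picks the setting M·S nearest the previous corrected frame in
Frobenius norm (ties to the lowest op index). The component-wise Frobenius
metric matches the component-wise language of the rejection rule; a
rotation-angle metric is available as an alternative. Mis-indexed frames
are those whose components differ from *both* neighbors by more than
`sigma_k` = 2 standard deviations of that component over the whole series
(one pass, outlier candidates included; endpoint frames use their single
neighbor twice). A component whose σ is numerically zero (e.g. fixed by a
special drift axis) is floored at 1e-9 of the data scale so floating-point
dust cannot flag frames.

A single random mis-indexed frame can derail the frame-to-frame walk onto a
different symmetry branch for the remainder of the series. `clean_series`
therefore runs disambiguate → reject → disambiguate, where the second pass
anchors only on surviving frames, chaining across the rejected gaps. On a
fully valid series the second pass is a no-op.

Net rotation uses the proper orthogonal Procrustes fit (Kabsch) of frame i
onto frame 0 rather than MᵢM₀⁻¹ directly: identical for exact rigid motion,
but the SVD projection absorbs the small non-orthogonal component noise of
real indexed matrices. Axis–angle extraction returns angles in [0°, 180°]
with the axis sign canonicalized (first nonzero component positive).
`detect_quake` reports the fluence after which the largest frame-to-frame
step occurred, if that step exceeds a threshold (default 1°/frame).

`refine_orientation` is deliberate plumbing, not an auto-indexer: it
predicts near-sphere reflections under a candidate orientation, assigns
observed spots to predictions within a capture radius (6 px default), and
fits the rotation by Kabsch **on unit scattered-ray directions**. Fitting
back-projected scattering vectors instead would silently drag every
reflection onto the Ewald sphere — a systematic bias on the order of the
rocking width — because a detector position constrains only the ray
direction, not the excitation error. Refinement is refused (candidate
returned, flagged) with fewer than 3 assignments, which is what happens
when the candidate is tens of degrees off and the excited sets are
disjoint.

## Seismograms

Batches are aligned by integer-pixel shifts from normalized circular
cross-correlation between the last frame of one batch and the first of the
next, accumulated along the series; a correlation coefficient below 0.2
(e.g. featureless noise) falls back to zero shift with a warning. Stacks
are mean-binned by 5 in all three dimensions (trailing remainders dropped,
fluence axis rebinned to bin means). The temporal low-pass is zero-phase
either way it is invoked: a 4th-order Butterworth applied
forward–backward when a cutoff (cycles/frame) is given, else a centered
5-frame moving average — both pass constants unchanged and are linear.
Seismograms sample the filtered stack along a line by bilinear
interpolation, one sample per pixel of line length. The fluctuation trace
is the SD **over line positions** of |value − temporal mean at that
position| per frame: per-position (not global-scalar) temporal mean is the
default because it makes a static scene identically zero and the metric
invariant to global offsets. The line should span the crystal interior;
crossing into background contrast contaminates the metric, exactly as it
would for a hand-drawn line on real images.

## Synthetic imaging stacks

The bend-contour generator renders an elliptical "crystal" (bright, 100
counts) on background (20 counts) crossed by Gaussian-profile dark bands
(contrast 0.6, width 4 px) whose positions migrate at `speed` pixels per
e⁻ Å⁻² until `settle_fluence` (default 0.5 e⁻ Å⁻², matching the regime in
which contour motion is concentrated), then freeze; Gaussian read noise on
every frame. It emulates migrating diffraction-contrast bands only — no
dynamical contrast, thickness fringes, support-film texture or dose-dependent
mass loss — so passing tests demonstrate that the measurement chain recovers
imposed kinematics, not that it would segment real micrographs.

## What the generator does and does not establish

The simulator shares the analysis code's geometry conventions but none of
its estimators: recovery tests close the loop generator → renderer/ scrambler
→ analysis → imposed parameter. Passing them shows the pipeline is
self-consistent and unbiased under the stated noise models (Poisson counts,
Gaussian component noise, uniform symmetry scrambling, random mis-indexing).
Real data add effects outside the model — dynamical diffraction, correlated
indexing errors, mosaicity growth, detector nonuniformity — so quantitative
performance there depends on upstream indexing quality, as it does for any
such pipeline.

## Problem sizes and numerical choices

Verification runs use: 1000 random rotations for the axis–angle oracle
check; 5 point groups (1, 2, 222, 4, 422, with compatible cells) × 50
seeded replicates × 100 frames for disambiguation; 100 replicates × 100
frames with 10% six-sigma outliers for rejection; a 150-frame,
1.5 e⁻ Å⁻² drift series and a 60-frame quake series for end-to-end
recovery; rendered series of 100 frames on a 512×512 detector (~60 spots)
for trace fidelity and 256×256 for the fluctuation contrast; 20 seeds × 50
traces for clustering; 100-frame 128×128 stacks for seismogram checks.
Tie-breaks are deterministic everywhere (lowest op index, lower pixel
index, stable sorts); all RNG flows through seeded `numpy` generators, and
every generator is bit-reproducible for a fixed seed.

## Known limitations

* No auto-indexing: orientation tables come from external serial indexing;
  `refine_orientation` only polishes a near-correct candidate.
* The 2σ rejection rule assumes the population σ of each component is
  dominated by real orientation variation; on a series whose components are
  pure iid noise its false-flag rate rises, inherent to the rule itself.
* Symmetry handling covers proper rotations only; improper operations
  cannot relate indexing settings of a chiral lattice and are excluded.
* SMV output is unsigned 16-bit; counts above 65535 must be written as MRC
  (mode 2 float or mode 6 uint16).
* TVIPS-format input is not parsed; convert to MRC upstream.
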