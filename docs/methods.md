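# Methods

This note records the models and procedures behind each stage, the defaults
that matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was open.

## Synthetic data and ground truth

The generator produces the four kinds of raw data the pipeline consumes, with
a `GroundTruth` record sufficient to repaint every planted object, and full
determinism given the spec and seed. All coordinates are (row, col), 0-based,
origin top-left.

**Nuclear-stain frames.** Nuclei are painted as near-circular ellipses (axis
ratio 0.95–1.0, random orientation) with a soft radial intensity profile — a
flat bright core fading to a rim at 15% of peak. The profile matters: the
second Otsu step splits the foreground's intensity distribution, and a flat
profile plus noise would shatter each nucleus into speckle, whereas cores
survive as single components. Fragments are concave lunes (a disk minus an
offset larger disk), reduced to their largest 8-connected piece.
Discrete-geometry caveat: solidity as measured on pixel sets (object pixels
over convex-hull pixels, as in `skimage.regionprops`) is below 1 even for a
perfect digital disk — it dips to ~0.92 at radii 5–12 px. The generator
therefore guarantees, for radius ≥ 6 px, intact solidity ≥ 0.92 and fragment
solidity < 0.80; the default 0.9 cut separates the classes with margin
(observed scene-level gaps ≥ 0.33). A continuous-geometry "≥ 0.95 intact"
guarantee is not attainable for discrete shapes at these scales.

**Calcium movies.** A constant somatic baseline plus planted transients:
boxcar by default (constant amplitude over the event) so each event's
footprint appears in exactly one positive difference frame — its onset —
making the planted AAI well-defined; an exponential-decay profile is
available. Footprints are compact pixel sets grown from the cell centroid,
always inside the cell. Noise follows the standard fluorescence-camera model,
Poisson shot noise on the signal (gain-scaled) plus additive Gaussian read
noise, each independently switchable to zero. The default 277 frames at 1 Hz
mirror a typical confocal recording; pre/post treatment comparisons use two
separate 150-frame recordings, never concatenated, because acquisition pauses
between them.

**Displacement fields.** Material points scattered in a disc follow either a
homogeneous equibiaxial stretch about the field center or a rigid
translation, with a half-sine stretch profile peaking at `rise_time`
(default 15 ms) over a total of ~30 ms with no dwell — the displacement
history of a cylindrical post indenting an elastic membrane. Time sampling
includes the analytic peak only when `dt` divides `rise_time`; fixtures use
`dt = rise_time / 15`. (A 1500-fps camera would sample 22.5 frames per 15 ms
rise and miss the exact peak by ~0.05% strain.)

**Puncta images.** Isotropic Gaussian spots over a scalar or spatially
varying background. No PSF model beyond the Gaussian, no photobleaching, no
hardware simulation.

What passing tests therefore show: the pipeline recovers *planted* objects
under *this* noise model. Real images add declumping problems (touching
nuclei are excluded by solidity, not split), non-uniform illumination,
focus drift, and movement — none of which the generator emulates.

## Nuclear segmentation

"Two-step Otsu" is interpreted as Otsu applied twice — globally, then within
the step-1 foreground — which removes dim material (fragments, debris) from
the final mask. A single-Otsu mode and a three-class multi-Otsu mode (keep
the brightest class) are one switch away; on trimodal scenes the two-step
and three-class variants agree. If the foreground is single-valued, step 2
is skipped. Otsu thresholds are computed exactly on one-bin-per-distinct-value
histograms (ties to the lowest maximizing split), and the returned value is
the midpoint of the split gap. Components are 8-connected; border objects
are retained (no border-exclusion rule is assumed; a flag could trivially be
added). Solidity filtering defaults: `min_solidity = 0.9`,
`min_area = 40 px²`, `max_area` unbounded — the solidity cut is not a
published value, so it is configurable and its default is chosen to bisect
the constructed intact/fragment gap. Somatic expansion grows each label by
Euclidean distance with nearest-seed assignment and exact ties to the lower
label id (deterministic; implemented by ascending-label distance transforms
rather than `expand_labels`, whose tie-break is unspecified).

## Calcium activity

Difference images take the positive part of frame-to-frame differences:
decreases are not scored, since the target is regions of *increased*
fluorescence. Per-difference-frame Li thresholds are the default ("global" =
image-wide); a stack-wide scope is available.

`li_threshold` minimizes the Li/Lee cross-entropy exactly over all candidate
split points via prefix sums, rather than using the iterative fixed-point
scheme, because the iterative scheme only guarantees a local optimum. The
returned threshold is the midpoint between the boundary values
(`foreground = frame > threshold`).

**Quiescence floor.** A global threshold method assumes the frame contains
two meaningful populations. A difference frame containing only camera noise
does not, and its exact cross-entropy minimum sits at the zero/nonzero
boundary — thresholding it would score roughly half the frame as "activity".
A frame is therefore scored zero unless at least `min_size` pixels exceed a
`degeneracy_floor`. The floor defaults to auto-calibration at 6x the robust
noise scale of the raw frame differences (`1.4826 * median |Δ|`), which is
the noise SD of the difference image for Gaussian read noise; it falls back
to 1e-6 (guarding exactly-flat frames) for noiseless data. Auto-calibration
assumes activity is temporally sparse; for pervasively active recordings
pass an explicit floor. The same consideration bounds what recovery is
possible: at SNR 10 the cross-entropy threshold isolates an event only when
the event's intensity mass is an appreciable fraction of the frame's, which
for 256×256 frames means domain-scale events (≥ ~3500 px²). Recovery
experiments use 4000-px² footprints at SNR 10 and measure errors of ~0.3%
(typical) to 12% (worst case over 20 seeds, caused by residual
onset/offset interactions).

Size filter default: `min_size = 4 px²` for clean data, 20 px² in the noisy
defaults — the published pipelines state only that "small artifacts" are
excluded.

Peak counting wraps `scipy.signal.find_peaks` (strict local maxima,
endpoints excluded, plateaus once). Data-driven defaults, since none are
published: prominence ≥ 3σ and height ≥ median + 3σ, with
σ = 1.4826·median|Δtrace|/√2 (robust to the transients themselves), and a
2-frame minimum separation. A `relative_min` height mode makes counts
invariant to constant offsets. Δ peak count applies the *pre*-trace
parameters to both recordings so the comparison is like-for-like.

## Membrane strain

Per point and time step, the stretch ratio is the least-squares slope
through the origin of current vs. reference pairwise distances,
λ_i(t) = Σ_j d_ij(t) d_ij(0) / Σ_j d_ij(0)². Distances are invariant to
rigid motion, so any translation+rotation yields exactly zero strain.
Conventions: Green–Lagrange E = (λ²−1)/2 (default) or nominal λ−1 — the two
agree to first order and the peak-rate arithmetic is convention-independent.
Collinear or coincident reference layouts are rejected (rank test on the
centered reference coordinates). Rise time is measured on the mean history,
from the last zero-strain sample before the peak to the peak. An affine
deformation-gradient fit (2×2 F per time step, principal stretches = its
singular values) is provided for anisotropy QC of nominally equibiaxial
fields. The severity calibration used in demos maps stretches 1.0204,
1.1824, 1.4616, 1.6194 to Green strains of ~2.1%, 19.9%, 56.8%, 81.1%.

## Morphology and puncta

The cell-area index divides the Li-thresholded phalloidin mask area by the
intact-nucleus count; zero nuclei raise an error rather than returning zero.
Puncta detection: white top-hat at the spot scale (removes any background
smoother than the spots), Li threshold on the residual with the same
6x-robust-noise floor as above, then an area gate (`size_range`, default
1–200 px²) and a mean-contrast gate inside the reference mask. "Area
density" is implemented as puncta count per unit reference area, with total
puncta area also reported; the reference defaults to the cytoplasm mask (not
the full field) so post-injury cell loss does not dilute the density.
Colocalization and puncta classification are out of scope.

## Statistics

Lilliefors: KS distance against a normal with estimated mean/SD; p from a
seeded Monte-Carlo null (default 10,000 replicates, each standardized the
same way), p = (1 + #{D* ≥ D}) / (n_mc + 1) — reproducible and exact in the
large-replicate limit, unlike table interpolation. Measured calibration:
type-I rate ≈ α; power against uniform(0,1) at n = 200 ≈ 94%.
Kruskal–Wallis uses midrank tie correction and the χ² approximation (k−1
df); its measured null rejection rate at α = 0.05 (3 groups of 12, 2000
simulations) is ~0.045–0.05. Post hocs default to two-sided Mann–Whitney
tests with Bonferroni multiplier k(k−1)/2 capped at 1; Dunn's pooled-rank
z-tests are a switch away. The compact letter display uses insert-and-absorb:
letters are group sets, each significant pair splits every letter containing
both, subsets are absorbed, uncovered groups get fresh letters; the result is
verified internally to satisfy share-a-letter ⇔ not-significant (minimal
letter count is not guaranteed). The unit of analysis (well vs. cell) must be
stated explicitly by the caller; nothing is inferred.

## Pipeline

A YAML config fully serializes a run (unknown keys are rejected by name);
every stage writes TIFF/CSV/JSON plus a manifest with the config hash,
package version, and per-stage record counts, and re-running a config+seed
reproduces outputs bit-for-bit. Demo problem sizes (128×128 wells, 40-frame
movies, 4 wells per condition) are chosen so a full run completes in
seconds; all sizes are config keys.

## Known limitations

- No declumping of touching nuclei; overlaps are excluded, not resolved.
- AAI auto-calibration misjudges the noise floor if most pixels change on
  most frames.
- Small (< ~3500 px²) transients at SNR ≤ 10 are not reliably isolated by
  global cross-entropy thresholding; per-cell trace analysis is the better
  read-out in that regime.
- The strain module assumes in-plane homogeneous deformation; out-of-plane
  motion biases the pairwise-distance fit.
- Lilliefors Monte-Carlo p-values are exact only in the large-`n_mc` limit;
  the default 10,000 gives ~0.5% standard error near p = 0.05.
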