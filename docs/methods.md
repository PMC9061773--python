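# Methods

## Model of the image

A single-channel fluorescence micrograph of a stained actin cytoskeleton is
modelled as the pixel-wise sum of three components:

1. **filaments** — bright, quasi-straight, elongated structures (the stress
   fibers of interest),
2. **artefacts** — smooth blob-like structure (out-of-focus light, nuclear
   background, stain aggregates),
3. **noise** — everything neither of the above represents sparsely.

Images are min–max normalized to [0, 1] per image on load. Only geometry is
compared downstream, never absolute intensity, so per-image normalization is
safe; no background subtraction is assumed. Coordinates are 0-based with
x = column, y = row and origin top-left; orientations are measured
counter-clockwise from the +x axis (i.e. toward −y as displayed) and folded
into the nematic interval [0, 180), since fibers are axes, not arrows.

## Decomposition (MCA)

The split is computed by morphological component analysis: alternating
projections in which each component in turn is re-estimated from its
marginal residual by transforming into its dictionary, hard-thresholding at
the current λ, and reconstructing. λ decreases linearly (exponential
schedule available) from `lambda_start` to `lambda_stop` over
`n_iterations` (default 100).

* **Directional dictionary** — a bank of elongated second-derivative-of-
  Gaussian ridge kernels, `n_scales` = 2 scales (σ_across = 1, 2 px,
  elongation 4) × `n_orientations` = 8 orientations, zero-mean and
  L2-normalized so coefficient magnitudes are comparable with wavelet
  coefficients. Analysis is FFT correlation; synthesis uses the
  normalized-adjoint approximate inverse (division by the bank's aggregate
  spectral weight, floored at 0.1% of its maximum). Any tight-frame-like
  oriented multiscale transform would serve; this one is simple, isotropic
  over orientation, and exactly transpose-equivariant when the orientation
  count is a multiple of 4.
* **Isotropic dictionary** — an undecimated (stationary) `sym4` wavelet
  transform, 4 levels, normalized. Only detail bands are thresholded; the
  approximation band always survives, so smooth low-frequency content is
  claimed by the artefact component by construction.

Defaults for the schedule are data-driven: `lambda_start` = 0.9 × the
largest initial coefficient magnitude over both dictionaries, and
`lambda_stop` = 3 × a robust noise scale (MAD of the finest wavelet details
/ 0.6745). If the estimated stop is not below the start (extremely noisy
input), it is clamped to half the start.

Numerical choices: the image is reflect-padded past the largest kernel
support (and to a multiple of 2^levels for the wavelet transform) so
periodic FFT artefacts never touch real content; iterations run in single
precision for speed. Exactness of the decomposition does not depend on
either: components are clipped at zero at the end (fluorescence is
non-negative) and the noise component is *defined* as the double-precision
remainder `input − filaments − artefacts`, so the three components always
sum to the input exactly.

## Enhancement, line scoring, binarization

The filament component is enhanced by: isotropic Gaussian smoothing
(σ = 1 px), a sign-flipped Laplacian (4-neighbor stencil; ridges become
positive), then a per-pixel maximum over 16 rotated anisotropic Gaussians
(σ_along = 6 px, σ_across = 1.5 px) which re-connects ridges along their
direction; the result is clipped at 0 and rescaled to [0, 1].

Line membership is scored by difference-of-boxes bar kernels: a positive
bar of length 3w and thickness w minus two flanking bars of the same size
at lateral offset ±w, each contrast-normalized, evaluated over widths
{1, 3, 5} px × 16 orientations. The maximum response (negatives clipped,
divided by the per-image maximum) is a normalized [0, 1] ranking score —
not a calibrated probability — and the arg-max records the best-fitting
width and angle per pixel. On an ideal line the response of the matching
width equals the line's amplitude and beats the mismatched widths on the
line's support.

Binarization input is the product of the enhanced image and the line score
(both cues must agree); scores below 1% of the image maximum are zeroed
first, because a pure ratio threshold would otherwise fire on numerically
tiny ripples over empty background. Wellner-style adaptive thresholding
then marks a pixel foreground iff it exceeds its local box mean (window
defaulting to image width / 8, rounded odd) by `offset_percent` = 15%. The
2D box mean is the standard generalization of Wellner's 1D running mean;
the rule is ratio-based and therefore invariant to global intensity gain.
A relative epsilon (10⁻⁹ of the image maximum) keeps the strict inequality
honest against box-filter rounding on flat background.

## Segment extraction

The mask is skeletonized to a 1-px medial axis. Branch pixels (more than
two 8-neighbors) are removed, each remaining arc is walked into an ordered
path, and every path is split recursively where it deviates from its chord
by more than 1.5 px (Douglas–Peucker criterion). Each quasi-straight piece
is fitted by total least squares (principal axis of the pixel scatter) and
kept only if the fitted chord is at least `min_length_px` = 30 px long —
the minimum length L used by the experiments this pipeline models; it is
compared against the straight chord, not the traced path, because output
segments are straight by construction. Each skeleton pixel contributes to
at most one segment.

Stitching merges pairs of segments whose nematic angle difference is ≤ 5°,
whose endpoint gap along the shared direction is ≤ 3 px (overlap counts as
gap 0) and whose midline lateral offset is ≤ 2 px, replacing the pair with
the total-least-squares line through all four endpoints. Candidates are
processed in ascending gap order (deterministic tie-break) and the merge
rounds iterate to a fixed point, making the operation idempotent. The
defaults are deliberately small relative to L = 30 so stitching cannot
bridge distinct fibers.

## Orientational order parameter

Each segment angle θᵢ gives a unit vector pᵢ = (cos θᵢ, sin θᵢ) and order
tensor pᵢpᵢᵀ. The mean order tensor T = ⟨2 pᵢpᵢᵀ − I⟩ (optionally weighted)
is symmetric and traceless, with eigenvalues ±λ. The OOP is the maximum
eigenvalue; algebraically λ = √(⟨cos 2θ⟩² + ⟨sin 2θ⟩²), and this closed
form is kept in the API as an independent cross-check of the eigenvalue
route. The director is the eigenvector of +λ. When the OOP is below
numerical noise (≤ 10⁻¹²) the population is isotropic and the director is
reported as undefined (NaN) rather than an arbitrary angle.

The OOP is *unweighted* by default: the extraction chops long fibers into
smaller segments, and weighting by segment length would double-count
geometry that the chopping already distorts; the optional length-weighted
mode exists precisely to test sensitivity to that choice. Angles outside
[0, 180) are folded on input, never rejected.

## Synthetic benchmark

The generator emulates stained-cytoskeleton images: `n_fibers` anti-aliased
straight fibers of width `width_px` and uniform random length within
`length_range_px`, centers uniform over the image (resampled, with bounded
retries, until both endpoints are inside), orientations drawn as θ = ψ/2
with ψ ~ von Mises(2·mean_angle, κ) — the standard axial-data construction;
κ = 0 is the isotropic "nest-like" phenotype, large κ the aligned
phenotype — plus `n_blobs` Gaussian blobs and i.i.d. additive Gaussian
noise, clipped to [0, 1]. Fibers, blobs and noise consume independent child
RNG streams of the seed, so adding blobs never moves fibers.

Default benchmark conditions: 512×512 px, 60 fibers, width 3 px, lengths
60–140 px, fiber amplitude 0.6, 2 blobs (σ = 12 px), noise σ = 0.05,
κ ∈ {0, 2, 8, 32}. The blob count and amplitude are this package's choice
of a realistic nuisance level. What the generator does *not* emulate:
Poisson photon statistics, curved fibers, cell-shaped masks, uneven
illumination, fiber crossing-density correlations. Passing the benchmark
therefore shows the pipeline recovers geometry under idealized straight-
fiber conditions; it does not certify performance on curved or densely
bundled cytoskeletons.

Scaled-down conditions (96×96 px, 25 fibers, lengths 25–50 px, L = 12,
40 MCA iterations, 3 wavelet levels, widths {1, 3}) are used where many
hundreds of extractions are needed — the population-separation check and
parts of the test-suite — chosen so each extraction stays well under a
second while the OOP contrast between conditions is unchanged.

## Population statistics

Two-sample comparisons use the pooled-variance (Student) t statistic with
n₁+n₂−2 degrees of freedom, two-sided p from the t distribution, rejection
at α = 0.05 — the convention of the experiments this package models. No
multiple-testing correction is applied across timepoints by default (a
Bonferroni option exists). SEM is the sample standard deviation (n−1) over
√n. Quantiles everywhere use linear interpolation between order statistics
(type-7), and boxplot whiskers extend to the most extreme values within
1.5×IQR of the box. Duplicating a sample changes its SEM by the exact
sample-sd factor √((n−1)/(2n−1)), not the population-sd approximation
1/√2; the tests assert the exact arithmetic.

## Known limitations

* Curved fibers are approximated by chains of straight segments; their
  angular contribution is correct only piecewise.
* One OOP is computed per image; multi-cell fields must be cropped to
  single cells upstream.
* The directional dictionary is a fixed kernel bank, not a learned or
  exactly tight curvelet frame; component assignment near fiber crossings
  is heuristic.
* The Wellner window default (width/8) assumes the cell roughly fills the
  field of view.
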