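# stressfiber

Quantify actin stress-fiber organisation from fluorescence micrographs.

Cells remodel their cytoskeleton during processes such as the
epithelial–mesenchymal transition: cortical actin reorganises into stress
fibers that first form in arbitrary directions and later align. This package
extracts those fibers from single-cell phalloidin / SiR-actin images as
straight line segments — location, length and orientation — and condenses
their alignment into a single figure of merit, the **orientational order
parameter (OOP)**. It is aimed at quantitative cell biologists and
biophysicists who want per-cell alignment numbers, fiber counts and
population statistics from plain actin images.

## Method

The pipeline treats an image as the sum of three components — quasi-straight
**filaments**, blob-like **artefacts**, and **noise** — and separates them by
morphological component analysis (MCA): alternating hard-thresholded
projections onto two dictionaries (an oriented multiscale ridge-kernel bank
for elongated structure, an undecimated isotropic wavelet transform for
smooth structure), with a threshold decreasing over 100 iterations. The
filament component is contrast-enhanced (Gaussian → sign-flipped Laplacian →
directed-Gaussian maximum), every pixel is scored for membership in a line
of each candidate width by a multi-scale oriented bar filter, and the score
is binarized with Wellner-style adaptive thresholding. The binary mask is
skeletonized and traced into straight segments of minimum length L (default
30 px); collinear overlapping segments are stitched.

Each segment contributes a unit orientation vector **p**ᵢ = (cos θᵢ, sin θᵢ).
The mean order tensor

T = ⟨ 2 **p**ᵢ**p**ᵢᵀ − I ⟩

is symmetric and traceless; the OOP is its maximum eigenvalue, ranging from
0 (isotropic) to 1 (perfectly aligned), and the corresponding eigenvector is
the director. The OOP is unweighted by fiber length by default (a
length-weighted mode is available). On top of this the package provides the
population statistics used for time courses and drug comparisons:
equal-variance two-sample t-tests at the 5% level, Pearson correlation,
mean ± SEM summaries and 1.5×IQR boxplot statistics.

A synthetic-image generator with exact ground truth (axial von Mises fiber
orientations with concentration κ, blob artefacts, Gaussian noise) makes
every stage testable without any microscope data.

## Worked example

Generate a synthetic cell with well-aligned fibers, extract them, and
compute the OOP:

```sh
stressfiber simulate --shape 256x256 --n-fibers 20 --kappa 1000000 \
    --mean-angle 30 --length-min 60 --length-max 100 --noise 0 \
    --n-blobs 0 --seed 1 --out cell.tif --truth truth.csv
stressfiber extract cell.tif --out-segments segments.csv \
    --out-summary summary.json --overlay overlay.png
stressfiber oop segments.csv
```

The simulate step prints

```
wrote cell.tif: 20 fibers, true_oop=1.0000
```

and the extract step prints

```
n_segments=17 total_length_px=1486.5 oop=1.0000
```

meaning 17 straight segments were recovered (a few of the 20 fibers overlap
and stitch into one) with a total extracted length of 1487 px, and their
orientations are almost perfectly aligned (OOP ≈ 1; for
fibers drawn isotropically the same pipeline reports OOP near 0). The JSON
summary records the OOP, the director angle, the fiber count and the full
configuration so the run can be replayed; `overlay.png` shows the extracted
segments drawn over the input for visual inspection.

The same steps are available as library calls (`generate_fiber_image`,
`extract_filaments`, `compute_oop`), which is how the test-suite uses them.

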