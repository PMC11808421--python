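# Methods

## Coefficient definition

For a selected pixel set $S$ the coefficient is the sample Pearson
correlation of the paired intensities over $S$, with both means computed
over $S$ — never over the whole image. Selection predicates use strict
inequalities: a pixel exactly at a threshold is background. The `ALL`
criterion ignores thresholds entirely; treating it as "thresholds = 0"
would, with strict inequality on non-negative data, exclude zero-valued
pixels and contradict the intent of including every pixel.

Accumulation is in double precision throughout; values are rounded to two
decimals only at presentation. A z-stack enters as one pooled voxel
population (no per-slice averaging), so 2D and 3D data flow through the
same code path.

### Degenerate selections

Thresholded selections can land on pathological pixel sets. The
conventions, in the order they are applied:

1. empty selection → `EmptySelectionError`;
2. both channels constant over the selection with positive values →
   coefficient reported as **1.0** with `degenerate=True`. The 0/0 limit
   has no unique value, but two constant positive vectors are positively
   proportional — the limiting case of perfect colocalisation. This rule
   deliberately covers a single selected pixel (a 1-pixel overlap of two
   uniform objects), so the AND column of the object-size sweep is
   uniform all the way down to 2 × 2-pixel squares;
3. otherwise fewer than two pixels, or exactly one channel constant →
   `DegenerateSelectionError` (no defensible sign for the coefficient).

## Synthetic image generators

The generators produce the study conditions; they are first-class,
tested code.

**Overlapping squares.** One uniform square per channel (default
intensity 0.8, background exactly 0) on a 1000 × 1000 canvas, offset
diagonally by $s(1-\sqrt{f})$ pixels in each axis so a fraction $f$
(default 0.25) of each square's area is shared. Only the four pixel-count
masses matter for any PCC, so the layout choice is presentation-only; the
analytic four-mass-point correlation
(`square_pair_pcc_all_closed_form`) doubles as the test oracle. Sides
must give a whole-pixel overlap (even sides for $f=0.25$).

**Gaussian spots.** Five isotropic 2D Gaussians per channel (σ = 15 px,
amplitude 0.8, truncated at 4σ) with one spot pair at identical centres
and all other centres ≥ 6σ apart, so truncated footprints never overlap.
σ and amplitude are choices of this package: they give spots comfortably
above the Otsu split on a 1000 × 1000 canvas while keeping the five-spot
layout sparse. Because the coincident spots are identical and isolated,
the AND selection sees exactly proportional signals and its coefficient
is 1.0 *without* invoking the degenerate convention. Layout-dependent
quantities (the ALL and OR values, selected fractions) vary with
placement and are treated qualitatively. Placement is a fixed
deterministic layout by default, or a seeded rejection-sampling mode;
both are bit-reproducible.

What these mocks do **not** emulate: detector noise (Poisson or read),
the microscope point-spread function, autofluorescence, or realistic
morphologies. Tests passing on them validate the arithmetic and the
criterion-dependent behaviours, not performance on noisy biological data.

## Thresholding

**Otsu.** 256 equal-width histogram bins over the data range (bins and
range configurable via `HistogramSpec`); the split maximising
between-class variance, ties toward the lower bin. The histogram is built
here and handed to scikit-image's maximiser; an exhaustive brute-force
search over all splits is the independent oracle in the tests. Constant
images raise `NoContrastError` rather than inventing a split.

**Costes.** The green threshold is slaved to the red one through the
ordinary least-squares regression line of green on red over all pixels —
the classic construction for this search. The red threshold starts at
the channel maximum and descends one histogram bin (of 256 by default)
per step; "below the thresholds" is *at-or-below in both channels*, the
exact complement of the strict OR selection, so above/below partitions
the image. The first step at which the below-threshold correlation is
≤ 0 wins. If the bottom of the grid is reached without that (identical
channels are the canonical case), the result is flagged
`converged=False` rather than raising: non-convergence is an informative
outcome. Steps whose below-set is too small or constant in a channel are
skipped. Note the stopping step count is data-dependent: for independent
noise the below-threshold correlation is a near-zero sample quantity and
may stay marginally positive for many steps before crossing zero.

## Z-range analysis

Windows are centred on the floor of the stack midpoint (lower-index bias
for even sizes), grown symmetrically by `step` slices per side and
clipped at the stack edges; thresholds are computed once (or supplied)
and held fixed across windows so the curve isolates the pixel-selection
effect. Empty OR/AND selections in a window record NaN for that row. The
default minimum window is 20 slices, matching the extent of the signal
core in the synthetic benchmark stack.

## Cytofluorogram

Quadrants use the same strict predicate as the pixel selection
(1 = green-only above, 2 = both, 3 = red-only, 4 = neither), so quadrant
2 equals the AND count and 1+2+3 the OR count exactly. The regression is
ordinary least squares of green on red; its slope equals
$\mathrm{PCC}\cdot s_G/s_R$ over the same pixel set and therefore shares
the coefficient's sign. The optional KDE (Gaussian kernel, Scott's rule,
128 × 128 grid padded by four kernel widths so the density normalises on
its own grid) is presentation-only.

## Statistics

Two-sample comparisons use the pooled equal-variance Student's t (not
Welch); one-sample tests compare a set of per-image coefficients against
zero, the no-correlation value. Hedges' g applies the small-sample
correction $J = 1-3/(4N-9)$, $N = n_1+n_2$, making $|g|$ strictly
smaller than Cohen's d.

Randomisation nulls transform the green channel only (configurable):
90° counter-clockwise rotation (one value per image; non-square images
are centre-cropped to the square overlap after rotation) or block
scrambling (tiles of `block_size` must divide the image; one value per
replicate, deterministic under a fixed seed). Thresholds are recomputed
on the transformed pair by default; for pure rotation and scrambling the
per-channel histograms — hence the Otsu thresholds — are unchanged, so
recomputation only matters for the cropped non-square case.

## Problem sizes and numerics

The benchmark canvases follow the study conditions (1000 × 1000 squares
and spots). The synthetic z-stack uses a 200 × 200 × 60 geometry — 20
signal slices between empty flanks — which exercises the same
invariances as a full-size stack because the thresholded selections are
independent of the background volume by construction. Null-distribution
tests use 100 independent-noise pairs at 32 × 32; the expected null mean
is zero regardless of image size, only the spread changes. Agreement
tolerances: 1e−12 against the naive double-loop oracle (pure
floating-point reordering), 1e−10 against closed forms (accumulated
rounding over 10⁶ terms).

## Known limitations

- No Manders coefficients, Spearman correlation or object-based
  colocalisation; no deconvolution or chromatic registration.
- The Costes search couples thresholds through a single global
  regression line; images with grossly unequal object counts per channel
  are known hard cases for this family of methods.
- TIFF only (grayscale pages; interleaved two-channel single files,
  page 0 = green); no proprietary microscope formats.
- Integer images are thresholded in native units; normalisation to
  [0, 1] is opt-in because Pearson correlation is scale-invariant but
  thresholds are not.
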