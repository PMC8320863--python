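# Methods

## Problem and model

Cell nuclei in H&E-stained tissue appear as roughly elliptical blobs of
6–12 px radius (at the magnifications this detector targets), dark in the red
channel of the RGB image.  The detector convolves the smoothed image with a
bank of generalized Laplacian-of-Gaussian (gLoG) filters — band-pass blob
detectors tuned to a range of scales and orientations — and treats regional
maxima of the response maps, restricted to a global foreground mask, as seed
candidates.  Mean-shift clustering collapses the several candidates each
nucleus produces into one center.

### gLoG kernels

G(x, y) = λ·exp(−(a x² + 2 b x y + c y²)) with

    a =  cos²θ/(2σx²) + sin²θ/(2σy²)
    b = −sin 2θ/(4σx²) + sin 2θ/(4σy²)
    c =  sin²θ/(2σx²) + cos²θ/(2σy²)
    λ = 1/(2π σx σy)

the standard oriented-Gaussian quadratic form (the unique convention making θ
a rotation angle), normalized so the continuous G integrates to 1.  The
Laplacian is evaluated in closed form,

    ∇²G = ((2ax + 2by)² + (2bx + 2cy)² − 2a − 2c) · G,

sampled on the kernel grid (x = col − center, y = row − center; the center
tap of an even-sized kernel is the lower-right of the four central taps), and
shifted to exact zero mean so flat regions give zero response.  No per-kernel
scale normalization is applied before summation across scales — the bank sums
raw kernels — but `scale_normalize`-style weighting can be added by callers
building custom banks from `glog_kernel`.

Bank defaults: σ ∈ {6, 6.5, …, 12} (13 scales), θ = nπ/9 for n = 0…8,
25×25 support.  Each oriented filter sums the 78 anisotropic pairs
(σx > σy); the RS filter sums the 13 isotropic kernels.  The full Cartesian
σx > σy pair set is used; no pairs are excluded at the grid boundary.

### Response polarity

∇²G has a negative center tap, so the raw summed filter responds maximally to
*dark* blobs.  The pipeline therefore tracks the effective nuclei brightness
(raw input polarity XOR the optional complement step) and couples two
switches to it: bright nuclei flip the threshold polarity from "keep H < τ"
to "keep H ≥ τ" and negate the gLoG response before 8-bit rescaling.  This
makes the plain-red-channel (dark nuclei) and complemented (bright nuclei)
input conventions produce identical detections on the same underlying tissue.

### 8-bit storage

Every stage stores 8-bit images, mirroring a block-RAM hardware budget.
Smoothing outputs lie in [0, 255] by construction (the kernel sums to 1) and
are truncated toward zero.  Signed gLoG responses are affinely min–max
rescaled to [0, 255] per map and truncated; rescaling is deterministic, uses
the full dynamic range, and preserves the intensity ordering that
regional-maxima extraction depends on — the true hardware mapping of signed
responses to 8 bits is unknown, and only the ordering matters downstream.
A constant response map (e.g. from a constant input) rescales to all zeros.

### Regional maxima

A regional maximum is an 8-connected constant-value plateau whose external
boundary pixels are all strictly lower.  They are found by reconstructing the
marker J = max(I − 1, 0) under mask I and testing I − J′ = 1.  The
reconstruction is the sequential hybrid algorithm: a raster scan updating
J(p) ← min(max({J(p)} ∪ {J(q) : q ∈ N⁺(p)}), I(p)) over the four raster
predecessors; an anti-raster scan doing the same over the four anti-raster
predecessors N⁻(p) and enqueueing p when some q ∈ N⁻(p) has J(q) < J(p) and
J(q) < I(q); and FIFO propagation that raises any 8-neighbor q with
J(q) < J(p) and J(q) < I(q) to min(J(p), I(q)).  The anti-raster scan uses
the anti-raster predecessor set (the reconstruction literature's convention),
and the propagation inequality is implemented as J(q) < I(q), equivalent to
J(q) ≠ I(q) under the maintained invariant J ≤ I.  The result is
pop-order independent (asserted in tests by randomizing the queue) and
bit-identical to the naive fixed-point iteration of min(dilate₈(J), I), which
is kept as an oracle.

Neighbors outside the image are skipped, so a border plateau whose in-image
boundary is lower counts as a maximum.  Pixels with I = 0 have J = J′ = 0 and
never pass the "= 1" test: an all-zero image yields no maxima (the marker
construction cannot descend below zero there).

### Thresholding

Otsu's threshold maximizes the between-class variance w₀w₁(μ₀−μ₁)² over the
256-bin histogram, with classes {v < τ} / {v ≥ τ} matching the mask rule and
ties broken toward the smallest maximizer.  A constant image has no threshold
(error from `otsu_threshold`); the pipeline maps that case to an empty mask
and hence no detections.  The comparison is strictly H < τ as printed in the
mask rule.  Presets pin τ = 155 (set1) / 150 (set2); the default is
auto-Otsu, recomputed per image.

### Mean-shift clustering

Flat circular kernel, default radius r = 8 px, strict distance < r for
membership and < 16 px for merging.  Convergence is declared when the
membership set repeats (guaranteed finite on integer candidates; a cycle
guard also stops the rare membership oscillation).  The current-round vote
V_C increments once per iteration of membership.  At the end of a round the
vote settlement applies to every candidate that collected votes this round,
not only the final kernel members — a candidate swept through early and
dropped before convergence would otherwise stay visited but unassigned.  The
converged center merges with the lowest-id existing nucleus strictly within
the merge threshold (midpoint rule, folding the merged cluster's votes).  The
reported nucleus coordinate is the mean of the candidates finally assigned to
the cluster; the raw converged kernel centers remain inspectable in the
cluster table.  Candidate pick order is deterministic row-major by default
for reproducibility (the arbitration order is not algorithmically
meaningful); a seeded random order is available.

## Fixed-point emulation

Coefficients quantize to signed Q2.14 (round to nearest lattice point;
error ≤ 2⁻¹⁵ per weight; overflow outside ±2 is an error).  The
multiply-accumulate is carried exactly on the integer lattice with a widening
accumulator — no intermediate rounding — then divided by 2¹⁴ and truncated to
8 bits.  For the 7×7 Gaussian the worst-case accumulated coefficient error is
49 × 2⁻¹⁵ × 255 ≈ 0.38 intensity levels, so float and fixed smoothed outputs
can never differ by more than one 8-bit level.  gLoG coefficients (magnitudes
~10⁻⁴–10⁻²) are quantized much more coarsely relative to their size; the
response maps shift slightly, but after rescaling, masking and clustering the
matched nucleus centers on easy synthetic images move well under 2 px.

## Parameter defaults

| parameter | default | notes |
|---|---|---|
| Gaussian size | 7×7 (set2: 8×8) | printed parameter sets |
| Gaussian σ | 1.0 px | not printed anywhere; a light smoothing that suppresses pixel noise without blurring 6-px nuclei (the filter must stay smaller than the smallest nucleus) |
| gLoG support | 25×25 (set2: 49×49) | matches typical nuclei size |
| σ range / step | 6–12 / 0.5 px | nuclei radius range |
| orientations | 9 (θ = nπ/9) | |
| τ | auto-Otsu (set1: 155, set2: 150) | global threshold |
| MS radius r | 8 px (set2: 6) | flat kernel |
| merge threshold | 16 px | nucleus min spacing assumption |
| fixed-point format | Q2.14 | 16 bits, 14 fractional |
| border mode | replicate | avoids dark-frame edge maxima |

## Synthetic data generator

`generate_image` renders n anisotropic Gaussian-profile blobs (semi-axes
drawn from the radius range, eccentricity ≤ 1.8, random orientation; profile
σ = semi-axis/2 so the nominal radius sits at the 2σ falloff) at
intensity 100 on a background of 200 (dark-on-bright default; a
bright-on-dark mode exercises the complemented path), with additive Gaussian
noise (σ = 3) and rejection-sampled centers at ≥ 30 px separation inside a
border margin.  It is deterministic per seed.  This emulates the blob
geometry and contrast the filter bank targets but **not** real H&E tissue:
no staining variation, chromatin texture, touching/overlapping nuclei,
stromal clutter or uneven illumination.  Passing the end-to-end recovery test
demonstrates the pipeline's correctness on its intended blob model, not
clinical-grade accuracy on tissue.

Scoring is greedy one-to-one matching by increasing distance with a
tolerance (default 8 px ≈ one nucleus radius); greedy rather than optimal
assignment is the standard, unambiguous convention for seed scoring.

## Numerical and degenerate-input choices

- Convolution is a direct tap loop in a fixed order: deterministic float
  summation, exact in fixed mode.  Full-size output; replicate default
  padding; reflect padding errors out when the kernel exceeds the image.
- Coordinates are 0-based (row, col) everywhere; CSV header is `row,col`.
- 16-bit inputs rescale linearly to 8 bits (the pipeline is specified
  entirely in 8-bit arithmetic).
- Empty candidate sets, empty detections and constant inputs all return
  empty results rather than raising.
- Problem sizes in tests and the acceptance script: 256×256 synthetic
  images, 10 seeds, oracle cross-checks on 100 random images up to 32×32 —
  sizes at which the brute-force oracles are exact and the full pipeline runs
  in about a second per image.

## Known limitations

- The global threshold is a single scalar per image; heavily non-uniform
  staining defeats it (an adaptive threshold could be substituted upstream of
  the masking stage).
- Touching nuclei closer than the merge threshold are fused into one center.
- The gLoG bank is fixed at build time; nuclei far outside 6–12 px radius
  need a different scale grid.
- Whole-slide formats and tiling are out of scope; inputs are single patches.
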