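# Methods

This note documents the models, numerical choices and limitations behind
`micropat`. It describes what the code computes and why the defaults are
what they are; every number quoted here is produced by the test suite or
the acceptance script, not asserted from external data.

## The measurement problem

A receiver-cell monolayer is cultured on a substrate carrying a binary
micropattern of surface-tethered ligand. Cells activate a synthetic
contact-dependent receptor (synNotch) where they touch ligand, driving a
fluorescent reporter or a differentiation program (e.g. MyoD → myotubes).
The quantification questions are: what fraction of cells activated; how
faithfully does the activation image reproduce the printed design; how do
dual-ligand patterns partition cells into four reporter states; and, for
myogenic conversion, what fraction of nuclei fused into myotubes on versus
off the pattern, and how aligned are the resulting fibers.

## Design patterns

Patterns are binary rasters with a physical pixel size. Rasterization
rounds micrometre dimensions to the nearest pixel and keeps partial
features truncated by the field edge, as a stamp does. The package-wide
coordinate convention is row-major, origin top-left, 0-based indices,
pixel centres on integer coordinates; x runs along columns, y along rows.

The scramble control permutes *all* pixels of the raster uniformly at
random. For a binary raster this is equivalent to relocating the
foreground pixels uniformly; it conserves the foreground count exactly
while destroying all spatial structure, which is what makes it the right
null for the fidelity score. Scrambles are deterministic given a seed, and
a null of `n_scrambles` is driven by child seeds spawned from one master
seed.

## Spatial fidelity and its null

Fidelity is the Pearson correlation between the {0,1} design raster and
the reporter image over the full field (the colocalization-plugin
default; an ROI restriction is available). A constant image or an
all-ones/all-zeros mask raises an error rather than returning a silent 0 —
a zero-variance correlation is undefined, not absent.

The scramble null uses `n_scrambles = 100` by default. The empirical
p-value uses the add-one rule `(1 + #{null >= observed}) / (n + 1)`:
conservative on ties and never exactly zero, so the minimum attainable p
with 100 scrambles is 1/101. Under pixel permutation the null correlation
has mean 0 and standard deviation ≈ `1/sqrt(N−1)` for `N` pixels; the test
suite checks both against theory.

## Activation model

Per-cell activation is Bernoulli with a Hill dose–response plus basal
leak:

    p(c) = p_basal + (p_max − p_basal) · c^h / (K^h + c^h)

- `p_max = 0.9`, `K = 30 µg/mL`, `h = 2`, `p_basal = 0.05` by default.
  These place the response near saturation at ~100 µg/mL ligand (the
  coating regime where activation plateaus) with a small basal leak, and
  reflect the bimodal, incomplete activation typical of this receptor
  class. `c` is the mean ligand dose under the cell's disk footprint —
  the receptor is contact-dependent, so a cell integrates the ligand it
  physically sits on; cells straddling a pattern edge therefore activate
  at intermediate probability, which is the generator's mechanism for
  fidelity loss at small feature sizes.
- A binary pattern converts to a dose raster as `mask × dose`; within-
  pattern dose gradients are not modelled.
- Dual-pathway cells: `both_ligand_mode='independent'` draws the two
  pathways independently; `'impaired'` deterministically vetoes
  double-active draws (both pathways reset to inactive). The veto is a
  stated phenomenological stand-in for stunted co-differentiation under
  simultaneous induction of two transcription-factor programs — the
  mechanism (receptor-level vs transcription-factor-level) is not modelled.

The Hill fit (`fit_dose_response`) is nonlinear least squares with
multistart initialization over a (K, h) grid (K at the positive doses and
their geometric mid, h ∈ {0.5, 1, 2, 4}), bounds keeping probabilities in
[0,1] and K positive; the start with the lowest residual sum of squares
wins. A constant response is flagged non-converged with `p_max` set to the
mean. Noiseless five-point ladders ({0, 10, 50, 100, 200} µg/mL) recover K
to better than 1%; with binomial sampling noise at 2000 cells per dose,
every one of 100 seeds recovers K within 20%.

## Synthetic scenes

`place_cells` is a hard-core point process: a Poisson-distributed count of
uniform proposals, rejecting any proposal within `min_spacing_um` of an
accepted cell (grid-hashed neighbour lookup), with an error after a
bounded proposal budget when the requested density is infeasible.

Rendering paints each cell as a uniform disk (nucleus as a smaller disk at
0.6× the cell radius), convolves with a Gaussian PSF and adds Gaussian
read noise (optionally Poisson shot noise). Where cells overlap the
default blend is additive — projected fluorescence adds — with a `'max'`
option for strict monolayer tiling. Active-reporter intensities can carry
log-normal spread (σ configurable, mean-preserving) to reproduce the
broad, overlapping intensity distributions of real reporter expression.
All randomness flows from one seed; scenes are bit-identical across runs.

Two cell-geometry regimes are used deliberately:

- *Quantification scenes* (percent activation, four-state classification,
  myogenic index) use disjoint or nearly disjoint cells (spacing ≥ cell
  diameter), so per-cell means are uncontaminated by neighbours and
  measured quantities can be compared to ground truth at binomial
  precision.
- *Fidelity scenes* use spread, overlapping fibroblasts (radius ~30 µm at
  800 cells/mm², a confluent monolayer) because the fidelity score is a
  tissue-scale statistic: with sparse nucleus-sized dots the Pearson
  correlation is dominated by empty background rather than by pattern
  geometry.

A consequence worth stating: against a flat binary mask, Pearson fidelity
of a *textured* image improves as sub-cellular texture is smoothed away.
Blur therefore has two regimes — below one cell diameter it removes
monolayer graininess and can raise the correlation; above it, it degrades
the pattern itself. The monotonic "fidelity decreases with PSF" property
holds, and is tested, in the optical-degradation regime (σ from one cell
diameter up), with deterministic activation so that per-cell Bernoulli
noise does not confound the comparison. The same feature-size sweep that
mirrors the experimental ordering (r for 500 µm squares/1000 µm gaps >
250/250 > 100/100, all parameters fixed) runs at 5 µm PSF on the confluent
geometry, where the ranking is driven by edge-straddling cells and basal
leak.

Myotube scenes scatter nuclei over the field, fuse each with probability
`on_pattern_fusion_prob` on-pattern (default basal 0.05 off-pattern,
encoding the leak of the myogenic program), group fused nuclei by
proximity into myotubes of ≥ 2 nuclei (singleton groups revert to
unfused; the *realized* fused flags are the ground truth), and render each
myotube as a ribbon — a rotated rectangle 15 µm wide whose length grows
with its nucleus count — with its member nuclei relocated onto the
centreline so that colocalization is physically consistent. Ribbon
orientations are axial von Mises about the pattern axis: a doubled-angle
von Mises draw halved, so `kappa = 0` is isotropic and `kappa = ∞`
collapses exactly onto the axis. On/off-pattern membership is recomputed
after relocation, so recorded truth always refers to final positions.

## Segmentation and per-cell measurement

The segmentation chain is Gaussian blur → binarize → optional
distance-transform watershed → area filter, labels contiguous from 1. The
default threshold is Otsu on the blurred channel; fixed raw-unit
thresholds are accepted for reproducibility (intensities are never
rescaled on read, so fixed thresholds are dialect-independent). Watershed
seeds are local maxima of the distance transform with a minimum separation
defaulting to the median object's equivalent radius. An image that
thresholds to empty yields zero labels, not an error. The segmentation
channel is configurable: nuclei by default, a constitutive cytoplasmic
marker for cell-body segmentation.

Positive/negative calls compare the *mean* intensity over the cell's
pixels to a threshold. Percent activation with zero cells is NaN with an
`undefined` flag — never a silent 0%. Cell-to-region assignment for the
four-state classification is by centroid membership with precedence in
mask order; a centroid in no region falls in `'unpatterned'`. State
counts per region always sum to the region total.

## Orientation statistics

Orientation is estimated from the structure tensor
`J = G_σ * (∇I ∇Iᵀ)` with `tensor_sigma = 2 px` by default (the standard
neighbourhood scale of the reference plugin), computed with reflective
boundary handling so image borders do not fabricate gradients. The local
orientation is the minor eigenvector's angle, reported in degrees in
[−90°, 90°) measured counter-clockwise from +x with y up; coherency is
`(λ₁−λ₂)/(λ₁+λ₂) ∈ [0,1]`; energy is the tensor trace. Constant images
have zero energy and an all-invalid mask — orientation is undefined there.

Histograms use 360 bins of 0.5° over the axial domain [−90°, 90°); line
structures have 180° symmetry, so this is the full support. The default
weight is pixel counts, with energy- and coherency-weighted variants. The
order parameter is computed from the histogram's bin centres via the
doubled-angle resultant — equivalently the largest eigenvalue of the mean
orientational order tensor ⟨2nnᵀ−I⟩, equal to 2⟨cos²(θ−θ̄)⟩−1 about the
director. Its endpoints are exact: all weight in one bin gives 1; a
uniform histogram gives 0 by symmetry of the 360 equal bins. Binning can
move each doubled angle by at most 0.5°, so the histogram path agrees
with direct per-pixel averaging to within `2·sin(0.25°)` ≈ 0.009; the
suite also checks convergence of sampled axial von Mises fields to the
closed form I₁(κ)/I₀(κ).

Curved-pattern coherency uses polyline band straightening: the polyline
is resampled at exact one-pixel arc steps, and pixels are bilinearly
interpolated along local normals over the requested band width, giving a
raster of height = band width and length = arc length. The routine warns
when the band half-width exceeds the local radius of curvature (the band
self-intersects); a single-vertex polyline is an error.

## Pipeline and reproducibility

The CLI stages (`simulate`, `quantify`, `fidelity`, `orient`, `myo`,
`dose`, `all`) read one YAML configuration with recorded defaults. Every
output table and JSON summary carries the seed, a hash of the scientific
parameters (the output directory is excluded from the hash), and the
package version; identical configurations produce byte-identical outputs.
Exit codes: 0 success, 2 configuration error, 1 runtime error.

## Problem sizes

Default test and acceptance problem sizes are chosen as the smallest at
which each statistical claim is decidable at 3-SE precision: 3×3 mm fields
at 10 µm/px for fidelity sweeps (~7 000 cells), 1 mm² at 4 µm/px for
percent-activation recovery (~1 000 cells), 2000 cells per dose × 100
seeds for Hill-K recovery, 10⁶ angles for the randomized orientation
endpoint, and ~500 on-pattern nuclei for myogenic-index recovery.

## What the synthetic scenes do and do not show

The generator reproduces the *statistical* structure of the experiments:
dose-dependent stochastic activation with leak, four-state dual-reporter
outcomes, confluent-monolayer reporter images registered to a design
raster, and aligned multinucleated fibers with ground-truth fusion. It
does not model reporter accumulation dynamics, cell migration,
mechanics of receptor activation, 3-D volumes (2-D projections only), or
within-pattern ligand gradients. Passing recovery tests therefore
demonstrates that the quantification chain is unbiased and correctly
calibrated on images whose generative process is known — not that any
particular biological claim holds; on real images, segmentation quality
and threshold choice remain the dominant sources of error, and the
Methods-style defaults here (Otsu, mean-intensity calls, centroid
colocalization) are declared choices, configurable where a lab's
convention differs.

## Known limitations

- Percent-activation accuracy degrades on heavily overlapping monolayers
  (additive fluorescence contaminates neighbouring cells' means); use
  disjoint-regime scenes to validate thresholds, or max-blend rendering.
- The greedy proximity grouping of fused nuclei is a placement heuristic,
  not a fusion model; realized fusion rates sit slightly below nominal
  probabilities because singleton groups revert (ground truth records the
  realized flags).
- The watershed's default seed separation assumes roughly round nuclei of
  similar size.
- Pattern-to-image registration is assumed exact; no alignment is
  performed.
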