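# Methods

## Model

The segmenter assumes a two-class image: pixel intensities are Gaussian
around a class mean (vessel μ₁ or μ₂, background the other), with a common
spread. The spatial constraint couples each pixel's likelihood to its
neighbours through mixing weights λ_ij, the Gaussian geometric closeness
h_ij = exp(−‖u_i − u_j‖²/(2σ_g²)) normalised over the window 𝒩_i. Because
the λ_ij are constants of the model they drop out of the minimised
functional; they are still computed and exposed (`vesselset.weights`) for
completeness and for future weighted variants. What survives is the
count-weighted data energy

    e_k(x_j) = c(j) · (x_j − μ_k)²,   c(j) = #{i ∈ Ω : j ∈ 𝒩_i},

a strict superset of the Chan–Vese data term (c ≡ 1). c(j) is computed by
convolving the domain indicator with the binary window, zero-padded, so
border neighbourhoods truncate naturally.

**Domain.** When the image carries a FOV mask, the domain Ω *is* the FOV:
neighbourhood counts, class means and the data force are all restricted to
it. The black surround of a fundus photograph is not retina; including it
drags the dark-class mean toward zero and visibly weakens the vessel-class
force (on the reference phantom, sensitivity drops from ≈0.96 to ≈0.62).
Without a FOV mask the full frame is the domain.

**Common variance.** Only the common-variance functional is implemented;
per-class variances would not alter the minimising partition under the
two-class assumption and the alternating scheme is derived without them.

## Level set evolution

The partition is the sign of φ; region membership is smoothed with
H_ε(z) = ½[1 + (2/π)arctan(z/ε)] and its derivative δ_ε. The total energy
adds a contour-length penalty (weight α) and the distance-regularisation
penalty ½(|∇φ|−1)² (weight β) that keeps φ well-conditioned without ever
reinitialising it to a signed distance function.

Minimisation alternates:

1. mean updates — count-weighted averages of each region under H_ε;
2. one time step Δt of the gradient flow.

### Numerical scheme

- Central differences with replicate (Neumann) edges everywhere; |∇φ| is
  floored at 1e−10 in denominators. The β-term is expanded as
  Δφ − div(∇φ/|∇φ|) for symmetry with the curvature operator.
- **Inner substepping.** The β-term is a diffusion with rate β; an explicit
  five-point step is stable only for β·dt ≲ 0.25, while the working
  parameters give β·Δt ≈ 6.5. A single explicit step therefore overflows
  within ~100 iterations (verified on the reference fixtures). Each Δt
  interval is instead integrated with m = ceil(βΔt/0.2) inner explicit
  substeps of the *full* right-hand side — the same flow advanced by the
  same total time, with every substep inside the stability bound. With the
  defaults m = 33; with β = 0, m = 1 (plain explicit Euler).
- **Initialisation.** Default is a binary step ±2 on a centred circle of
  radius min(h, w)/3 — a step rather than a distance function so that
  δ_ε(φ₀) is bounded away from zero everywhere and every pixel feels the
  data force from the first iteration. Checkerboard (sine product) and
  Otsu-threshold initialisations are selectable; the segmentation is
  insensitive to the choice (tested). The circle centre sits at the integer
  pixel (h//2, w//2), which also breaks exact left–right ties on symmetric
  images.
- **Stopping.** The evolution stops when the fraction of pixels whose sign
  of φ changed between consecutive outer iterations falls below 1e−4, or
  after 500 iterations. Two-class block fixtures converge in 2–3
  iterations. On fine vessel phantoms a small population of vessel-edge
  pixels (~0.5%) flickers indefinitely — the regularisation diffusion and
  the δ-throttled data force fight over them — so the sign criterion never
  fires and the run uses the full budget; the segmentation itself is stable
  from about iteration 5 and `converged=False` is reported honestly.
- **Reported means.** During evolution the means use H_ε per the update
  rule. The *returned* means are recomputed with the exact step over the
  delivered binary partition: they are the minimisers of the data term for
  the partition the caller actually receives (H_ε-weighted means sit a
  couple of intensity units off when stationarity is reached before H_ε
  saturates).
- **Vessel labelling.** The converged region with the lower mean is labelled
  vessel by default (vessels are dark in the fundus green channel);
  `vessel_class="brighter"` flips the rule.
- Empty regions keep the previous mean; non-finite φ raises a divergence
  error carrying the iteration and the largest update magnitude.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| α | 1.0 | — | contour length weight; smooths the vessel boundary |
| β | 0.001·255² ≈ 65.0 | — | distance-regularisation weight, calibrated to 0–255 intensities |
| Δt | 0.1 | time | gradient-flow step per outer iteration |
| ε | 1.0 | φ units | width of H_ε/δ_ε; not prescribed by the formulation, 1.0 is the standard choice for O(1) initial φ |
| σ_g² | 10 | pixel² | spatial scale of the closeness kernel |
| radius | 1 | pixels | neighbourhood window (1 ⇒ 3×3) |
| tolerance | 1e−4 | — | sign-change fraction declaring stationarity |
| max_iterations | 500 | — | outer-iteration budget |

Images are kept on the native 0–255 scale because β is calibrated to it;
`--normalize` rescales intensities to [0, 1] and β by 1/255² together, which
leaves the minimiser unchanged.

## Synthetic data

`two_block_fixture` is the minimal two-class image (left/right constant
blocks plus Gaussian noise). `generate_phantom` emulates what the model
assumes about fundus images: a dark curvilinear tree (random-walk
centerlines with smoothly varying heading, linear width taper within 2–5 px,
one bifurcation level per branch) on a bright disk-shaped FOV, intensities
80/180 with σ = 10 on the 0–255 scale, zero outside the FOV. Defaults are
the reference conditions used throughout the tests; everything is
bit-reproducible from the seed.

The phantom deliberately omits features of real fundus photographs:
illumination gradients, the bright optic disc, central vessel reflexes,
pathologies, and vessel-contrast variation. Passing the phantom tests shows
the method works when its class model holds; it does not bound performance
on real DRIVE/STARE images, which the CLI can process when the user supplies
them.

## Evaluation

Counts are restricted to the FOV; sensitivity = TP/(TP+FN) over vessel
pixels, specificity = TN/(TN+FP) over background, accuracy over all FOV
pixels. A rate whose denominator is empty is reported as missing, never as
zero. Aggregates average per-image metrics with equal weights.

## Problem sizes

The reference checks use a 64×64 two-block fixture (noise σ = 5) for
parameter recovery and energy descent, a 256² phantom for end-to-end
segmentation quality, and ≤16×16 random fields for oracle equivalence of
every numeric operation against independent scalar-loop implementations.

## Known limitations

- The alternating scheme minimises a nonconvex functional; the smoothed
  H_ε/δ_ε give it a global character in practice (tested via initialisation
  insensitivity) but no guarantee exists.
- The sign-change stopping rule can leave `converged=False` on images with
  fine structure even though the segmentation is stable (see above).
- Two phases only; bright lesions or the optic disc are forced into the
  background class by the two-class assumption.
- The data force is pointwise given the means: very low-contrast vessels
  (|μ separation| comparable to noise) degrade gracefully but are not
  specially enhanced — no matched filtering or vesselness prefiltering is
  applied by design.
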