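# vesselset

Two-phase level set segmentation of retinal blood vessels driven by a
spatially weighted Bayesian region energy.

Retinal fundus photographs show dark, curvilinear vessel trees on a brighter
background, and separating them from that background is a standard first
step for diagnosing cardiovascular and ophthalmologic disease. `vesselset`
implements an unsupervised region-based segmenter for this problem: no
training data, just a two-class intensity model with a spatial coupling that
encourages connected vessel structure.

## The model

Pixels are assumed to follow one of two Gaussian intensity classes (vessel /
background) with a common spread. Each pixel's likelihood is coupled to its
neighbours through mixing weights λ_ij ∝ exp(−‖u_i − u_j‖²/(2σ_g²)) over a
square window 𝒩_i, which makes the negative log-likelihood (up to constants)

    ℱ(μ) = Σ_k Σ_{j∈Ω_k} e_k(x_j),    e_k(x_j) = c(j) · (x_j − μ_k)²,

where c(j) counts the neighbourhood windows containing pixel j. With the
partition carried by the sign of a level set function φ (Ω₁ = {φ > 0}), a
contour length term and a distance-regularisation term are added:

    ℱ(φ, μ) = Σ_j e₁ H_ε(φ) + Σ_j e₂ (1 − H_ε(φ))
              + α Σ_i δ_ε(φ)|∇φ| + β Σ_i ½(|∇φ| − 1)²,

with the smoothed step pair H_ε(z) = ½[1 + (2/π)arctan(z/ε)],
δ_ε(z) = (1/π)·ε/(ε² + z²). Minimisation alternates closed-form mean
updates with the gradient flow

    ∂φ/∂t = δ_ε(φ)(e₂ − e₁) + α δ_ε(φ) div(∇φ/|∇φ|) + β div((1 − 1/|∇φ|)∇φ)

until the sign pattern of φ is stationary. Defaults (α = 1, Δt = 0.1,
β = 0.001·255², σ_g² = 10, 3×3 window) are calibrated for 0–255 intensities.
All metrics (accuracy, sensitivity, specificity) are computed inside the
circular field of view (FOV) of the photograph.

## Worked example

```python
import numpy as np
from vesselset import PhantomSpec, generate_phantom, segment, score

sample = generate_phantom(PhantomSpec(seed=7))     # 256² vessel phantom
result = segment(sample.image)                     # two-phase level set
m = score(result.vessel, sample.truth, sample.fov)
print(f"mu = ({result.mu[0]:.1f}, {result.mu[1]:.1f})")
print(f"accuracy={m.accuracy:.4f} sensitivity={m.sensitivity:.4f} "
      f"specificity={m.specificity:.4f}")
```

prints

```
mu = (86.4, 179.8)
accuracy=0.9952 sensitivity=0.9635 specificity=0.9968
```

The recovered means sit near the phantom's generating class means (vessel 80,
background 180; the dark-class mean is pulled slightly up by vessel-edge
pixels). 99.5% of FOV pixels are classified correctly, 96% of true vessel
pixels are found, and 99.7% of background pixels are kept clean.

The same pipeline runs from the shell, including on DRIVE/STARE-layout
directories when you have the databases:

```sh
vesselset phantom --out data --seed 7
vesselset segment data/phantom-7_image.png --fov data/phantom-7_fov.png --out runs
vesselset evaluate runs data truth-dir   # Table-style metrics report
```

Short narrative scripts for each capability live in `examples/`.

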