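"""Neighborhood weighting kernels.

The spatial coupling of the segmentation model ties each pixel's likelihood
to its neighbours through mixing weights λ_ij.  λ_ij is the geometric
closeness h_ij = exp(−‖u_i − u_j‖²/(2σ_g²)) normalised to sum to one over
the neighbourhood 𝒩_i.  The indicator window ρ (1 inside the neighbourhood,
0 outside) drives the counting convolutions of the energy module.

The mixing weights are constants of the model: they drop out of the
minimised functional, but are computed and exposed for completeness and for
weighted variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Square pixel neighbourhood of side 2·radius + 1.

    Parameters
    ----------
    radius:
        Half-width of the window in pixels; radius 1 gives the default
        3×3 window.
    sigma_g_sq:
        σ_g², the squared spatial scale (pixel²) of the Gaussian closeness;
        default 10.
    include_center:
        Whether the pixel belongs to its own neighbourhood. Default True so
        a pixel's own intensity contributes to its likelihood.
    """

    radius: int = 1
    sigma_g_sq: float = 10.0
    include_center: bool = True

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if not self.sigma_g_sq > 0:
            raise ValueError(f"sigma_g_sq must be positive, got {self.sigma_g_sq}")

    @property
    def size(self) -> int:
        """Number of pixels in the window (including a masked center)."""
        return (2 * self.radius + 1) ** 2


@dataclass(frozen=True)
class WeightKernel:
    """Geometric closeness h and normalised mixing weights λ over a window."""

    h: np.ndarray
    lam: np.ndarray


def geometric_closeness(spec: NeighborhoodSpec) -> np.ndarray:
    """Gaussian closeness kernel h at every window offset.

    h(du, dv) = exp(−(du² + dv²)/(2 σ_g²)); the center value is 1 and h
    decays monotonically with the offset norm.
    """
    r = spec.radius
    dv, du = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    return np.exp(-(du * du + dv * dv) / (2.0 * spec.sigma_g_sq))


def window_indicator(spec: NeighborhoodSpec) -> np.ndarray:
    """Binary window ρ: 1 inside the neighbourhood, 0 outside.

    The center entry is 0 when ``include_center`` is False.
    """
    k = np.ones((2 * spec.radius + 1,) * 2, dtype=float)
    if not spec.include_center:
        k[spec.radius, spec.radius] = 0.0
    return k


def mixing_weights(spec: NeighborhoodSpec) -> WeightKernel:
    """Closeness kernel together with λ = h / Σ h over the neighbourhood.

    λ sums to exactly one over the neighbourhood set; entries outside the
    set (the center when excluded) are zero.
    """
    h = geometric_closeness(spec)
    rho = window_indicator(spec)
    total = float(np.sum(h * rho))
    if total <= 0:
        raise ValueError("degenerate closeness kernel: window sums to zero")
    return WeightKernel(h=h, lam=h * rho / total)
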