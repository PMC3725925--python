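"""Region energy functional for two-phase segmentation.

The model assumes two Gaussian intensity classes with a common variance, so
the negative log-likelihood reduces (up to constants) to

    ℱ(μ) = Σ_k Σ_{j∈Ω_k} e_k(x_j),      e_k(x_j) = c(j)·(x_j − μ_k)²,

where c(j) counts how many neighbourhood windows contain pixel j — the
spatial coupling turns the plain Chan–Vese data term into a count-weighted
one.  With a level set function φ whose sign encodes the two regions, the
total functional is

    ℱ(φ, μ) = Σ_j e₁ H_ε(φ) + Σ_j e₂ (1 − H_ε(φ)) + α ℒ(φ) + β ℛ(φ),

with ℒ the contour length Σ δ_ε(φ)|∇φ| and ℛ the distance-regularisation
penalty Σ ½(|∇φ| − 1)² that keeps φ close to a signed distance function
without reinitialisation.

Counting convolutions use zero padding so that border neighbourhoods
truncate naturally (out-of-domain pixels simply do not exist); gradients use
central differences with replicate edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import convolve2d

from ._fd import dirac_eps, grad_magnitude, heaviside_eps
from .weights import NeighborhoodSpec, window_indicator

#: default regularisation weight, calibrated to the 0–255 intensity scale
DEFAULT_BETA = 0.001 * 255.0**2


@dataclass
class IntensityImage:
    """2-D scalar intensity field, optionally with a field-of-view mask.

    ``values`` is stored as float64; the native 0–255 scale is the default
    and the regularisation weight β is calibrated to it.  ``scale`` records
    the maximum of the nominal intensity range.
    """

    values: np.ndarray
    fov: np.ndarray | None = None
    scale: float = 255.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.fov is not None:
            self.fov = np.asarray(self.fov, dtype=bool)
            if self.fov.shape != self.values.shape:
                raise ValueError(
                    f"fov shape {self.fov.shape} != image shape {self.values.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class ModelParams:
    """Class means and the fixed hyperparameters of the functional.

    Defaults follow the working parameter set for 0–255 fundus images:
    α = 1.0, Δt = 0.1, β = 0.001·255², σ_g² = 10 with a 3×3 window, ε = 1.
    ``mu`` may be None, in which case the means are estimated during the
    evolution.
    """

    mu: tuple[float, float] | None = None
    alpha: float = 1.0
    beta: float = DEFAULT_BETA
    dt: float = 0.1
    epsilon: float = 1.0
    spec: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")

    def with_mu(self, mu: tuple[float, float]) -> "ModelParams":
        return replace(self, mu=(float(mu[0]), float(mu[1])))


@dataclass(frozen=True)
class EnergyBreakdown:
    """Total energy and its three components (data, α-length, β-distance)."""

    data_term: float
    length_term: float
    regularization_term: float
    alpha: float
    beta: float

    @property
    def total(self) -> float:
        return (
            self.data_term
            + self.alpha * self.length_term
            + self.beta * self.regularization_term
        )


def neighbor_count(
    shape: tuple[int, int],
    spec: NeighborhoodSpec,
    fov: np.ndarray | None = None,
) -> np.ndarray:
    """c(j): number of pixels i ∈ Ω whose window 𝒩_i contains j.

    Equals the window size in the interior and shrinks towards borders
    (zero-padded convolution of the domain indicator with ρ).  When a FOV
    mask is given the domain Ω is the FOV, so counts also shrink at the FOV
    boundary and vanish away from it.
    """
    rho = window_indicator(spec)
    dom = np.ones(shape, dtype=float) if fov is None else np.asarray(fov, float)
    return convolve2d(dom, rho, mode="same", boundary="fill")


def energy_density(
    image: IntensityImage, mu_k: float, spec: NeighborhoodSpec | None = None
) -> np.ndarray:
    """Per-pixel class energy e_k(x_j) = c(j)·(x_j − μ_k)².

    Defined for j ∈ Ω: with a FOV mask present, Ω is the FOV and e_k is
    zero outside it.
    """
    spec = spec or NeighborhoodSpec()
    c = neighbor_count(image.shape, spec, image.fov)
    d = image.values - float(mu_k)
    out = c * d * d
    if image.fov is not None:
        out = np.where(image.fov, out, 0.0)
    return out


def data_energy(image: IntensityImage, phi: np.ndarray, params: ModelParams) -> float:
    """Region data term Σ e₁ H_ε(φ) + Σ e₂ (1 − H_ε(φ))."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != image.shape:
        raise ValueError(f"phi shape {phi.shape} != image shape {image.shape}")
    if params.mu is None:
        raise ValueError("params.mu must be set to evaluate the data energy")
    e1 = energy_density(image, params.mu[0], params.spec)
    e2 = energy_density(image, params.mu[1], params.spec)
    h = heaviside_eps(phi, params.epsilon)
    return float(np.sum(e1 * h) + np.sum(e2 * (1.0 - h)))


def length_energy(phi: np.ndarray, epsilon: float = 1.0) -> float:
    """Contour length ℒ(φ) = Σ δ_ε(φ)|∇φ| (arc length of the zero level)."""
    phi = np.asarray(phi, dtype=float)
    return float(np.sum(dirac_eps(phi, epsilon) * grad_magnitude(phi)))


def distance_regularization_energy(phi: np.ndarray) -> float:
    """ℛ(φ) = Σ ½(|∇φ| − 1)²; zero iff φ is a sampled signed distance."""
    mag = grad_magnitude(np.asarray(phi, dtype=float))
    return float(np.sum(0.5 * (mag - 1.0) ** 2))


def total_energy(
    image: IntensityImage, phi: np.ndarray, params: ModelParams
) -> EnergyBreakdown:
    """Assemble ℱ(φ, μ) = data + α·ℒ + β·ℛ."""
    return EnergyBreakdown(
        data_term=data_energy(image, phi, params),
        length_term=length_energy(phi, params.epsilon),
        regularization_term=distance_regularization_energy(phi),
        alpha=params.alpha,
        beta=params.beta,
    )
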