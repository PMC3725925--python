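"""Finite-difference stencils and smoothed step functions shared by the
energy and evolution modules.

All gradients are central differences with replicate (Neumann) boundary
handling; the same convention is used everywhere so that energies and their
gradient flow are mutually consistent.
"""

from __future__ import annotations

import numpy as np

#: floor applied to |∇φ| wherever it appears in a denominator
GRAD_FLOOR = 1e-10


def heaviside_eps(z: np.ndarray | float, epsilon: float = 1.0) -> np.ndarray:
    """Smoothed Heaviside H_ε(z) = ½[1 + (2/π) arctan(z/ε)].

    Strictly increasing, maps R onto (0, 1) with H_ε(0) = ½.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    z = np.asarray(z, dtype=float)
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(z / epsilon))


def dirac_eps(z: np.ndarray | float, epsilon: float = 1.0) -> np.ndarray:
    """Smoothed Dirac δ_ε(z) = (1/π)·ε/(ε² + z²), the derivative of H_ε.

    Even, positive, peaks at δ_ε(0) = 1/(πε) and integrates to 1 over R.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    z = np.asarray(z, dtype=float)
    return (epsilon / np.pi) / (epsilon * epsilon + z * z)


def grad_central(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (∂f/∂row, ∂f/∂col) with replicate edges."""
    fp = np.pad(np.asarray(f, dtype=float), 1, mode="edge")
    gy = 0.5 * (fp[2:, 1:-1] - fp[:-2, 1:-1])
    gx = 0.5 * (fp[1:-1, 2:] - fp[1:-1, :-2])
    return gy, gx


def divergence(vy: np.ndarray, vx: np.ndarray) -> np.ndarray:
    """Divergence of a vector field, same stencil as :func:`grad_central`."""
    dy, _ = grad_central(vy)
    _, dx = grad_central(vx)
    return dy + dx


def laplacian(f: np.ndarray) -> np.ndarray:
    """Five-point Laplacian with replicate edges."""
    fp = np.pad(np.asarray(f, dtype=float), 1, mode="edge")
    return (
        fp[2:, 1:-1] + fp[:-2, 1:-1] + fp[1:-1, 2:] + fp[1:-1, :-2]
        - 4.0 * fp[1:-1, 1:-1]
    )


def grad_magnitude(f: np.ndarray) -> np.ndarray:
    gy, gx = grad_central(f)
    return np.sqrt(gy * gy + gx * gx)


def curvature(f: np.ndarray) -> np.ndarray:
    """div(∇f/|∇f|): mean curvature of the level lines of f.

    |∇f| is floored at GRAD_FLOOR before normalising, which bounds the
    normalised gradient components by 1 in magnitude.
    """
    gy, gx = grad_central(f)
    mag = np.maximum(np.sqrt(gy * gy + gx * gx), GRAD_FLOOR)
    return divergence(gy / mag, gx / mag)
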