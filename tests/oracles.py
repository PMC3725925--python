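"""Independent scalar-loop oracles for the energy and evolution operations.

Everything here is written with explicit Python loops and index clamping,
sharing no array code with the package, so that agreement with the
vectorised implementations is a real check and not a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def _clamp(i: int, n: int) -> int:
    return max(0, min(i, n - 1))


def heaviside(z: float, eps: float) -> float:
    return 0.5 * (1.0 + (2.0 / math.pi) * math.atan(z / eps))


def dirac(z: float, eps: float) -> float:
    return (eps / math.pi) / (eps * eps + z * z)


def neighbor_count(shape, radius: int, include_center: bool = True, fov=None) -> np.ndarray:
    """c(j) = #{i in the domain : j in the window of i}, by brute force."""
    h, w = shape
    c = np.zeros((h, w))
    for iy in range(h):
        for ix in range(w):
            if fov is not None and not fov[iy, ix]:
                continue
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if not include_center and dy == 0 and dx == 0:
                        continue
                    jy, jx = iy + dy, ix + dx
                    if 0 <= jy < h and 0 <= jx < w:
                        c[jy, jx] += 1.0
    return c


def energy_density(values, mu_k: float, radius: int, include_center: bool = True, fov=None) -> np.ndarray:
    c = neighbor_count(values.shape, radius, include_center, fov)
    h, w = values.shape
    e = np.zeros((h, w))
    for jy in range(h):
        for jx in range(w):
            if fov is not None and not fov[jy, jx]:
                continue
            dv = values[jy, jx] - mu_k
            # same multiply association as the vectorised code so that the
            # chaotic data force near φ = 0 cannot amplify ulp differences
            e[jy, jx] = c[jy, jx] * dv * dv
    return e


def data_energy(values, phi, mu1, mu2, eps, radius, include_center=True, fov=None) -> float:
    e1 = energy_density(values, mu1, radius, include_center, fov)
    e2 = energy_density(values, mu2, radius, include_center, fov)
    total = 0.0
    h, w = values.shape
    for jy in range(h):
        for jx in range(w):
            hv = heaviside(phi[jy, jx], eps)
            total += e1[jy, jx] * hv + e2[jy, jx] * (1.0 - hv)
    return total


def _grad_at(f, y, x):
    h, w = f.shape
    gy = 0.5 * (f[_clamp(y + 1, h), x] - f[_clamp(y - 1, h), x])
    gx = 0.5 * (f[y, _clamp(x + 1, w)] - f[y, _clamp(x - 1, w)])
    return gy, gx


def length_energy(phi, eps: float) -> float:
    h, w = phi.shape
    total = 0.0
    for y in range(h):
        for x in range(w):
            gy, gx = _grad_at(phi, y, x)
            total += dirac(phi[y, x], eps) * math.sqrt(gy * gy + gx * gx)
    return total


def distance_regularization_energy(phi) -> float:
    h, w = phi.shape
    total = 0.0
    for y in range(h):
        for x in range(w):
            gy, gx = _grad_at(phi, y, x)
            total += 0.5 * (math.sqrt(gy * gy + gx * gx) - 1.0) ** 2
    return total


def update_means(values, phi, eps, radius, include_center=True, sharp=False, fov=None):
    c = neighbor_count(values.shape, radius, include_center, fov)
    h, w = values.shape
    num1 = den1 = num2 = den2 = 0.0
    for y in range(h):
        for x in range(w):
            if fov is not None and not fov[y, x]:
                continue
            hv = (1.0 if phi[y, x] >= 0 else 0.0) if sharp else heaviside(phi[y, x], eps)
            num1 += c[y, x] * values[y, x] * hv
            den1 += c[y, x] * hv
            num2 += c[y, x] * values[y, x] * (1.0 - hv)
            den2 += c[y, x] * (1.0 - hv)
    return num1 / den1, num2 / den2


def _rhs_loops(phi, e_diff, alpha, beta, eps, floor=1e-10):
    """One right-hand-side evaluation of the gradient flow, all loops."""
    h, w = phi.shape
    ny = np.zeros((h, w))
    nx = np.zeros((h, w))
    lap = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            gy, gx = _grad_at(phi, y, x)
            mag = max(math.sqrt(gy * gy + gx * gx), floor)
            ny[y, x] = gy / mag
            nx[y, x] = gx / mag
            lap[y, x] = (
                phi[_clamp(y + 1, h), x] + phi[_clamp(y - 1, h), x]
                + phi[y, _clamp(x + 1, w)] + phi[y, _clamp(x - 1, w)]
                - 4.0 * phi[y, x]
            )
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            ky = 0.5 * (ny[_clamp(y + 1, h), x] - ny[_clamp(y - 1, h), x])
            kx = 0.5 * (nx[y, _clamp(x + 1, w)] - nx[y, _clamp(x - 1, w)])
            kappa = ky + kx
            d = dirac(phi[y, x], eps)
            out[y, x] = d * e_diff[y, x] + alpha * d * kappa + beta * (lap[y, x] - kappa)
    return out


def gradient_flow_step(values, phi, mu, alpha, beta, dt, eps, radius,
                       include_center=True, fov=None, stable_number=0.2):
    """One Δt interval with the same CFL-limited inner substepping."""
    e1 = energy_density(values, mu[0], radius, include_center, fov)
    e2 = energy_density(values, mu[1], radius, include_center, fov)
    e_diff = e2 - e1
    m = max(1, math.ceil(beta * dt / stable_number))
    dt_in = dt / m
    phi = phi.copy()
    for _ in range(m):
        phi = phi + dt_in * _rhs_loops(phi, e_diff, alpha, beta, eps)
    return phi
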