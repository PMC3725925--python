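"""Ground-truthed synthetic inputs.

The phantom realises exactly the assumptions of the segmentation model: two
intensity classes with Gaussian noise of common spread — a dark curvilinear
vessel tree on a brighter circular field of view.  Vessel realism is
deliberately minimal (random-walk tubes with linear taper and a single
bifurcation level): the purpose is to exercise the model under its own
assumptions, not to imitate retinal anatomy.

Everything is bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import IntensityImage
from .io import RetinalSample


class GenerationError(RuntimeError):
    """The requested phantom degenerated (e.g. empty vessel tree)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Vessel phantom parameters.

    Defaults give a 256² phantom with vessel mean 80 and background mean 180
    on the 0–255 scale, noise σ = 10, six branches of width 2–5 px inside a
    FOV disk filling 90% of the frame — a mid-contrast, mid-noise regime for
    two-class fundus-like images.
    """

    shape: tuple[int, int] = (256, 256)
    mu_vessel: float = 80.0
    mu_background: float = 180.0
    noise_sigma: float = 10.0
    n_branches: int = 6
    width_range: tuple[float, float] = (2.0, 5.0)
    curvature_scale: float = 0.15
    fov_radius_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_vessel == self.mu_background:
            raise ValueError("mu_vessel must differ from mu_background")
        if self.width_range[0] < 1:
            raise ValueError("minimum vessel width must be >= 1 pixel")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0 < self.fov_radius_fraction <= 1:
            raise ValueError("fov_radius_fraction must be in (0, 1]")


def _stamp_disk(mask: np.ndarray, cy: float, cx: float, radius: float) -> None:
    """Mark a filled disk in-place, clipped to the frame."""
    h, w = mask.shape
    r = max(radius, 0.5)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _walk_branch(
    tree: np.ndarray,
    rng: np.random.Generator,
    start: tuple[float, float],
    heading: float,
    length: int,
    w_start: float,
    w_end: float,
    curvature_scale: float,
    fov_center: tuple[float, float],
    fov_radius: float,
    allow_split: bool,
) -> None:
    """Trace one tapering tube by a smooth random walk; may bifurcate once."""
    cy, cx = start
    split_at = rng.integers(length // 3, length) if allow_split and length >= 3 else -1
    for step in range(length):
        frac = step / max(length - 1, 1)
        width = w_start + (w_end - w_start) * frac
        _stamp_disk(tree, cy, cx, width / 2.0)
        if step == split_at:
            child_heading = heading + rng.choice((-1.0, 1.0)) * rng.uniform(0.35, 0.8)
            child_len = max(int((length - step) * 0.8), 2)
            _walk_branch(
                tree, rng, (cy, cx), child_heading, child_len,
                width, w_end, curvature_scale, fov_center, fov_radius,
                allow_split=False,
            )
        heading += rng.normal(0.0, curvature_scale)
        cy += np.sin(heading)
        cx += np.cos(heading)
        if (cy - fov_center[0]) ** 2 + (cx - fov_center[1]) ** 2 > fov_radius**2:
            break


def generate_phantom(spec: PhantomSpec) -> RetinalSample:
    """Dark vessel tree on a bright FOV disk with Gaussian class noise.

    Returns the noisy image, the exact binary vessel truth, and the FOV
    disk.  Pixels outside the FOV are zero (before noise), mimicking the
    dark surround of fundus photographs.
    """
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    fov_radius = spec.fov_radius_fraction * min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    fov = (yy - cy) ** 2 + (xx - cx) ** 2 <= fov_radius**2

    tree = np.zeros((h, w), dtype=bool)
    w_min, w_max = spec.width_range
    for _ in range(spec.n_branches):
        heading = rng.uniform(0.0, 2.0 * np.pi)
        length = int(fov_radius * rng.uniform(0.7, 1.0))
        start = (cy + rng.normal(0, 2), cx + rng.normal(0, 2))
        root_width = rng.uniform(max(w_min, 0.6 * w_max), w_max)
        _walk_branch(
            tree, rng, start, heading, length, root_width, w_min,
            spec.curvature_scale, (cy, cx), fov_radius, allow_split=True,
        )

    truth = tree & fov
    if not truth.any():
        raise GenerationError("vessel tree is empty after clipping to the FOV")

    clean = np.where(fov, np.where(truth, spec.mu_vessel, spec.mu_background), 0.0)
    noisy = clean + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    noisy = np.clip(noisy, 0.0, 255.0)
    image = IntensityImage(values=noisy, fov=fov)
    return RetinalSample(
        image=image, fov=fov, truth=truth, sample_id=f"phantom-{spec.seed}"
    )


def two_block_fixture(
    shape: tuple[int, int] = (64, 64),
    v_left: float = 50.0,
    v_right: float = 200.0,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> RetinalSample:
    """Minimal two-class fixture: left half v_left, right half v_right.

    The truth map marks the darker half as vessel (matching the default
    vessel-class rule); the FOV is the full frame.
    """
    h, w = shape
    if w < 2:
        raise ValueError("width must be >= 2")
    rng = np.random.default_rng(seed)
    clean = np.empty((h, w), dtype=float)
    clean[:, : w // 2] = v_left
    clean[:, w // 2 :] = v_right
    noisy = clean + rng.normal(0.0, noise_sigma, size=(h, w))
    fov = np.ones((h, w), dtype=bool)
    if v_left == v_right:
        truth = np.zeros((h, w), dtype=bool)
    else:
        darker = v_left if v_left < v_right else v_right
        truth = clean == darker
    return RetinalSample(
        image=IntensityImage(values=noisy, fov=fov),
        fov=fov,
        truth=truth,
        sample_id=f"two-block-{seed}",
    )
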