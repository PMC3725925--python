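"""Reading retinal images, masks and ground truth.

Supports the directory layouts of the two common fundus benchmarks: the
DRIVE layout (``images/``, ``mask/``, ``1st_manual/`` with names like
``21_training.tif`` / ``21_training_mask.gif`` / ``21_manual1.gif``) and the
STARE layout (flat ``im0001.ppm`` files with ``im0001.ah.ppm`` /
``im0001.vk.ppm`` manual maps, no FOV masks).  When no FOV mask is
available one is estimated from the image brightness.

Conventions: row-major, 0-based pixel-center coordinates; RGB images are
reduced to a single working channel (default green — the highest-contrast
channel for vessels in fundus photographs); 8-bit masks binarise at > 127.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .energy import IntensityImage

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".ppm", ".gif", ".jpg", ".jpeg")

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}
#: Rec. 601 luma weights for the "gray" rule
_LUMA = np.array([0.299, 0.587, 0.114])


class FovEstimationError(RuntimeError):
    """No plausible field of view could be found; supply an explicit mask."""


@dataclass
class RetinalSample:
    """One fundus image with its FOV mask and optional vessel ground truth."""

    image: IntensityImage
    fov: np.ndarray
    truth: np.ndarray | None
    sample_id: str

    def __post_init__(self) -> None:
        self.fov = np.asarray(self.fov, dtype=bool)
        if self.fov.shape != self.image.shape:
            raise ValueError("fov shape does not match the image")
        if not self.fov.any():
            raise ValueError("fov mask is empty")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=bool)
            if self.truth.shape != self.image.shape:
                raise ValueError("truth shape does not match the image")


def _binarize(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:  # masks occasionally ship as RGB; any channel works
        arr = arr[..., 0]
    if arr.dtype == bool:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        return arr > 127
    return arr > 0.5 * float(arr.max()) if arr.max() > 0 else arr > 0


def extract_channel(arr: np.ndarray, channel_rule: str = "green") -> np.ndarray:
    """Reduce a decoded image array to the 2-D working channel."""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        if channel_rule != "gray":
            logger.info("grayscale input: channel rule %r is a passthrough", channel_rule)
        return arr.astype(float)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        if channel_rule == "gray":
            return arr[..., :3].astype(float) @ _LUMA
        try:
            idx = _CHANNEL_INDEX[channel_rule]
        except KeyError:
            raise ValueError(f"unknown channel rule {channel_rule!r}") from None
        logger.info("channel rule %r -> channel index %d", channel_rule, idx)
        return arr[..., idx].astype(float)
    raise ValueError(f"expected a 2-D or 3-D image array, got shape {arr.shape}")


def estimate_fov(image: IntensityImage, threshold_fraction: float = 0.08) -> np.ndarray:
    """Estimate the field of view from brightness.

    Largest connected component of pixels brighter than
    ``threshold_fraction``·max, morphologically closed (disk radius 5) and
    hole-filled.
    """
    from skimage.morphology import closing, disk

    vmax = float(image.values.max())
    rough = image.values > threshold_fraction * vmax if vmax > 0 else np.zeros(image.shape, bool)
    if not rough.any():
        raise FovEstimationError(
            "could not estimate a field of view (image too dark); "
            "supply an explicit mask file"
        )
    labels, n = ndi.label(rough)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        rough = labels == (1 + int(np.argmax(sizes)))
    mask = closing(rough, disk(5))
    return ndi.binary_fill_holes(mask)


def load_sample(
    image_path: str | Path,
    fov_path: str | Path | None = None,
    truth_path: str | Path | None = None,
    channel_rule: str = "green",
    fov_threshold_fraction: float = 0.08,
) -> RetinalSample:
    """Load an image (plus optional FOV / truth maps) into a RetinalSample.

    A missing FOV mask is estimated with :func:`estimate_fov`.
    """
    image_path = Path(image_path)
    try:
        raw = iio.imread(image_path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"cannot read image {image_path}: {exc}") from exc
    values = extract_channel(raw, channel_rule)
    image = IntensityImage(values=values)

    if fov_path is not None:
        fov = _binarize(iio.imread(Path(fov_path)))
        if fov.shape != image.shape:
            raise ValueError(
                f"FOV mask shape {fov.shape} != image shape {image.shape} ({fov_path})"
            )
    else:
        fov = estimate_fov(image, fov_threshold_fraction)
    image.fov = fov

    truth = None
    if truth_path is not None:
        truth = _binarize(iio.imread(Path(truth_path)))
        if truth.shape != image.shape:
            raise ValueError(
                f"truth map shape {truth.shape} != image shape {image.shape} ({truth_path})"
            )
    return RetinalSample(image=image, fov=fov, truth=truth, sample_id=image_path.stem)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary map as an 8-bit PNG (0 / 255)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary map written by :func:`save_mask` (or any 8-bit mask)."""
    return _binarize(iio.imread(Path(path)))


def _sample_number(stem: str) -> str:
    """Leading digit group of a file stem ('21_training' -> '21')."""
    digits = ""
    for ch in stem:
        if ch.isdigit():
            digits += ch
        elif digits:
            break
    return digits or stem


def find_drive_samples(
    root: str | Path, annotator: int = 1
) -> list[dict[str, Path | None]]:
    """Pair image/mask/manual files in a DRIVE-layout directory.

    Returns a list of dicts with keys ``image``, ``fov``, ``truth``,
    ``sample_id``, sorted by sample id.
    """
    root = Path(root)
    images = sorted(
        p for p in (root / "images").glob("*") if p.suffix.lower() in IMAGE_SUFFIXES
    )
    manual_dir = root / f"{annotator}st_manual" if annotator == 1 else root / f"{annotator}nd_manual"
    out = []
    for img in images:
        sid = _sample_number(img.stem)
        fov = next(iter((root / "mask").glob(f"{img.stem}_mask.*")), None)
        truth = next(iter(manual_dir.glob(f"{sid}_manual*.*")), None) if manual_dir.is_dir() else None
        out.append({"image": img, "fov": fov, "truth": truth, "sample_id": sid})
    return out


def find_stare_samples(
    root: str | Path, annotator: str = "ah"
) -> list[dict[str, Path | None]]:
    """Pair image/manual files in a flat STARE-layout directory.

    STARE ships no FOV masks; ``fov`` is always None (estimated downstream).
    """
    root = Path(root)
    out = []
    for img in sorted(root.glob("im*")):
        if img.suffix.lower() not in IMAGE_SUFFIXES:
            continue
        stem = img.stem
        if ".ah" in stem or ".vk" in stem:  # manual maps, not raw images
            continue
        truth = next(iter(root.glob(f"{stem}.{annotator}.*")), None)
        out.append({"image": img, "fov": None, "truth": truth, "sample_id": stem})
    return out
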