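"""Image preprocessing and segmentation for two-channel punctum imaging.

The processing chain mirrors a standard ImageJ punctum workflow: rolling-ball
background subtraction, whole-field photobleaching correction for movies,
local-mean ("auto local threshold") segmentation of diffraction-limited
patches, and connected-component patch detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.morphology import disk
from skimage.transform import resize

__all__ = [
    "Field2C",
    "BinaryMask",
    "PatchSet",
    "subtract_background",
    "correct_photobleaching",
    "local_threshold",
    "detect_patches",
]


@dataclass
class Field2C:
    """One registered two-channel field of view.

    ``red`` is the anchor channel (membrane platforms), ``green`` the prey
    channel. Intensities are in ADU, pixel coordinates 0-based (row, col).
    """

    red: np.ndarray
    green: np.ndarray
    strain: str = ""
    condition: str = "minusRAP"
    field_index: int = 0

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.shape != self.green.shape:
            raise ValueError("red and green channels must have the same shape")
        if self.red.ndim != 2:
            raise ValueError("channels must be 2-D arrays")
        for name, chan in (("red", self.red), ("green", self.green)):
            if not np.all(np.isfinite(chan)):
                raise ValueError(f"{name} channel contains non-finite values")
            if np.any(chan < 0):
                raise ValueError(f"{name} channel contains negative intensities")
        if self.condition not in ("minusRAP", "plusRAP"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class BinaryMask:
    """Boolean foreground mask produced by segmentation of one channel."""

    mask: np.ndarray
    source_channel: str = ""
    params: tuple = ()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class PatchSet:
    """Connected components of a mask: (centroid_row, centroid_col, area_px)."""

    patches: list[tuple[float, float, int]] = field(default_factory=list)
    connectivity: int = 8

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def centroids(self) -> np.ndarray:
        if not self.patches:
            return np.empty((0, 2))
        return np.array([(r, c) for r, c, _ in self.patches], dtype=float)

    @property
    def total_area(self) -> int:
        return int(sum(a for _, _, a in self.patches))


def _ball_structure(radius: float) -> np.ndarray:
    """Height profile of a ball of the given radius (non-flat SE)."""
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    height = np.sqrt(np.clip(radius**2 - d2, 0.0, None))
    # push pixels outside the ball far down so they never bind
    height[d2 > radius**2] = -np.inf
    return height


def _rolling_ball_background(image: np.ndarray, radius: float) -> np.ndarray:
    """Background as grayscale opening with a ball structuring element."""
    structure = _ball_structure(radius)
    finite = np.isfinite(structure)
    # scipy handles non-flat SEs through the structure argument; -inf entries
    # are replaced by a large negative offset (ndimage rejects inf)
    safe = np.where(finite, structure, structure[finite].min() - 1e12)
    return ndimage.grey_opening(image, structure=safe, mode="reflect")


def _block_min(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-minimum downsampling (keeps the rolling ball under the surface)."""
    h, w = image.shape
    ph = (-h) % factor
    pw = (-w) % factor
    padded = np.pad(image, ((0, ph), (0, pw)), mode="edge")
    hh, ww = padded.shape
    return padded.reshape(hh // factor, factor, ww // factor, factor).min(axis=(1, 3))


def subtract_background(
    image: np.ndarray,
    radius_px: float = 115.0,
    downsample: int | Literal["auto"] = "auto",
) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is estimated by rolling a ball of the given radius under
    the intensity surface (a grayscale opening with a ball structuring
    element) and subtracted; the result is clipped at zero. Features narrower
    than the ball are preserved.

    For large radii the image is first shrunk by block-minimum (the classic
    ImageJ speed-up), the ball rolled on the shrunk image, and the background
    interpolated back up; pass ``downsample=1`` to force the exact
    computation.

    Parameters
    ----------
    image : 2-D array
        Input intensities (finite).
    radius_px : float
        Ball radius in pixels; must be >= 1 and smaller than the image extent.
    downsample : int or "auto"
        Shrink factor; "auto" picks 1/2/4/8 by radius.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px >= min(image.shape):
        raise ValueError("rolling-ball radius exceeds image extent")

    if downsample == "auto":
        if radius_px <= 16:
            factor = 1
        elif radius_px <= 32:
            factor = 2
        elif radius_px <= 100:
            factor = 4
        else:
            factor = 8
    else:
        factor = int(downsample)
        if factor < 1:
            raise ValueError("downsample factor must be >= 1")

    if factor == 1:
        background = _rolling_ball_background(image, radius_px)
    else:
        small = _block_min(image, factor)
        background = _rolling_ball_background(small, max(radius_px / factor, 1.0))
        background = resize(
            background,
            (small.shape[0] * factor, small.shape[1] * factor),
            order=1,
            mode="edge",
            anti_aliasing=False,
        )[: image.shape[0], : image.shape[1]]

    background = np.clip(background, 0.0, None)
    background = np.minimum(background, image)
    return np.clip(image - background, 0.0, None)


def correct_photobleaching(stack: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Rescale each frame of a movie so the whole-field mean is constant.

    Every frame is multiplied by mean(frame 0)/mean(frame t); relative
    intra-frame structure is unchanged. Model-free ratio correction.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must contain at least 2 frames (T, H, W)")
    means = stack.mean(axis=(1, 2))
    if np.any(means == 0):
        raise ValueError("frame with zero mean intensity cannot be corrected")
    factors = means[0] / means
    return stack * factors[:, None, None]


def local_threshold(
    image: np.ndarray,
    radius_px: int = 5,
    offset: float = 12.0,
    window: Literal["disk", "square"] = "disk",
    source_channel: str = "",
) -> BinaryMask:
    """Local adaptive (mean) threshold for punctate structures.

    A pixel is foreground iff ``image(p) > local_mean(p) + offset`` where the
    local mean is taken over a disk (default, radius ``radius_px``) or square
    window of half-width ``radius_px``, with reflective border padding. The
    defaults (radius 5, offset 12) select diffraction-limited spots standing
    at least 12 ADU above their neighborhood, the ImageJ mean-method call
    with C = -12.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")

    # sum-then-divide keeps integer-valued images exact (ADU are counts)
    if window == "disk":
        kernel = disk(int(radius_px)).astype(float)
    elif window == "square":
        kernel = np.ones((2 * int(radius_px) + 1,) * 2)
    else:
        raise ValueError("window must be 'disk' or 'square'")
    local_mean = ndimage.correlate(image, kernel, mode="reflect") / kernel.sum()

    return BinaryMask(
        mask=image > local_mean + offset,
        source_channel=source_channel,
        params=(radius_px, offset),
    )


def detect_patches(
    mask: BinaryMask | np.ndarray,
    min_area_px: int = 4,
    max_area_px: int = 200,
) -> PatchSet:
    """8-connected components of a mask filtered by pixel area.

    Components with area in ``[min_area_px, max_area_px]`` (inclusive) are
    kept; centroids are arithmetic means of member-pixel coordinates.
    """
    if min_area_px > max_area_px:
        raise ValueError("min_area_px must be <= max_area_px")
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    labeled = label(arr, connectivity=2)
    patches = []
    for prop in regionprops(labeled):
        if min_area_px <= prop.area <= max_area_px:
            r, c = prop.centroid
            patches.append((float(r), float(c), int(prop.area)))
    return PatchSet(patches=patches, connectivity=8)
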