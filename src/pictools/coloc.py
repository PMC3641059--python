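"""Area-based colocalization scoring between prey and anchor masks.

The recruitment readout is deliberately simple: the number of pixels in the
intersection of the green (prey) and red (anchor) foreground masks,
normalized by the red-mask area (which scales with cell number and is
unaffected by the treatment), then compared between +rapamycin and vehicle
conditions as a ratio. Intensity-correlation measures (Pearson/Manders) are
out of scope: the metric here is area-based only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .imgproc import BinaryMask, PatchSet

__all__ = [
    "ColocRecord",
    "RecruitmentScore",
    "EmptyMaskError",
    "UndefinedFractionError",
    "colocalization_area",
    "recruitment_ratio",
    "patch_colocalization_fraction",
    "score_manual",
]


class EmptyMaskError(ValueError):
    """Raised when the red (normalizing) mask is empty."""


class UndefinedFractionError(ValueError):
    """Raised when a patch fraction is requested for an empty patch set."""


@dataclass(frozen=True)
class ColocRecord:
    """Per-field colocalization measurement.

    ``a_inter`` is the pixel count of the green∧red mask intersection,
    ``a_red`` the red-mask pixel count, and ``s = a_inter / a_red`` the
    normalized colocalization score (0 <= s <= 1).
    """

    a_inter: int
    a_red: int
    s: float
    strain: str = ""
    condition: str = "minusRAP"
    field_index: int = 0


@dataclass(frozen=True)
class RecruitmentScore:
    """Per-strain +RAP/−RAP ratio of mean normalized colocalization scores.

    ``pseudocount_used`` flags records where the vehicle-condition mean score
    was exactly zero and the ratio fell back to pooled intersection sums with
    a one-pixel pseudocount.
    """

    ratio: float
    strain: str = ""
    pseudocount_used: bool = False


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    return mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)


def colocalization_area(
    green_mask: BinaryMask | np.ndarray,
    red_mask: BinaryMask | np.ndarray,
    strain: str = "",
    condition: str = "minusRAP",
    field_index: int = 0,
) -> ColocRecord:
    """Intersection area of the two masks, normalized by the red-mask area."""
    green = _as_bool(green_mask)
    red = _as_bool(red_mask)
    if green.shape != red.shape:
        raise ValueError("masks must have the same shape")
    a_red = int(red.sum())
    if a_red == 0:
        raise EmptyMaskError("red mask is empty; cannot normalize")
    a_inter = int(np.logical_and(green, red).sum())
    return ColocRecord(
        a_inter=a_inter,
        a_red=a_red,
        s=a_inter / a_red,
        strain=strain,
        condition=condition,
        field_index=field_index,
    )


def recruitment_ratio(
    records_plus: list[ColocRecord],
    records_minus: list[ColocRecord],
    pseudocount: float = 1.0,
) -> RecruitmentScore:
    """Ratio of mean normalized scores, +RAP over −RAP.

    When the vehicle-condition mean score is exactly zero the ratio is
    instead computed from pooled intersection sums with ``pseudocount``
    pixels added to both numerators (preserves ordering, avoids infinities)
    and the result is flagged.
    """
    if not records_plus or not records_minus:
        raise ValueError("both condition groups must be non-empty")
    strains = {r.strain for r in records_plus} | {r.strain for r in records_minus}
    if len(strains) > 1:
        raise ValueError(f"records mix strains: {sorted(strains)}")
    strain = records_plus[0].strain

    mean_plus = float(np.mean([r.s for r in records_plus]))
    mean_minus = float(np.mean([r.s for r in records_minus]))
    if mean_minus > 0:
        return RecruitmentScore(ratio=mean_plus / mean_minus, strain=strain)

    s_plus = (sum(r.a_inter for r in records_plus) + pseudocount) / sum(
        r.a_red for r in records_plus
    )
    s_minus = (sum(r.a_inter for r in records_minus) + pseudocount) / sum(
        r.a_red for r in records_minus
    )
    return RecruitmentScore(ratio=s_plus / s_minus, strain=strain, pseudocount_used=True)


def patch_colocalization_fraction(
    green_patches: PatchSet,
    red_mask: BinaryMask | np.ndarray,
    tolerance_px: int = 0,
) -> float:
    """Fraction of green patch centroids on (or within tolerance of) the red mask.

    This is the quantitative form of the manual scoring rule: a prey scores
    as an interactor when more than 90% of its membrane patches colocalize
    with the anchor.
    """
    if tolerance_px < 0:
        raise ValueError("tolerance_px must be >= 0")
    if len(green_patches) == 0:
        raise UndefinedFractionError(
            "patch fraction undefined for an empty green patch set"
        )
    red = _as_bool(red_mask)
    if tolerance_px > 0:
        red = ndimage.binary_dilation(red, structure=disk(int(tolerance_px)))
    h, w = red.shape
    hits = 0
    for r, c, _ in green_patches.patches:
        ri = min(max(int(round(r)), 0), h - 1)
        ci = min(max(int(round(c)), 0), w - 1)
        if red[ri, ci]:
            hits += 1
    return hits / len(green_patches)


def score_manual(fraction: float, cutoff: float = 0.9) -> bool:
    """Manual interaction call: true iff fraction is strictly above cutoff."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return fraction > cutoff
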