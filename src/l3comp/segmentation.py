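"""HU-threshold body-composition segmentation with spatial compartments.

Tissue candidates come from the Alberta-protocol Hounsfield-unit ranges
(skeletal muscle -29..150, visceral fat -150..-50, subcutaneous fat
-190..-30, all bounds inclusive).  Because the two fat ranges overlap,
geometry decides the compartment: the abdominal muscle wall is closed
morphologically and filled, fat inside that contour is visceral (VAT),
fat between the contour and the body boundary is subcutaneous (SAT).

The segmentation is deterministic: 8-neighbour connectivity for
connected components, 4-neighbour for hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .errors import AlignmentError, InvalidInputError, NoBodyError

TISSUES = ("sm", "vat", "sat")

#: HU threshold below which a pixel is considered air / gas (not body).
BODY_AIR_THRESHOLD_HU = -190.0


@dataclass(frozen=True)
class ThresholdSet:
    """Inclusive per-tissue HU bounds.

    Defaults are the Alberta-protocol SliceOmatic thresholds used for
    abdominal body-composition grading.
    """

    sm: tuple[float, float] = (-29.0, 150.0)
    vat: tuple[float, float] = (-150.0, -50.0)
    sat: tuple[float, float] = (-190.0, -30.0)

    def __post_init__(self) -> None:
        for t in TISSUES:
            lo, hi = getattr(self, t)
            if not lo < hi:
                raise InvalidInputError(f"{t} bounds must satisfy low < high, got ({lo}, {hi})")

    def bounds(self, tissue: str) -> tuple[float, float]:
        if tissue not in TISSUES:
            raise InvalidInputError(f"unknown tissue {tissue!r}, expected one of {TISSUES}")
        return getattr(self, tissue)


ALBERTA = ThresholdSet()


@dataclass(frozen=True)
class MorphologyParams:
    """Structural parameters of the compartment separation."""

    closing_radius_px: int = 5
    min_object_px: int = 20
    body_closing_radius_px: int = 3

    def __post_init__(self) -> None:
        if self.closing_radius_px < 1 or self.min_object_px < 0:
            raise InvalidInputError("morphology parameters must be positive")


DEFAULT_MORPHOLOGY = MorphologyParams()


class LabelMask:
    """Mutually exclusive per-pixel tissue assignment.

    A single integer grid guarantees label disjointness by construction:
    0 = background, 1 = SM, 2 = VAT, 3 = SAT.
    """

    BACKGROUND, SM, VAT, SAT = 0, 1, 2, 3
    _CODE = {"sm": SM, "vat": VAT, "sat": SAT}

    def __init__(self, labels: np.ndarray):
        labels = np.asarray(labels)
        if labels.ndim != 2:
            raise InvalidInputError("labels must be a 2-D grid")
        if labels.min() < 0 or labels.max() > 3:
            raise InvalidInputError("labels must be in {0, 1, 2, 3}")
        self.labels = labels.astype(np.uint8)

    @classmethod
    def from_masks(cls, sm: np.ndarray, vat: np.ndarray, sat: np.ndarray) -> "LabelMask":
        labels = np.zeros(sm.shape, dtype=np.uint8)
        labels[sat] = cls.SAT
        labels[vat] = cls.VAT
        labels[sm] = cls.SM  # muscle has precedence; ranges make overlap impossible anyway
        return cls(labels)

    def mask(self, tissue: str) -> np.ndarray:
        if tissue not in self._CODE:
            raise InvalidInputError(f"unknown tissue {tissue!r}")
        return self.labels == self._CODE[tissue]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelMask) and np.array_equal(self.labels, other.labels)


def body_mask(
    hu_image: np.ndarray,
    air_threshold_hu: float = BODY_AIR_THRESHOLD_HU,
    closing_radius_px: int = DEFAULT_MORPHOLOGY.body_closing_radius_px,
) -> np.ndarray:
    """Binary mask of the patient cross-section.

    Largest 8-connected component of pixels above the air threshold,
    after morphological closing; interior air pockets (e.g. bowel gas)
    are filled so the body is simply connected.
    """
    hu = np.asarray(hu_image)
    cand = hu > air_threshold_hu
    if closing_radius_px > 0:
        cand = morphology.closing(cand, morphology.disk(closing_radius_px))
    # fill interior air pockets (e.g. bowel gas) before picking the largest
    # component, so a gas-separated interior region cannot outgrow the wall
    cand = ndimage.binary_fill_holes(cand)  # 4-connected background
    lab = measure.label(cand, connectivity=2)
    if lab.max() == 0:
        raise NoBodyError("no body found: image is all air")
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return lab == largest


def threshold_tissue(
    hu_image: np.ndarray, thresholds: ThresholdSet, tissue: str
) -> np.ndarray:
    """Raw (pre-compartment) candidate mask: ``low <= HU <= high``."""
    lo, hi = thresholds.bounds(tissue)
    hu = np.asarray(hu_image)
    return (hu >= lo) & (hu <= hi)


def muscle_contour(sm: np.ndarray, closing_radius_px: int) -> np.ndarray:
    """Filled outer muscle contour: close the muscle mask, then fill it.

    The result is the whole region enclosed by (and including) the
    abdominal muscle wall; its complement within the body is the
    subcutaneous compartment.
    """
    closed = morphology.closing(sm, morphology.disk(closing_radius_px))
    return ndimage.binary_fill_holes(closed)


def segment_composition(
    hu_image: np.ndarray,
    thresholds: ThresholdSet = ALBERTA,
    morphology_params: MorphologyParams = DEFAULT_MORPHOLOGY,
) -> LabelMask:
    """Segment skeletal muscle, visceral fat and subcutaneous fat.

    Pipeline: body mask -> muscle by HU range (small objects removed) ->
    filled muscle contour -> SAT = SAT-range fat outside the contour,
    VAT = VAT-range fat inside it.  Fat pixels inside the contour whose
    HU falls only in the SAT range (outside -150..-50) stay background.
    """
    hu = np.asarray(hu_image)
    body = body_mask(hu, closing_radius_px=morphology_params.body_closing_radius_px)
    sm = threshold_tissue(hu, thresholds, "sm") & body
    if morphology_params.min_object_px > 0:
        sm = morphology.remove_small_objects(
            sm, max_size=morphology_params.min_object_px - 1, connectivity=2
        )
    contour = muscle_contour(sm, morphology_params.closing_radius_px)
    sat = threshold_tissue(hu, thresholds, "sat") & body & ~contour
    vat = threshold_tissue(hu, thresholds, "vat") & contour & ~sm
    return LabelMask.from_masks(sm, vat, sat)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Sorensen-Dice overlap ``2|A∩B| / (|A|+|B|)``; 1.0 when both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def dice_per_tissue(pred: LabelMask, truth: LabelMask) -> dict[str, float]:
    """Per-tissue Dice between a predicted and a reference label mask."""
    if pred.shape != truth.shape:
        raise AlignmentError(f"label shapes differ: {pred.shape} vs {truth.shape}")
    return {t: dice(pred.mask(t), truth.mask(t)) for t in TISSUES}


def save_mask_png(
    mask: LabelMask,
    path: "str | Path",
    slice_id: str = "",
    thresholds: ThresholdSet = ALBERTA,
) -> None:
    """Persist a label mask as an indexed PNG (0/1/2/3 = bg/SM/VAT/SAT)
    plus a JSON sidecar recording the source slice and thresholds."""
    import json

    from PIL import Image

    path = Path(path)
    img = Image.fromarray(mask.labels, mode="P")
    # background black, SM red, VAT yellow, SAT blue
    img.putpalette([0, 0, 0, 220, 40, 40, 230, 200, 40, 60, 90, 220])
    img.save(path)
    sidecar = {
        "slice_id": slice_id,
        "labels": {"background": 0, "sm": 1, "vat": 2, "sat": 3},
        "thresholds_hu": {t: list(thresholds.bounds(t)) for t in TISSUES},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_mask_png(path: "str | Path") -> LabelMask:
    """Read a label mask written by :func:`save_mask_png`."""
    from PIL import Image

    return LabelMask(np.asarray(Image.open(path)))
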