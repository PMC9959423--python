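"""Image-level tooth segmentation and opaque/brown quantification.

Pipeline: per-pixel 5-class FKNN labeling (k = 1) -> binary tooth mask ->
morphological opening + dilation -> reclassification of background pixels
enclosed by the tooth (FKNN k = 5, restricted to the four tooth classes)
-> collapse to three tooth classes -> removal of tiny opaque/brown
components -> opaque and brown area ratios.

Tiny components are dropped when their area falls below 0.55% (opaque) or
0.05% (brown) of the tooth region; dropped pixels become white_yellow so
cleanup can never create disease evidence.  Ratios use the tooth pixel
count |white_yellow| + |opaque| + |brown| as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import measure, morphology

from .color_features import image_to_features
from .fknn import FknnConfig, classify_batch
from .labels import (BACKGROUND, BACKGROUND3, BROWN3, OPAQUE3, TOOTH_CLASSES,
                     TO_THREE_CLASS, WHITE_YELLOW)
from .prototypes import PrototypeSet


@dataclass
class SegmentationConfig:
    scale_hue: bool = True
    opening_radius: int | None = None   # None -> max(1, round(0.002 * image diagonal))
    dilation_radius: int = 1
    min_opaque_frac: float = 0.0055
    min_brown_frac: float = 0.0005
    m_scale: float = 1.5


@dataclass
class SegmentationResult:
    class_map5: np.ndarray     # raster of 5-class codes
    class_map3: np.ndarray     # raster of {white_yellow, opaque, brown, background}
    mask: np.ndarray           # binary tooth mask
    r_opaque: float
    r_brown: float
    intermediates: dict = field(default_factory=dict)


_COLLAPSE = np.array([TO_THREE_CLASS[c] for c in range(5)], dtype=np.intp)


def predict_class_map(img, prototypes: PrototypeSet, scale_hue: bool = True,
                      m_scale: float = 1.5) -> np.ndarray:
    """Per-pixel 5-class labels by nearest prototype (FKNN k = 1)."""
    img = np.asarray(img)
    features, _ = image_to_features(img, scale_hue=scale_hue)
    codes = classify_batch(features, prototypes, FknnConfig(k=1, m_scale=m_scale))
    return codes.reshape(img.shape[:2])


def default_opening_radius(shape) -> int:
    """Opening radius scaled to the image diagonal (resolution invariance)."""
    diag = float(np.hypot(shape[0], shape[1]))
    return max(1, round(0.002 * diag))


def morphological_cleanup(mask, opening_radius: int | None = None,
                          dilation_radius: int = 1) -> np.ndarray:
    """Binary opening (disk) to drop speckle, then dilation to restore area."""
    mask = np.asarray(mask, dtype=bool)
    r_open = default_opening_radius(mask.shape) if opening_radius is None else opening_radius
    out = morphology.opening(mask, morphology.disk(r_open))
    if dilation_radius > 0:
        out = morphology.dilation(out, morphology.disk(dilation_radius))
    return out.astype(bool)


def reclassify_enclosed_background(img, mask, class_map, prototypes: PrototypeSet,
                                   scale_hue: bool = True, m_scale: float = 1.5):
    """Relabel background pixels enclosed by the tooth region.

    Enclosed pixels (hole-filling difference of the mask) are reclassified
    with FKNN k = 5 restricted to the four tooth classes — unrestricted,
    the classifier could return background again and the step would be a
    no-op.  Pixels outside the holes never change.  Returns the updated
    (class_map, mask).
    """
    mask = np.asarray(mask, dtype=bool)
    holes = binary_fill_holes(mask) & ~mask
    class_map = np.asarray(class_map).copy()
    if not holes.any():
        return class_map, mask
    img = np.asarray(img)
    features, _ = image_to_features(img, scale_hue=scale_hue)
    hole_idx = np.flatnonzero(holes.ravel())
    tooth_protos = prototypes.subset(TOOTH_CLASSES)
    codes = classify_batch(features[hole_idx], tooth_protos,
                           FknnConfig(k=5, m_scale=m_scale))
    flat = class_map.ravel()
    flat[hole_idx] = codes
    return flat.reshape(class_map.shape), mask | holes


def to_three_class(class_map, mask) -> np.ndarray:
    """Collapse 5-class labels to {white_yellow, opaque, brown, background}.

    Everything outside the mask is background; background-labeled pixels
    inside the mask stay background (they are excluded from the tooth
    denominator).
    """
    out = _COLLAPSE[np.asarray(class_map, dtype=np.intp)]
    out[~np.asarray(mask, dtype=bool)] = BACKGROUND3
    return out


def _tooth_pixel_count(class_map3, mask) -> int:
    inside = np.asarray(class_map3)[np.asarray(mask, dtype=bool)]
    return int(np.count_nonzero(inside != BACKGROUND3))


def remove_small_regions(class_map3, mask, min_opaque_frac: float = 0.0055,
                         min_brown_frac: float = 0.0005) -> np.ndarray:
    """Drop tiny opaque/brown connected components (8-connectivity).

    Components smaller than the given fraction of the tooth pixel count
    are reassigned to white_yellow.
    """
    class_map3 = np.asarray(class_map3).copy()
    tooth = _tooth_pixel_count(class_map3, mask)
    if tooth == 0:
        raise ValueError("zero tooth area")
    for code, frac in ((OPAQUE3, min_opaque_frac), (BROWN3, min_brown_frac)):
        labeled = measure.label(class_map3 == code, connectivity=2)
        if labeled.max() == 0:
            continue
        areas = np.bincount(labeled.ravel())
        small = np.flatnonzero(areas < frac * tooth)
        small = small[small != 0]
        if small.size:
            class_map3[np.isin(labeled, small)] = WHITE_YELLOW
    return class_map3


def compute_ratios(class_map3, mask) -> tuple:
    """(r_opaque, r_brown) over tooth pixels.

    tooth = |white_yellow| + |opaque| + |brown| within the mask.
    """
    inside = np.asarray(class_map3)[np.asarray(mask, dtype=bool)]
    counts = np.bincount(inside, minlength=4)
    tooth = int(counts[WHITE_YELLOW] + counts[OPAQUE3] + counts[BROWN3])
    if tooth == 0:
        raise ValueError("zero tooth area")
    return counts[OPAQUE3] / tooth, counts[BROWN3] / tooth


def segment_image(img, prototypes: PrototypeSet,
                  cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Full segmentation chain for one mouth photograph."""
    cfg = cfg or SegmentationConfig()
    cm5 = predict_class_map(img, prototypes, scale_hue=cfg.scale_hue,
                            m_scale=cfg.m_scale)
    raw_mask = cm5 != BACKGROUND
    mask = morphological_cleanup(raw_mask, cfg.opening_radius, cfg.dilation_radius)
    cm5, mask = reclassify_enclosed_background(img, mask, cm5, prototypes,
                                               scale_hue=cfg.scale_hue,
                                               m_scale=cfg.m_scale)
    cm3 = to_three_class(cm5, mask)
    cm3 = remove_small_regions(cm3, mask, cfg.min_opaque_frac, cfg.min_brown_frac)
    r_opaque, r_brown = compute_ratios(cm3, mask)
    return SegmentationResult(
        class_map5=cm5, class_map3=cm3, mask=mask,
        r_opaque=float(r_opaque), r_brown=float(r_brown),
        intermediates={"raw_mask": raw_mask},
    )
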