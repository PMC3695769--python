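"""Semi-quantitative T2-weighted edema analysis.

Myocardial signal on dark-blood T2-weighted images is referenced to
skeletal muscle in the same slice (preferably a large serratus anterior
ROI). A global or regional SI ratio at or above the cutoff (1.9 for
dark-blood triple-inversion-recovery spin echo, locally established values
preferred) indicates edema; a parametric pixel map flags myocardial pixels
with a ratio of 2 or higher. The classification and map cutoffs are kept
as separate parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GeometryError, UnreliableReferenceError
from .geometry import ContourPolygon, rasterize_polygon

T2_RATIO_CUTOFF = 1.9
T2_MAP_CUTOFF = 2.0


@dataclass
class T2RatioResult:
    global_ratio: float
    regional_ratios: dict[str, float]
    cutoff: float
    positive: bool
    cutoff_provenance: str  # "default" | "local"
    sequence_tag: str = ""
    warnings: list[str] = field(default_factory=list)


def _as_mask(
    region: ContourPolygon | np.ndarray,
    shape: tuple[int, int],
    pixel_spacing: tuple[float, float],
) -> np.ndarray:
    if isinstance(region, ContourPolygon):
        return rasterize_polygon(region, shape, pixel_spacing)
    return np.asarray(region, dtype=bool)


def si_ratio(
    image: np.ndarray,
    region_mask: np.ndarray,
    skeletal_roi: ContourPolygon | np.ndarray,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    min_skeletal_pixels: int = 20,
) -> float:
    """Mean-SI ratio of a myocardial region to skeletal muscle."""
    image = np.asarray(image, dtype=float)
    region = np.asarray(region_mask, dtype=bool)
    skel = _as_mask(skeletal_roi, image.shape, pixel_spacing)
    if skel.sum() < min_skeletal_pixels:
        raise UnreliableReferenceError(
            f"skeletal ROI has {int(skel.sum())} pixels, need {min_skeletal_pixels}"
        )
    if not region.any():
        raise GeometryError("empty myocardial region")
    skeletal_mean = float(image[skel].mean())
    if skeletal_mean <= 0:
        raise UnreliableReferenceError("skeletal muscle mean SI is not positive")
    return float(image[region].mean()) / skeletal_mean


def edema_classify(ratio: float, cutoff: float = T2_RATIO_CUTOFF) -> bool:
    """Positive when the ratio is at or above the cutoff (boundary counts)."""
    if not np.isfinite(ratio):
        raise DomainError("ratio must be finite")
    return ratio >= cutoff


def t2_ratio_analysis(
    image: np.ndarray,
    myo_mask: np.ndarray,
    skeletal_roi: ContourPolygon | np.ndarray,
    regional_masks: dict[str, np.ndarray] | None = None,
    cutoff: float = T2_RATIO_CUTOFF,
    cutoff_provenance: str = "default",
    sequence_tag: str = "",
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> T2RatioResult:
    """Global plus optional regional SI-ratio analysis with classification."""
    g = si_ratio(image, myo_mask, skeletal_roi, pixel_spacing)
    regional = {
        name: si_ratio(image, m, skeletal_roi, pixel_spacing)
        for name, m in (regional_masks or {}).items()
    }
    warnings: list[str] = []
    if "surface" in sequence_tag.lower():
        warnings.append(
            "surface-coil acquisition: signal inhomogeneity can bias the ratio; "
            "body coil or a validated correction is expected upstream"
        )
    return T2RatioResult(
        global_ratio=g,
        regional_ratios=regional,
        cutoff=cutoff,
        positive=edema_classify(g, cutoff),
        cutoff_provenance=cutoff_provenance,
        sequence_tag=sequence_tag,
        warnings=warnings,
    )


def ratio_map(
    image: np.ndarray,
    myo_mask: np.ndarray,
    skeletal_mean: float,
    map_cutoff: float = T2_MAP_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel SI ratio over the myocardium and the flagged overlay mask.

    Returns ``(ratio_image, flagged_mask)``; pixels outside the myocardium
    carry NaN in the ratio image and are never flagged.
    """
    if skeletal_mean <= 0:
        raise DomainError("skeletal mean must be positive")
    image = np.asarray(image, dtype=float)
    myo = np.asarray(myo_mask, dtype=bool)
    ratios = np.full(image.shape, np.nan)
    ratios[myo] = image[myo] / skeletal_mean
    flagged = np.zeros(image.shape, dtype=bool)
    flagged[myo] = ratios[myo] >= map_cutoff
    return ratios, flagged
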