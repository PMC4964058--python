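"""ROI definition and aggregation: organs, AHA myocardial segments.

ROI-level R2* follows the reporting convention of the clinical T2*
workflow: the mean T2* over quality-gated pixels is computed first and
the ROI R2* is its inverse (1000 / mean T2*[ms]).  Because 1/mean(x) is
not mean(1/x), the pixelwise-mean R2* is also carried for comparison.

Myocardial segmentation uses the AHA 16-segment model: 6 basal (1-6),
6 mid-ventricular (7-12) and 4 apical (13-16) sectors, assigned by polar
angle about the LV centre, counted counterclockwise from the anterior RV
insertion point (short axis viewed with anterior up); the true apex
(segment 17) is not used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .relaxometry import R2StarMap

LEVEL_SEGMENTS: dict[str, tuple[int, ...]] = {
    "basal": tuple(range(1, 7)),
    "mid": tuple(range(7, 13)),
    "apical": tuple(range(13, 17)),
}


@dataclass
class ROISet:
    """Named boolean masks over one image grid."""

    masks: dict[str, np.ndarray]
    provenance: str = "phantom-truth"  # or "user-supplied"

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("ROI masks must share one image shape")


@dataclass
class SegmentModel:
    """AHA sector masks for one short-axis level."""

    lv_center: tuple[float, float]  # (row, col), pixel-centre coordinates
    rv_insertion_angle: float       # radians, anterior RV insertion
    level: str
    segments: dict[int, np.ndarray]


def aha_segments(myocardium_mask: np.ndarray, lv_center: tuple[float, float],
                 rv_insertion_angle: float, level: str = "mid") -> SegmentModel:
    """Partition a myocardial annulus mask into AHA sectors.

    Pixels are assigned by their polar angle about ``lv_center``; sector
    boundaries are anchored at ``rv_insertion_angle`` (radians, measured
    counterclockwise from the +column axis with anterior up, i.e. image
    rows increase away from anterior).  Basal/mid levels give six 60-deg
    sectors, apical four 90-deg sectors; together the sectors exactly
    partition the input mask.
    """
    if level not in LEVEL_SEGMENTS:
        raise ValueError(f"level must be one of {tuple(LEVEL_SEGMENTS)}")
    mask = np.asarray(myocardium_mask, bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("myocardium mask is empty")
    cy, cx = lv_center
    if not (rows.min() <= cy <= rows.max() and cols.min() <= cx <= cols.max()):
        raise ValueError("lv_center lies outside the mask's bounding box")

    ids = LEVEL_SEGMENTS[level]
    width = 2.0 * np.pi / len(ids)
    # counterclockwise angle in the displayed image (anterior = up = -row)
    theta = np.arctan2(-(rows - cy), cols - cx)
    sector = np.floor(((theta - rv_insertion_angle) % (2.0 * np.pi)) / width).astype(int)
    sector = np.clip(sector, 0, len(ids) - 1)

    segments: dict[int, np.ndarray] = {}
    for k, seg_id in enumerate(ids):
        m = np.zeros_like(mask)
        sel = sector == k
        m[rows[sel], cols[sel]] = True
        segments[seg_id] = m
    return SegmentModel((cy, cx), rv_insertion_angle, level, segments)


@dataclass
class TissueROIStats:
    """Aggregate relaxometry over one ROI.

    ``r2star`` is 1000 / mean T2*; ``r2star_pixelwise`` is the mean of
    per-pixel R2* values (Jensen-gap companion).  ``valid`` is False when
    every pixel in the ROI was gated out.
    """

    tissue: str
    n_pixels_total: int
    n_pixels_used: int
    mean_t2star_ms: float
    r2star: float
    r2star_pixelwise: float
    fraction_gated_out: float
    valid: bool
    subject_id: str = ""
    session: str = ""


def roi_statistics(r2map: R2StarMap, roi_mask: np.ndarray, tissue: str = "",
                   gate_applied: bool = True, subject_id: str = "",
                   session: str = "") -> TissueROIStats:
    """Mean T2* (and its inverse) over the quality-gated pixels of a ROI."""
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    usable = r2map.quality if gate_applied else r2map.valid
    used = roi_mask & usable
    n_total = int(roi_mask.sum())
    n_used = int(used.sum())
    if n_used == 0:
        return TissueROIStats(tissue, n_total, 0, np.nan, np.nan, np.nan, 1.0,
                              False, subject_id, session)
    mean_t2 = float(r2map.t2star_ms[used].mean())
    return TissueROIStats(
        tissue=tissue,
        n_pixels_total=n_total,
        n_pixels_used=n_used,
        mean_t2star_ms=mean_t2,
        r2star=1000.0 / mean_t2,
        r2star_pixelwise=float(r2map.r2star[used].mean()),
        fraction_gated_out=1.0 - n_used / n_total,
        valid=True,
        subject_id=subject_id,
        session=session,
    )


@dataclass
class PanmyocardialResult:
    """Unweighted mean R2* over AHA segments."""

    r2star: float
    n_segments_used: int
    reliable: bool


def panmyocardial_average(segment_stats: Mapping[int, TissueROIStats] | Sequence[TissueROIStats]
                          ) -> PanmyocardialResult:
    """Average segment R2* values (intended over AHA segments 1-16).

    Invalid segments are excluded with a warning; the result is flagged
    unreliable when more than 4 segments are invalid.
    """
    if isinstance(segment_stats, Mapping):
        stats_list = list(segment_stats.values())
    else:
        stats_list = list(segment_stats)
    if not stats_list:
        raise ValueError("no segment statistics supplied")
    valid = [s for s in stats_list if s.valid]
    n_invalid = len(stats_list) - len(valid)
    if n_invalid:
        warnings.warn(f"{n_invalid} invalid segment(s) excluded from the "
                      "panmyocardial average", stacklevel=2)
    if not valid:
        return PanmyocardialResult(np.nan, 0, False)
    value = float(np.mean([s.r2star for s in valid]))
    return PanmyocardialResult(value, len(valid), n_invalid <= 4)


def delta_r2star(pre: TissueROIStats, post: TissueROIStats) -> float:
    """Post-minus-pre ROI R2* change (s^-1) for one tissue of one subject."""
    if pre.tissue != post.tissue:
        raise ValueError(f"tissue mismatch: {pre.tissue!r} vs {post.tissue!r}")
    if pre.subject_id != post.subject_id:
        raise ValueError(f"subject mismatch: {pre.subject_id!r} vs {post.subject_id!r}")
    if not (pre.valid and post.valid):
        return np.nan
    return post.r2star - pre.r2star
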