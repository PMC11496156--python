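"""Subregion protocol and GBZ70-2015 stage aggregation.

The diagnostic workflow grades the profusion of small opacities separately
in six lung zones (right/left x upper/middle/lower) and then maps the six
levels, plus a large-opacity aggregation flag, to a final stage in
{Normal, I, II, III}.  This module provides the geometric subregion
splitter (lung mask -> six tiles), the left/right recombination into the
C1-C3 data cases, and the staging decision table.

The published decision table's count phrases are internally inconsistent
(its Normal row covers only "one subregion" while Stage I asks for "more
than two"); the conventions used here are one consistent, exhaustive and
monotone completion: Stage I needs level >= 1 in at least two zones,
Stage II needs level >= 2 in at least five zones or level 3 in at least
four, Stage III needs level 3 in at least five zones plus aggregation.
Counts are cumulative over higher levels because profusion is ordinal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "ZONES",
    "CASE_OF_ZONE",
    "ProfusionProfile",
    "StageResult",
    "SubregionSet",
    "final_stage",
    "split_subregions",
    "recombine_cases",
    "SegmentationInputError",
    "DegenerateGeometryError",
]

ZONES = ("RU", "RM", "RL", "LU", "LM", "LL")

# left/right rows of the same height are pooled into one data case
CASE_OF_ZONE = {"RU": "C1", "LU": "C1", "RM": "C2", "LM": "C2", "RL": "C3", "LL": "C3"}


class SegmentationInputError(ValueError):
    """Empty or unusable lung mask."""


class DegenerateGeometryError(ValueError):
    """A lung component too small to split into three bands."""


@dataclass
class ProfusionProfile:
    """Six per-zone profusion levels plus the large-opacity aggregation flag."""

    levels: dict
    aggregation: bool = False

    def __post_init__(self):
        if not isinstance(self.levels, dict):
            self.levels = dict(zip(ZONES, self.levels))
        if set(self.levels) != set(ZONES):
            raise ValueError(f"profile must cover zones {ZONES}, got {sorted(self.levels)}")
        for z, lv in self.levels.items():
            if int(lv) not in (0, 1, 2, 3):
                raise ValueError(f"zone {z}: level {lv} outside [0, 3]")
            self.levels[z] = int(lv)

    def as_array(self) -> np.ndarray:
        return np.array([self.levels[z] for z in ZONES], dtype=np.intp)


@dataclass
class StageResult:
    stage: str                 # one of "Normal", "I", "II", "III"
    triggered_rule: str


def final_stage(profile: ProfusionProfile) -> StageResult:
    """Aggregate six subregion levels into the final stage.

    Total and deterministic on {0..3}^6 x {aggregation}; rules are evaluated
    in precedence III -> II -> I -> Normal, so raising any level or setting
    the aggregation flag never lowers the stage.
    """
    lv = profile.as_array()
    c1 = int((lv >= 1).sum())
    c2 = int((lv >= 2).sum())
    c3 = int((lv >= 3).sum())
    if c3 >= 5 and profile.aggregation:
        return StageResult("III", "profusion level 3 in more than four subregions, with opacity aggregation")
    if c2 >= 5:
        return StageResult("II", "profusion level 2 or higher in more than four subregions")
    if c3 >= 4:
        return StageResult("II", "profusion level 3 in four or more subregions")
    if c1 >= 2:
        return StageResult("I", "profusion level 1 or higher in at least two subregions")
    return StageResult("Normal", "no opacities, or opacities in at most one subregion")


@dataclass
class SubregionSet:
    """Six resized zone tiles with their source bounding boxes.

    Boxes are 0-based half-open (row_start, row_end, col_start, col_end) in
    source-image pixel coordinates.
    """

    tiles: dict
    boxes: dict


def _lung_components(mask: np.ndarray):
    """Return (right_mask, left_mask) in radiographic convention.

    The patient's right lung appears on the image left, so the component
    whose centroid has the smaller column index is the right lung.  A single
    component spanning both image halves falls back to a midline split.
    """
    labeled, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationInputError("empty lung mask")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    if n >= 2:
        comps = [(labeled == order[0]), (labeled == order[1])]
    else:
        comp = labeled == 1
        mid = mask.shape[1] // 2
        halves = [comp[:, :mid].any(), comp[:, mid:].any()]
        if not all(halves):
            missing = "left" if not halves[1] else "right"
            raise SegmentationInputError(f"{missing} lung absent from the mask")
        right = comp.copy()
        right[:, mid:] = False
        left = comp.copy()
        left[:, :mid] = False
        comps = [right, left]
    cols = [np.flatnonzero(c.any(axis=0)).mean() for c in comps]
    right, left = (comps[0], comps[1]) if cols[0] < cols[1] else (comps[1], comps[0])
    return right, left


def _split_lung(image: np.ndarray, lung: np.ndarray, side: str, tile_size: int):
    rows = np.flatnonzero(lung.any(axis=1))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    h = r1 - r0
    if h < 3:
        raise DegenerateGeometryError(f"{side} lung component height {h} < 3 pixels")
    tiles, boxes = {}, {}
    for band, letter in enumerate("UML"):
        br0 = r0 + (h * band) // 3
        br1 = r0 + (h * (band + 1)) // 3
        sub = lung[br0:br1]
        cols = np.flatnonzero(sub.any(axis=0))
        if cols.size == 0:
            raise DegenerateGeometryError(f"{side} lung has no mask pixels in band {letter}")
        c0, c1 = int(cols[0]), int(cols[-1]) + 1
        crop = np.where(sub[:, c0:c1], image[br0:br1, c0:c1], 0.0)
        tile = resize(crop.astype(np.float64), (tile_size, tile_size),
                      anti_aliasing=True, preserve_range=True).astype(np.float32)
        zone = ("R" if side == "right" else "L") + letter
        tiles[zone] = tile
        boxes[zone] = (br0, br1, c0, c1)
    return tiles, boxes


def split_subregions(image: np.ndarray, mask: np.ndarray, tile_size: int = 256) -> SubregionSet:
    """Split a chest image into six zone tiles using its binary lung mask.

    Each lung's bounding box is cut into three equal-height bands; each band
    is cropped to the mask's bounding box within it, background outside the
    mask zeroed, and the crop resized to ``tile_size`` squared.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask) > 0
    if image.shape != mask.shape:
        raise SegmentationInputError(
            f"mask shape {mask.shape} does not match image shape {image.shape}")
    right, left = _lung_components(mask)
    tiles, boxes = {}, {}
    for lung, side in ((right, "right"), (left, "left")):
        t, b = _split_lung(image, lung, side, tile_size)
        tiles.update(t)
        boxes.update(b)
    return SubregionSet(tiles=tiles, boxes=boxes)


def recombine_cases(items) -> dict:
    """Pool left/right zone rows into the three data cases C1-C3.

    ``items`` is either a pandas DataFrame with a ``zone`` column (returns a
    dict of sub-frames) or an iterable of ``(zone_id, payload)`` pairs
    (returns a dict of payload lists).  Counts are conserved:
    |C1| + |C2| + |C3| equals the number of input tiles.
    """
    import pandas as pd

    if isinstance(items, pd.DataFrame):
        if "zone" not in items.columns:
            raise ValueError("DataFrame input needs a 'zone' column")
        bad = sorted(set(items["zone"]) - set(ZONES))
        if bad:
            raise ValueError(f"unknown zone ids: {bad}")
        case = items["zone"].map(CASE_OF_ZONE)
        return {c: items[case == c].reset_index(drop=True) for c in ("C1", "C2", "C3")}
    out = {"C1": [], "C2": [], "C3": []}
    for zone, payload in items:
        if zone not in CASE_OF_ZONE:
            raise ValueError(f"unknown zone id: {zone!r}")
        out[CASE_OF_ZONE[zone]].append(payload)
    return out
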