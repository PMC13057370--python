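"""Threshold, refine, watershed-split and filter T-cell regions.

The green-channel 8-bit image is binarized (Otsu by default), the mask is
cleaned (hole filling, light opening, debris removal), touching cells are
separated by a distance-transform watershed, and final regions are filtered
by the circularity >= 0.10 rule and a minimum area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_li, threshold_otsu, threshold_triangle
from skimage.morphology import disk, h_maxima, opening
from skimage.segmentation import watershed

from .preprocess import GrayImage8
from . import morphometry

__all__ = [
    "SegmentationParams",
    "LabelMap",
    "binarize",
    "refine",
    "watershed_split",
    "filter_regions",
    "segment_cells",
]


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation chain.

    threshold_method
        ``"li"`` (default; minimum cross-entropy), ``"otsu"``, ``"triangle"``
        or ``"fixed"`` (uses ``fixed_threshold``).  Li is the default because
        fluorescence fields have sparse foreground (a few percent of pixels)
        spanning a wide brightness range, where Otsu occasionally bisects the
        cell population instead of separating cells from background.
    min_area_px
        Regions below this pixel count are removed; 20 px rejects debris
        specks and small air bubbles without touching real cells.
    min_circularity
        Hard lower bound on Circ; regions below are discarded (default 0.10,
        boundary retained).
    watershed_min_distance_px
        Minimum separation between watershed seed peaks.
    seed_min_depth_px
        Seeds must rise at least this much above their surrounding distance
        landscape (h-maxima suppression); prevents oversplitting irregular
        elongated cells.
    min_contrast_sigma
        Guard for the Otsu path: the threshold must exceed the image median
        by this many robust standard deviations (1.4826 * MAD), otherwise the
        field is treated as signal-free and the mask is empty.  Without it,
        Otsu bisects the noise of an empty field and reports spurious
        foreground.  Set 0 to disable.
    """

    threshold_method: str = "li"
    fixed_threshold: int | None = None
    min_area_px: int = 20
    min_circularity: float = 0.10
    fill_holes: bool = True
    opening_radius_px: int = 1
    watershed_min_distance_px: int = 7
    seed_min_depth_px: float = 2.5
    seed_smoothing_sigma: float = 1.0
    min_contrast_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("li", "otsu", "triangle", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.threshold_method == "fixed":
            if self.fixed_threshold is None:
                raise ValueError("fixed threshold method requires fixed_threshold")
            if not 0 <= self.fixed_threshold <= 255:
                raise ValueError("fixed_threshold must lie in [0, 255]")


@dataclass
class LabelMap:
    """Integer-labelled regions; 0 = background, labels run 1..region_count."""

    labels: np.ndarray
    region_count: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        present = present[present > 0]
        if self.region_count is None:
            self.region_count = int(len(present))
        if len(present) and not np.array_equal(
                present, np.arange(1, len(present) + 1)):
            raise ValueError("labels must be consecutive 1..region_count")
        if len(present) != self.region_count:
            raise ValueError("region_count inconsistent with labels present")


def _as_pixels(gray) -> np.ndarray:
    if isinstance(gray, GrayImage8):
        return gray.pixels
    return np.asarray(gray)


def binarize(gray, params: SegmentationParams) -> tuple:
    """Binary threshold; returns ``(mask, threshold_value)``.

    Foreground = pixels strictly above the threshold.  Otsu on a constant
    image is an error; a fixed threshold must lie in [0, 255] (validated at
    parameter construction).
    """
    img = _as_pixels(gray)
    if params.threshold_method != "fixed":
        if np.unique(img).size < 2:
            raise ValueError(
                "automatic threshold undefined on a constant image")
        fn = {"li": threshold_li, "otsu": threshold_otsu,
              "triangle": threshold_triangle}[params.threshold_method]
        thresh = float(fn(img))
        if params.min_contrast_sigma > 0:
            med = float(np.median(img))
            mad = float(np.median(np.abs(img.astype(np.float64) - med)))
            floor = med + params.min_contrast_sigma * 1.4826 * mad
            if thresh < floor:
                return np.zeros(img.shape, dtype=bool), thresh
    else:
        thresh = float(params.fixed_threshold)
    return img > thresh, thresh


def refine(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Post-threshold refinement: fill holes, open, drop sub-area debris.

    Idempotent: applying it twice equals applying it once.
    """
    out = np.asarray(mask, dtype=bool)
    if params.fill_holes:
        out = ndi.binary_fill_holes(out)
    if params.opening_radius_px > 0:
        out = opening(out, disk(params.opening_radius_px))
        if params.fill_holes:
            out = ndi.binary_fill_holes(out)
    if params.min_area_px > 1:
        comp, n = ndi.label(out)
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes < params.min_area_px)
        out = out & ~np.isin(comp, small[small > 0])
    return out


def watershed_split(mask: np.ndarray, params: SegmentationParams) -> LabelMap:
    """Separate touching cells with a distance-transform watershed.

    The Euclidean distance to background is the topographic surface; seeds
    are its regional maxima after light smoothing, depth suppression
    (``seed_min_depth_px``) and minimum-distance merging.  Ridge-line pixels
    are assigned to background, so the labelled foreground is a subset of the
    input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return LabelMap(np.zeros(mask.shape, dtype=np.int32), 0)

    distance = ndi.distance_transform_edt(mask)
    smoothed = ndi.gaussian_filter(distance, params.seed_smoothing_sigma)
    if params.seed_min_depth_px > 0:
        peaks = h_maxima(smoothed, params.seed_min_depth_px)
    else:
        peaks = smoothed == ndi.maximum_filter(smoothed, size=3)
        peaks &= mask
    # merge seed blobs closer than the minimum seed distance
    merge_r = max(int(params.watershed_min_distance_px) // 2, 1)
    merged = ndi.binary_dilation(peaks, structure=disk(merge_r)) & mask
    markers, n_seeds = ndi.label(merged)
    if n_seeds == 0:
        markers, _ = ndi.label(mask)
    ws = watershed(-distance, markers, mask=mask, watershed_line=True)

    # relabel consecutively in 4-connected components order
    out = np.zeros(mask.shape, dtype=np.int32)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    next_label = 0
    for lab in range(1, ws.max() + 1):
        comp, n_comp = ndi.label(ws == lab, structure=structure)
        for c in range(1, n_comp + 1):
            next_label += 1
            out[comp == c] = next_label
    return LabelMap(out, next_label)


def filter_regions(label_map: LabelMap, features: pd.DataFrame,
                   params: SegmentationParams) -> tuple:
    """Drop regions failing Circ >= min_circularity or Area >= min_area_px.

    ``features`` must come from ``morphometry.measure_all`` on the same label
    map (checked via its ``label`` column).  Survivors are relabelled
    1..k preserving the original label order; returns
    ``(filtered LabelMap, {old_label: new_label})``.
    """
    present = np.unique(label_map.labels)
    present = present[present > 0]
    if "label" not in features.columns or not np.array_equal(
            np.sort(features["label"].to_numpy()), present):
        raise ValueError("feature table does not match the label map")

    keep = features[
        (features["Circ"] >= params.min_circularity)
        & (features["Area"] >= params.min_area_px)
    ]["label"].tolist()
    mapping = {old: new for new, old in enumerate(sorted(keep), start=1)}
    lut = np.zeros(int(label_map.labels.max()) + 1, dtype=np.int32)
    for old, new in mapping.items():
        lut[old] = new
    return LabelMap(lut[label_map.labels], len(mapping)), mapping


def segment_cells(gray, params: SegmentationParams | None = None,
                  pixel_size_um: float | None = None) -> tuple:
    """Full chain: binarize -> refine -> watershed -> measure -> filter.

    Returns ``(LabelMap, FeatureTable, log)`` where the feature table holds
    the surviving regions (relabelled) and the log records the threshold and
    per-stage region counts.
    """
    params = params or SegmentationParams()
    mask, thresh = binarize(gray, params)
    refined = refine(mask, params)
    ws = watershed_split(refined, params)
    feats = morphometry.measure_all(ws.labels, _as_pixels(gray), pixel_size_um)
    filtered, mapping = filter_regions(ws, feats, params)
    feats = feats[feats["label"].isin(mapping)].copy()
    feats["label"] = feats["label"].map(mapping)
    feats = feats.sort_values("label").reset_index(drop=True)
    log = {
        "threshold": thresh,
        "operator_sequence": ["binarize", "refine", "watershed_split",
                              "measure_all", "filter_regions"],
        "regions_after_watershed": ws.region_count,
        "regions_after_filter": filtered.region_count,
    }
    return filtered, feats, log
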