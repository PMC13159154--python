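"""Object segmentation and viability metrics for chip images.

Cells and aggregates are segmented as intensity-thresholded connected
components; viability comes from the two stain masks: the viable area is the
Hoechst (DAPI) mask area minus the dead-stain (TRITC) positive area within
it, and viability% is the viable area normalized to the total stained area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_multiotsu
from skimage.measure import label, regionprops_table
from skimage.segmentation import relabel_sequential

from .imagecore import ChipImage, gaussian_smooth


class DegenerateHistogramError(ValueError):
    """Otsu thresholding on an image without enough distinct gray levels."""


DEFAULT_MIN_AREA_PX = 20
DEFAULT_AGGREGATE_CUTOFF_PX = 200


def otsu_threshold(img: ChipImage, n_classes: int = 2) -> np.ndarray:
    """Otsu threshold(s) maximizing between-class variance (256-bin histogram).

    ``n_classes=2`` returns one threshold, ``n_classes=3`` two ordered
    thresholds. For the three-class rule used on the dead-cell stain, the
    "positive" pixels are the top class (above the second threshold): the
    dead-cell signal is the brightest population and the middle class is
    treated as background haze.
    """
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    pixels = np.asarray(img.pixels)
    if len(np.unique(pixels)) < n_classes:
        raise DegenerateHistogramError(
            f"degenerate histogram: need >= {n_classes} distinct gray levels"
        )
    if n_classes == 2:
        return np.atleast_1d(_otsu_two_class(pixels)).astype(np.float64)
    return threshold_multiotsu(pixels, classes=3, nbins=256).astype(np.float64)


def _otsu_two_class(pixels: np.ndarray, nbins: int = 256) -> float:
    """Two-class Otsu with a plateau-midpoint tie-break.

    Maximizes the between-class variance over a 256-bin histogram; when the
    objective is flat across a run of candidate cuts (e.g. an empty gap
    between two well-separated modes) the middle of the plateau is returned,
    so the threshold lands strictly between the modes rather than at one of
    them.
    """
    hist, edges = np.histogram(pixels.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist.astype(np.float64) / hist.sum()
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mu_t = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (mu_t - m[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)
    vmax = sigma_b.max()
    plateau = np.flatnonzero(sigma_b >= vmax * (1 - 1e-12))
    cut = plateau[len(plateau) // 2]  # cut between bins `cut` and `cut+1`
    return float((centers[cut] + centers[cut + 1]) / 2)


def foreground_mask(img: ChipImage, n_classes: int = 2) -> np.ndarray:
    """Boolean stain-positive mask: 2-class → above threshold; 3-class → top class."""
    t = otsu_threshold(img, n_classes)
    return np.asarray(img.pixels) > t[-1]


def segment_objects(
    img: ChipImage,
    threshold: float,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    intensity_images: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """8-connected components above ``threshold``; small components removed.

    Returns the dense label mask (labels 1..N) and a per-object table with
    area, centroid, eccentricity, solidity, perimeter and — for each entry in
    ``intensity_images`` — sum/mean intensities. Empty results are allowed.
    """
    mask = np.asarray(img.pixels) > threshold
    return segment_mask(mask, min_area_px, intensity_images)


def segment_mask(
    mask: np.ndarray,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    intensity_images: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label a boolean mask (8-connectivity), drop components < ``min_area_px``."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = label(mask, connectivity=2, return_num=True)
    if n and min_area_px > 1:
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        keep = areas >= min_area_px
        keep[0] = False
        labels[~keep[labels]] = 0
        labels, _, _ = relabel_sequential(labels)
        n = int(labels.max())
    if n == 0:
        cols = ["object_id", "area_px", "centroid_x", "centroid_y",
                "eccentricity", "solidity", "perimeter"]
        return labels, pd.DataFrame(columns=cols)
    props = regionprops_table(
        labels,
        properties=("label", "area", "centroid", "eccentricity", "solidity", "perimeter"),
    )
    table = pd.DataFrame(
        {
            "object_id": props["label"],
            "area_px": props["area"].astype(int),
            "centroid_x": props["centroid-1"],
            "centroid_y": props["centroid-0"],
            "eccentricity": props["eccentricity"],
            "solidity": props["solidity"],
            "perimeter": props["perimeter"],
        }
    )
    for name, intensity in (intensity_images or {}).items():
        intensity = np.asarray(intensity, dtype=np.float64)
        sums = np.bincount(labels.ravel(), weights=intensity.ravel(), minlength=n + 1)[1:]
        table[f"sum_intensity_{name}"] = sums
        table[f"mean_intensity_{name}"] = sums / table["area_px"].to_numpy()
    return labels, table


def classify_objects(
    objects: pd.DataFrame, aggregate_area_cutoff_px: int = DEFAULT_AGGREGATE_CUTOFF_PX
) -> tuple[pd.DataFrame, float]:
    """Label each object single-cell vs aggregate by an area cutoff.

    An object is an aggregate iff ``area_px >= cutoff`` (ties count as
    aggregates). Returns the table with a ``class`` column plus the
    percentage of aggregates (NaN when there are no objects).
    """
    out = objects.copy()
    if not len(out):
        out["class"] = pd.Series(dtype=object)
        return out, float("nan")
    is_agg = out["area_px"].to_numpy() >= aggregate_area_cutoff_px
    out["class"] = np.where(is_agg, "aggregate", "single_cell")
    return out, 100.0 * float(is_agg.sum()) / len(out)


@dataclass
class ViabilityResult:
    viable_area: int
    dead_area: int
    total_area: int
    viability_pct: float
    viable_to_total_ratio: float
    defined: bool = True


def compute_viability(hoechst_mask: np.ndarray, ethd2_mask: np.ndarray) -> ViabilityResult:
    """Viable area and viability% from the two stain masks.

    Dead pixels are counted only inside the all-cells (Hoechst) mask:
    ``viable = |hoechst| − |ethd2 ∩ hoechst|``;
    ``viability% = 100 · viable / |hoechst|``. A chip with an empty Hoechst
    mask has undefined viability — flagged via ``defined=False`` rather than
    silently propagating NaN arithmetic.
    """
    hoechst_mask = np.asarray(hoechst_mask, dtype=bool)
    ethd2_mask = np.asarray(ethd2_mask, dtype=bool)
    if hoechst_mask.shape != ethd2_mask.shape:
        raise ValueError("masks must share one shape")
    total = int(hoechst_mask.sum())
    dead = int((ethd2_mask & hoechst_mask).sum())
    viable = total - dead
    if total == 0:
        return ViabilityResult(0, 0, 0, float("nan"), float("nan"), defined=False)
    pct = 100.0 * viable / total
    return ViabilityResult(viable, dead, total, pct, pct, defined=True)


@dataclass
class ChipFeatures:
    """Per-chip aggregated features for one timepoint."""

    chip_id: str
    day: int
    dose: float
    n_objects: int = 0
    pct_aggregates: float = float("nan")
    mean_object_area: float = float("nan")
    sum_object_area: int = 0
    hoechst_mask_area: int = 0
    ethd2_mask_area_within: int = 0
    viable_area: int = 0
    viability_pct: float = float("nan")
    normalized_viable_area: float = float("nan")  # filled against vehicle later
    viable_to_total_ratio: float = float("nan")
    atp_signal: float = float("nan")
    qc: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SegmentationParams:
    min_area_px: int = DEFAULT_MIN_AREA_PX
    aggregate_cutoff_px: int = DEFAULT_AGGREGATE_CUTOFF_PX
    smooth_sigma_px: float = 1.0
    hoechst_threshold: float | None = None  # None → 2-class Otsu


def chip_features(
    dapi: ChipImage,
    tritc: ChipImage,
    dose: float = 0.0,
    params: SegmentationParams | None = None,
) -> ChipFeatures:
    """Assemble the full per-chip feature record from the two stain channels.

    Hoechst foreground by 2-class Otsu (or a fixed threshold when given);
    dead-stain foreground by 3-class Otsu top class; objects are 8-connected
    components of the Hoechst mask. ``normalized_viable_area`` is computed
    later against the vehicle-control mean (see assaystats).
    """
    params = params or SegmentationParams()
    feats = ChipFeatures(chip_id=dapi.chip_id, day=dapi.day, dose=dose)
    qc = []

    dapi_s = gaussian_smooth(dapi, params.smooth_sigma_px)
    tritc_s = gaussian_smooth(tritc, params.smooth_sigma_px)
    try:
        if params.hoechst_threshold is not None:
            hoechst_mask = dapi_s.pixels > params.hoechst_threshold
        else:
            hoechst_mask = foreground_mask(dapi_s, n_classes=2)
    except DegenerateHistogramError:
        hoechst_mask = np.zeros(dapi.shape, dtype=bool)
        qc.append("dapi_degenerate")
    try:
        ethd2_mask = foreground_mask(tritc_s, n_classes=3)
    except DegenerateHistogramError:
        ethd2_mask = np.zeros(tritc.shape, dtype=bool)
        qc.append("tritc_degenerate")

    labels, objects = segment_mask(
        hoechst_mask, params.min_area_px, {"dapi": dapi.astype_float()}
    )
    hoechst_mask = labels > 0  # after artifact removal
    ethd2_mask = ethd2_mask & hoechst_mask
    objects, pct_agg = classify_objects(objects, params.aggregate_cutoff_px)

    feats.n_objects = len(objects)
    feats.pct_aggregates = pct_agg
    if len(objects):
        feats.mean_object_area = float(objects["area_px"].mean())
        feats.sum_object_area = int(objects["area_px"].sum())
    viab = compute_viability(hoechst_mask, ethd2_mask)
    feats.hoechst_mask_area = viab.total_area
    feats.ethd2_mask_area_within = viab.dead_area
    feats.viable_area = viab.viable_area
    feats.viability_pct = viab.viability_pct
    feats.viable_to_total_ratio = viab.viable_to_total_ratio
    if not viab.defined:
        qc.append("empty_hoechst_mask")
    feats.qc = ";".join(qc)
    return feats


def features_table(feature_list: list[ChipFeatures]) -> pd.DataFrame:
    """Stack per-chip features into one table (one row per chip/timepoint)."""
    return pd.DataFrame([f.to_dict() for f in feature_list])
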