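"""Spheroid-wise fluorescence quantification and fidelity analysis.

Measures per-object intensity statistics under a segmentation mask and asks
whether a restored projection carries the same quantitative information as
the ground-truth projection: per-spheroid intensities from the two images,
paired by mask identity, should fall on the identity line of a log-scale
scatter (slope 1, high R^2).  Also aggregates treatment time-courses of mean
spheroid fluorescence with the small-object area filter used to exclude
debris (default 1200 um^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .training import log_transform

__all__ = ["SpheroidRecord", "FidelityFit", "segment_objects", "filter_labels",
           "measure_objects", "fidelity_regression", "timecourse",
           "DEFAULT_MIN_AREA"]

DEFAULT_MIN_AREA = 1200.0  # um^2, debris-exclusion threshold


@dataclass
class SpheroidRecord:
    label: int
    area: float                 # um^2
    mean_intensity: float       # ADU/s
    sum_log_intensity: float    # sum of log-domain pixel values in the mask


@dataclass
class FidelityFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def segment_objects(image: np.ndarray, threshold: Optional[float] = None,
                    min_area: float = DEFAULT_MIN_AREA,
                    pixel_size: float = 1.39) -> np.ndarray:
    """Threshold + 8-connected components + area filter -> labeled mask.

    ``threshold`` defaults to Otsu's value.  Components smaller than
    ``min_area`` (um^2) are dropped; survivors are relabeled 1..n ordered by
    descending area, ties broken by the first (row-major) pixel.
    """
    image = np.asarray(image, float)
    if image.size == 0:
        raise ValueError("empty image")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if threshold is None:
        threshold = float(threshold_otsu(image))
    labeled = cc_label(image > threshold, connectivity=2)
    return _filter_and_order(labeled, min_area, pixel_size)


def filter_labels(labeled: np.ndarray, min_area: float = DEFAULT_MIN_AREA,
                  pixel_size: float = 1.39) -> np.ndarray:
    """Area-filter and canonically relabel an existing labeled mask.

    Used when the mask comes from elsewhere (e.g. a ground-truth phantom
    mask) rather than from :func:`segment_objects`.
    """
    return _filter_and_order(np.asarray(labeled), min_area, pixel_size)


def _filter_and_order(labeled: np.ndarray, min_area: float,
                      pixel_size: float) -> np.ndarray:
    area_per_px = pixel_size**2
    keep = []
    for region in regionprops(labeled):
        area = region.num_pixels * area_per_px
        if area >= min_area:
            first_pixel = tuple(region.coords[0])
            keep.append((-area, first_pixel, region.label))
    keep.sort()
    out = np.zeros_like(labeled, dtype=np.int32)
    for new_label, (_, _, old_label) in enumerate(keep, start=1):
        out[labeled == old_label] = new_label
    return out


def measure_objects(labeled: np.ndarray, intensity: np.ndarray,
                    pixel_size: float = 1.39,
                    log_offset: float = 1.0,
                    labels: Optional[Sequence[int]] = None) -> List[SpheroidRecord]:
    """Per-object area, mean linear intensity and summed log intensity."""
    labeled = np.asarray(labeled)
    intensity = np.asarray(intensity, float)
    if labeled.shape != intensity.shape:
        raise ValueError("mask and image must share shape")
    present = set(np.unique(labeled)) - {0}
    wanted = sorted(present) if labels is None else list(labels)
    log_img = log_transform(intensity, log_offset)
    records = []
    for lab in wanted:
        if lab not in present:
            raise ValueError(f"label {lab} absent from mask")
        mask = labeled == lab
        records.append(SpheroidRecord(
            label=int(lab),
            area=float(mask.sum()) * pixel_size**2,
            mean_intensity=float(intensity[mask].mean()),
            sum_log_intensity=float(log_img[mask].sum()),
        ))
    return records


def fidelity_regression(x: Sequence[float], y: Sequence[float],
                        log_scale: bool = True) -> FidelityFit:
    """OLS of comparison values against reference values on the log scale.

    x, y are per-object statistics paired by object identity (x from the
    reference projection, y from the image under test).  Natural log is
    applied to both when ``log_scale``.  Identity (y = x) gives slope 1,
    intercept 0, R^2 = 1; a constant multiplicative bias appears as a nonzero
    intercept.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 paired objects")
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-scale regression requires positive values")
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return FidelityFit(slope=float(fit.slope), intercept=float(fit.intercept),
                       r_squared=float(fit.rvalue**2), n_points=int(x.size))


def timecourse(records: Iterable[dict]) -> pd.DataFrame:
    """Mean +/- standard error of spheroid intensity per day and condition.

    Each record needs keys {day, condition, image, value}.  Objects are first
    averaged within an image; images are then the replication unit: per
    (day, condition) cell the table reports the mean over images and the
    standard error (NaN when a single image).
    """
    df = pd.DataFrame(list(records))
    required = {"day", "condition", "image", "value"}
    if df.empty or not required.issubset(df.columns):
        raise ValueError(f"records need fields {sorted(required)}")
    per_image = (df.groupby(["day", "condition", "image"])["value"]
                   .mean().reset_index())
    out = (per_image.groupby(["day", "condition"])["value"]
           .agg(mean="mean", sem=lambda v: v.sem(ddof=1), n_images="count")
           .reset_index())
    return out
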