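"""Region-level intensity quantification.

Mean-grey optical density of immunostained regions, thresholded
stained-surface ratio of chromogen (DAB) sections, percent-of-control
normalisation, and ROI averaging of elemental concentration maps.

The chromogen "surface" measure is single-channel: a pixel is stain-positive
when its intensity is at or above a threshold that is chosen once per stain
and reused across all images of a study (store it in the analysis config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ElementalMap

__all__ = [
    "RegionMeasure",
    "mean_grey",
    "surface_fraction",
    "percent_of_control",
    "roi_mean_concentration",
]


@dataclass
class RegionMeasure:
    """One region-level measurement."""

    region: str
    value: float
    kind: str  # "mean_grey" | "surface_ratio" | "mean_ppm"
    n_pixels: int


def _roi_values(image: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if image.shape != roi_mask.shape:
        raise ValueError("image and ROI mask shapes differ")
    values = image[roi_mask]
    if values.size == 0:
        raise ValueError("empty ROI")
    return values


def mean_grey(image: np.ndarray, roi_mask: np.ndarray,
              region: str = "roi") -> RegionMeasure:
    """Arithmetic mean intensity within the ROI (optical-density readout)."""
    values = _roi_values(image, roi_mask)
    return RegionMeasure(region=region, value=float(values.mean()),
                         kind="mean_grey", n_pixels=values.size)


def surface_fraction(image: np.ndarray, roi_mask: np.ndarray,
                     threshold: float, region: str = "roi") -> RegionMeasure:
    """Fraction of ROI pixels at or above the stain-positive threshold."""
    values = _roi_values(image, roi_mask)
    frac = float(np.count_nonzero(values >= threshold)) / values.size
    return RegionMeasure(region=region, value=frac,
                         kind="surface_ratio", n_pixels=values.size)


def percent_of_control(values: np.ndarray,
                       control_values: np.ndarray) -> np.ndarray:
    """Express each value as a percentage of the control-group mean."""
    control_values = np.asarray(control_values, dtype=float)
    ctrl_mean = control_values.mean()
    if ctrl_mean == 0:
        raise ValueError("control mean is zero; percent-of-control undefined")
    return 100.0 * np.asarray(values, dtype=float) / ctrl_mean


def roi_mean_concentration(emap: ElementalMap,
                           roi_mask: np.ndarray | None = None,
                           region: str = "roi") -> RegionMeasure:
    """Mean elemental concentration (ppm) over an ROI (whole map by default)."""
    if roi_mask is None:
        roi_mask = np.ones(emap.grid.shape, dtype=bool)
    values = _roi_values(emap.grid, roi_mask)
    return RegionMeasure(region=region, value=float(values.mean()),
                         kind="mean_ppm", n_pixels=values.size)
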