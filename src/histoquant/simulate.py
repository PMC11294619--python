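"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here: single-neuron
two-channel images with catalogued puncta, 3-D neuron fields sliced into
serial sections, chromogen (DAB-like) images with a known stained-surface
fraction, elemental concentration maps, and two-group measurement tables with
a specified true mean difference. The catalogue returned alongside each
artefact is the oracle against which the pipeline is validated.

All randomness flows from a single explicit integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import (
    AnnotatedImage,
    ElementalMap,
    GroundTruth,
    PunctumTruth,
    Section,
    SectionSeries,
)
from .exceptions import PlacementError

__all__ = [
    "CellImageParams",
    "generate_cell_image",
    "generate_neuron_field",
    "generate_dab_image",
    "generate_elemental_map",
    "generate_group_table",
]

# retries per punctum before declaring the geometry infeasible
_MAX_RETRIES = 1000
# minimum centre-to-centre spacing, in punctum radii, so noiseless detection
# never merges neighbouring spots
_MIN_SEPARATION_RADII = 2.5


def _ellipse_mask(shape: tuple[int, int], centre_px: tuple[float, float],
                  semi_axes_px: tuple[float, float]) -> np.ndarray:
    """Rasterise an axis-aligned ellipse, membership tested at pixel centres."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dy = (rr + 0.5) - centre_px[0]
    dx = (cc + 0.5) - centre_px[1]
    a, b = semi_axes_px
    return (dy / a) ** 2 + (dx / b) ** 2 <= 1.0


@dataclass
class CellImageParams:
    """Geometry, intensity and noise settings for one synthetic neuron image.

    The soma and nucleus are axis-aligned ellipses given in pixel units
    (centre, semi-axes along rows/cols). Puncta are isotropic Gaussian spots
    (σ = radius/2, truncated at 3σ) of amplitude ``punctum_intensity`` above a
    flat ``background_level``. Noise follows the standard fluorescence camera
    model: optional Poisson resampling of the signal, then additive Gaussian
    read noise.

    Defaults describe a macaque-scale dopaminergic soma (~30×24 µm) with a
    ~10×8 µm nucleus imaged at 0.2 µm/px, and lysosome-sized puncta
    (radius 0.4 µm).
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.2
    soma_centre_px: tuple[float, float] = (128.0, 128.0)
    soma_semi_axes_px: tuple[float, float] = (75.0, 60.0)
    nucleus_centre_px: tuple[float, float] = (128.0, 128.0)
    nucleus_semi_axes_px: tuple[float, float] = (25.0, 20.0)
    n_perinuclear: int = 10
    n_cytosolic: int = 5
    punctum_radius_um: float = 0.4
    punctum_intensity: float = 200.0
    background_level: float = 50.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    perinuclear_band_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perinuclear < 0 or self.n_cytosolic < 0:
            raise ValueError("puncta counts must be non-negative")
        if self.punctum_radius_um <= 0:
            raise ValueError("punctum_radius_um must be positive")
        if self.perinuclear_band_um <= 0:
            raise ValueError("perinuclear_band_um must be positive")
        if self.punctum_radius_um >= self.perinuclear_band_um:
            raise ValueError(
                "punctum_radius_um must be smaller than perinuclear_band_um "
                "so perinuclear spots fit inside the band"
            )
        if self.background_level < 0 or self.gaussian_noise_sd < 0:
            raise ValueError("background_level and gaussian_noise_sd must be >= 0")
        if self.punctum_intensity <= self.background_level:
            raise ValueError("punctum_intensity must exceed background_level")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Rasterise the soma and nucleus masks; nucleus must sit strictly inside."""
        soma = _ellipse_mask(self.image_size_px, self.soma_centre_px,
                             self.soma_semi_axes_px)
        nucleus = _ellipse_mask(self.image_size_px, self.nucleus_centre_px,
                                self.nucleus_semi_axes_px)
        interior = ndimage.binary_erosion(soma)
        if not nucleus.any() or np.any(nucleus & ~interior):
            raise ValueError("nucleus ellipse must lie strictly inside the soma")
        return soma, nucleus


def _render_spot(image: np.ndarray, centre_px: tuple[float, float],
                 sigma_px: float, amplitude: float) -> None:
    """Add a truncated (3σ) isotropic Gaussian spot in place."""
    r0, c0 = centre_px
    rad = 3.0 * sigma_px
    rmin = max(int(math.floor(r0 - rad)), 0)
    rmax = min(int(math.ceil(r0 + rad)) + 1, image.shape[0])
    cmin = max(int(math.floor(c0 - rad)), 0)
    cmax = min(int(math.ceil(c0 + rad)) + 1, image.shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    d2 = ((rr + 0.5) - r0) ** 2 + ((cc + 0.5) - c0) ** 2
    spot = amplitude * np.exp(-d2 / (2.0 * sigma_px**2))
    spot[d2 > rad**2] = 0.0
    image[rmin:rmax, cmin:cmax] += spot


def _apply_noise(signal: np.ndarray, rng: np.random.Generator,
                 poisson: bool, gauss_sd: float) -> np.ndarray:
    out = signal
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if gauss_sd > 0:
        out = out + rng.normal(0.0, gauss_sd, size=out.shape)
    return out


def generate_cell_image(params: CellImageParams) -> tuple[AnnotatedImage, GroundTruth]:
    """Generate one two-channel neuron image plus its punctum catalogue.

    The ``cell`` channel fills the soma (segmentation marker); the ``puncta``
    channel carries the catalogued spots. Perinuclear puncta centres lie
    within ``perinuclear_band_um`` of the nucleus border, cytosolic centres
    farther than that band but inside the soma, and every centre keeps one
    punctum radius clear of the soma border so no spot is clipped.

    Raises
    ------
    PlacementError
        If rejection sampling cannot place a punctum after bounded retries.
    """
    soma, nucleus = params.masks()
    px = params.pixel_size_um
    rng = np.random.default_rng(params.seed)

    cytoplasm = soma & ~nucleus
    dist_nucleus_um = ndimage.distance_transform_edt(~nucleus) * px
    dist_outside_um = ndimage.distance_transform_edt(soma) * px
    interior = cytoplasm & (dist_outside_um > params.punctum_radius_um)
    peri_zone = interior & (dist_nucleus_um <= params.perinuclear_band_um)
    cyto_zone = interior & (dist_nucleus_um > params.perinuclear_band_um)

    min_sep = _MIN_SEPARATION_RADII * params.punctum_radius_um
    placed: list[tuple[float, float]] = []
    catalog: list[PunctumTruth] = []

    for compartment, zone, n in (("perinuclear", peri_zone, params.n_perinuclear),
                                 ("cytosolic", cyto_zone, params.n_cytosolic)):
        if n == 0:
            continue
        cand = np.argwhere(zone)
        if cand.size == 0:
            raise PlacementError(compartment, 0, n)
        for k in range(n):
            for _ in range(_MAX_RETRIES):
                i, j = cand[rng.integers(len(cand))]
                centre = ((i + 0.5) * px, (j + 0.5) * px)
                if all(math.hypot(centre[0] - p[0], centre[1] - p[1]) >= min_sep
                       for p in placed):
                    placed.append(centre)
                    catalog.append(PunctumTruth(centre_um=centre,
                                                radius_um=params.punctum_radius_um,
                                                compartment=compartment))
                    break
            else:
                raise PlacementError(compartment, k, n)

    sigma_px = (params.punctum_radius_um / 2.0) / px
    amplitude = params.punctum_intensity - params.background_level
    puncta_ch = np.full(params.image_size_px, params.background_level, dtype=float)
    for p in catalog:
        _render_spot(puncta_ch, (p.centre_um[0] / px, p.centre_um[1] / px),
                     sigma_px, amplitude)
    cell_ch = np.where(soma, params.punctum_intensity, params.background_level)

    puncta_ch = _apply_noise(puncta_ch, rng, params.poisson_noise,
                             params.gaussian_noise_sd)
    cell_ch = _apply_noise(cell_ch, rng, params.poisson_noise,
                           params.gaussian_noise_sd)

    image = AnnotatedImage(channels={"cell": cell_ch, "puncta": puncta_ch},
                           pixel_size_um=px, soma_mask=soma, nucleus_mask=nucleus)
    return image, GroundTruth(puncta_catalog=catalog)


def generate_neuron_field(region_size_um: tuple[float, float, float] = (6000.0, 4000.0, 3000.0),
                          n_neurons: int = 12000,
                          section_thickness_um: float = 50.0,
                          section_period: int = 12,
                          seed: int = 0) -> tuple[SectionSeries, GroundTruth]:
    """Place neurons uniformly in a 3-D region and slice into serial sections.

    Each neuron is reduced to a single reference point (the nucleolus proxy
    enforced by counting only cells whose nucleus falls in the probe) and is
    assigned to exactly one section — the one containing its z coordinate.
    Every ``section_period``-th section, starting from a seed-drawn random
    phase, is flagged as sampled (systematic 1-in-k series).
    """
    if any(d <= 0 for d in region_size_um):
        raise ValueError("region dimensions must be positive")
    if n_neurons < 0:
        raise ValueError("n_neurons must be non-negative")
    if section_period < 1:
        raise ValueError("section_period must be >= 1")
    if section_thickness_um <= 0:
        raise ValueError("section_thickness_um must be positive")

    lx, ly, lz = region_size_um
    n_sections = int(math.ceil(lz / section_thickness_um - 1e-9))
    rng = np.random.default_rng(seed)
    phase = int(rng.integers(section_period))
    pts = rng.uniform(0.0, 1.0, size=(n_neurons, 3)) * np.array([lx, ly, lz])
    sec_idx = np.minimum((pts[:, 2] // section_thickness_um).astype(int),
                         n_sections - 1)

    sections = []
    for i in range(n_sections):
        in_sec = pts[sec_idx == i, :2]
        sections.append(Section(index=i, sampled=(i % section_period == phase),
                                points_um=in_sec))
    series = SectionSeries(sections=sections, thickness_um=section_thickness_um,
                           region_size_um=(lx, ly), section_period=section_period)
    return series, GroundTruth(true_neuron_count=n_neurons)


def generate_dab_image(size_px: tuple[int, int] = (256, 256),
                       surface_fraction: float = 0.3,
                       stain_level: float = 150.0,
                       background_level: float = 20.0,
                       noise_sd: float = 0.0,
                       seed: int = 0,
                       blob_radius_px: tuple[float, float] = (4.0, 16.0),
                       ) -> tuple[np.ndarray, GroundTruth]:
    """Generate a chromogen-stained image with a known stained-surface fraction.

    Random discs are unioned until the stained pixel count reaches
    ``round(surface_fraction * n_pixels)``; the last disc is trimmed
    (outermost pixels first) so the achieved fraction is exact at the pixel
    level. The achieved fraction is recorded as ``true_surface_fraction``.
    """
    if not 0.0 <= surface_fraction <= 1.0:
        raise ValueError("surface_fraction must be in [0, 1]")
    h, w = size_px
    n_px = h * w
    target = int(round(surface_fraction * n_px))
    rng = np.random.default_rng(seed)
    stained = np.zeros((h, w), dtype=bool)
    count = 0
    while count < target:
        r = rng.uniform(*blob_radius_px)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rmin, rmax = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
        cmin, cmax = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
        rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
        d2 = ((rr + 0.5) - cy) ** 2 + ((cc + 0.5) - cx) ** 2
        new = (d2 <= r * r) & ~stained[rmin:rmax, cmin:cmax]
        n_new = int(new.sum())
        if count + n_new <= target:
            stained[rmin:rmax, cmin:cmax] |= new
            count += n_new
        else:
            # trim the disc from the rim inward to land exactly on target
            keep = target - count
            order = np.argsort(d2[new])[:keep]
            ii, jj = np.nonzero(new)
            stained[rmin + ii[order], cmin + jj[order]] = True
            count = target

    image = np.where(stained, stain_level, background_level).astype(float)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    truth = GroundTruth(true_surface_fraction=count / n_px,
                        target_surface_fraction=surface_fraction)
    return image, truth


def generate_elemental_map(grid_shape: tuple[int, int] = (100, 100),
                           step_um: float = 5.0,
                           mean_ppm: float = 150.0,
                           sd_ppm: float = 10.0,
                           seed: int = 0,
                           element: str = "Fe") -> ElementalMap:
    """Generate a per-pixel concentration map around ``mean_ppm`` (clipped at 0).

    Default geometry is a 100×100 grid at 5 µm step — a 500×500 µm field.
    """
    if mean_ppm < 0:
        raise ValueError("mean_ppm must be non-negative")
    if sd_ppm < 0:
        raise ValueError("sd_ppm must be non-negative")
    rng = np.random.default_rng(seed)
    grid = np.clip(rng.normal(mean_ppm, sd_ppm, size=grid_shape), 0.0, None)
    return ElementalMap(element=element, grid=grid, step_um=step_um)


def generate_group_table(n_control: int = 6, n_test: int = 4,
                         control_mean: float = 100.0, effect: float = -30.0,
                         sd: float = 8.0, seed: int = 0,
                         variable: str = "measure",
                         control_label: str = "control",
                         test_label: str = "test",
                         ) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a two-group per-hemisphere measurement table.

    Values are normal with means ``control_mean`` and ``control_mean + effect``
    and common standard deviation ``sd``; one row per hemisphere with columns
    ``group, hemisphere, variable, value``.
    """
    if n_control < 2 or n_test < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    ctrl = rng.normal(control_mean, sd, size=n_control)
    test = rng.normal(control_mean + effect, sd, size=n_test)
    rows = [{"group": control_label, "hemisphere": f"ctrl_h{i + 1}",
             "variable": variable, "value": v} for i, v in enumerate(ctrl)]
    rows += [{"group": test_label, "hemisphere": f"test_h{i + 1}",
              "variable": variable, "value": v} for i, v in enumerate(test)]
    return pd.DataFrame(rows), GroundTruth(true_mean_difference=effect)
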