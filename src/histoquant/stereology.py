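"""Optical-fractionator estimation of total neuron number.

Counting frames of known area are laid out on a systematic grid with a
uniform-random offset per section (systematic uniform random sampling), cells
are counted with the unbiased-counting-frame rule (inclusion on the top and
right edges, exclusion on the left and bottom edges and their extensions),
and the total is estimated as

    N̂ = ΣQ⁻ / (ssf · asf · tsf)

where ssf = 1/section_period is the section sampling fraction, asf the
area sampling fraction (frame area / grid cell area) and tsf the thickness
sampling fraction (1 by default: planar counting with no guard zones).

Default design: 100×80 µm frames spaced 600×400 µm on a 1-in-12 section
series, giving asf = 1/30 and an overall multiplier of 360 per counted cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import SectionSeries

__all__ = [
    "StereologyDesign",
    "StereologyEstimate",
    "Frame",
    "place_sampling_grid",
    "count_frame",
    "fractionator_estimate",
    "run_stereology",
]


@dataclass(frozen=True)
class Frame:
    """One counting frame: origin (x0, y0) and size (w, h), all in µm."""

    x0: float
    y0: float
    w: float
    h: float


@dataclass
class StereologyDesign:
    """Sampling-fraction bundle of the fractionator design."""

    frame_w_um: float = 100.0
    frame_h_um: float = 80.0
    grid_dx_um: float = 600.0
    grid_dy_um: float = 400.0
    section_period: int = 12
    tsf: float = 1.0

    def __post_init__(self) -> None:
        if min(self.frame_w_um, self.frame_h_um) <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.grid_dx_um < self.frame_w_um or self.grid_dy_um < self.frame_h_um:
            raise ValueError("grid spacing must be at least the frame size")
        if self.section_period < 1:
            raise ValueError("section_period must be >= 1")
        if not 0 < self.tsf <= 1:
            raise ValueError("tsf must be in (0, 1]")

    @property
    def asf(self) -> float:
        """Area sampling fraction: frame area over grid cell area."""
        return (self.frame_w_um * self.frame_h_um) / (self.grid_dx_um * self.grid_dy_um)

    @property
    def ssf(self) -> float:
        """Section sampling fraction."""
        return 1.0 / self.section_period


@dataclass
class StereologyEstimate:
    """Fractionator output: raw count, total estimate, per-section breakdown."""

    sum_Q: int
    n_hat: float
    per_section_counts: list[int] = field(default_factory=list)


def place_sampling_grid(region_bounds_um: tuple[float, float, float, float],
                        design: StereologyDesign,
                        offset_um: tuple[float, float]) -> list[Frame]:
    """Lay counting frames on a systematic grid over a rectangular region.

    ``region_bounds_um`` is ``(xmin, ymin, xmax, ymax)``. Frames sit at
    ``(xmin + offset_x + i·dx, ymin + offset_y + j·dy)`` for every origin
    inside the bounds; the offset should be drawn uniformly in one grid cell
    (``[0, dx) × [0, dy)``) for systematic uniform random sampling. Frames
    whose origin is inside the region may extend past its far edges; the
    region delineation is assumed to contain all countable cells, so the
    overhang is empty.
    """
    xmin, ymin, xmax, ymax = region_bounds_um
    if xmax - xmin < design.frame_w_um or ymax - ymin < design.frame_h_um:
        raise ValueError("region smaller than one counting frame")
    ox, oy = offset_um
    frames = []
    y = ymin + oy
    while y < ymax:
        x = xmin + ox
        while x < xmax:
            frames.append(Frame(x, y, design.frame_w_um, design.frame_h_um))
            x += design.grid_dx_um
        y += design.grid_dy_um
    return frames


def count_frame(points_um: np.ndarray, frame: Frame) -> int:
    """Count points in one unbiased counting frame.

    A point is counted when it lies strictly right of the left edge and
    strictly above the bottom edge, up to and including the right and top
    edges: ``x0 < x <= x0 + w`` and ``y0 < y <= y0 + h``. Abutting frames
    therefore count every point exactly once.
    """
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        return 0
    x, y = pts[:, 0], pts[:, 1]
    return int(np.count_nonzero((x > frame.x0) & (x <= frame.x0 + frame.w)
                                & (y > frame.y0) & (y <= frame.y0 + frame.h)))


def fractionator_estimate(sum_Q: int, design: StereologyDesign) -> StereologyEstimate:
    """Scale the raw count by the inverse sampling fractions."""
    if sum_Q < 0:
        raise ValueError("sum_Q must be non-negative")
    f = design.ssf * design.asf * design.tsf
    if f <= 0:
        raise ValueError("total sampling fraction must be positive")
    return StereologyEstimate(sum_Q=int(sum_Q), n_hat=sum_Q / f)


def run_stereology(series: SectionSeries, design: StereologyDesign | None = None,
                   seed: int = 0) -> StereologyEstimate:
    """Run the fractionator over the sampled sections of a series.

    An independent uniform-random grid offset is drawn per sampled section;
    counts are accumulated over the sampled sections only and scaled by the
    design's sampling fractions.
    """
    design = design or StereologyDesign()
    sampled = series.sampled_sections
    if not sampled:
        raise ValueError("series has no sampled sections")
    rng = np.random.default_rng(seed)
    bounds = (0.0, 0.0, series.region_size_um[0], series.region_size_um[1])
    per_section = []
    for section in sampled:
        offset = (rng.uniform(0.0, design.grid_dx_um),
                  rng.uniform(0.0, design.grid_dy_um))
        frames = place_sampling_grid(bounds, design, offset)
        per_section.append(sum(count_frame(section.points_um, fr) for fr in frames))
    est = fractionator_estimate(int(np.sum(per_section)), design)
    est.per_section_counts = per_section
    return est
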