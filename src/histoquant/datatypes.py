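"""Core in-memory containers shared by the generators and the analysis modules.

Conventions
-----------
* Images are 2-D ``float64`` arrays indexed ``(row, col)``; masks are boolean
  arrays of the same shape.
* Pixel indices are 0-based; the physical position of pixel ``(i, j)`` is
  ``((i + 0.5) * pixel_size_um, (j + 0.5) * pixel_size_um)`` (pixel-centre
  convention). All physical quantities are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AnnotatedImage:
    """A multi-channel field of view with its cell and nucleus annotations.

    Emulates a single confocal z-plane of one labelled neuron: a cell-marker
    channel used for segmentation (the masks are carried along as inputs, as
    segmentation is manual upstream) plus one or more marker channels in which
    puncta are detected.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    soma_mask: np.ndarray
    nucleus_mask: np.ndarray
    z_plane_id: str = "z0"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        shapes |= {self.soma_mask.shape, self.nucleus_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel/mask shapes differ: {shapes}")
        self.soma_mask = self.soma_mask.astype(bool)
        self.nucleus_mask = self.nucleus_mask.astype(bool)
        if np.any(self.nucleus_mask & ~self.soma_mask):
            raise ValueError("nucleus_mask must be contained in soma_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.soma_mask.shape


@dataclass
class ElementalMap:
    """Per-pixel elemental concentration grid (ppm, µg/g dry weight)."""

    element: str
    grid: np.ndarray
    step_um: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        if np.any(self.grid < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical size (height, width) of the mapped area in µm."""
        return (self.grid.shape[0] * self.step_um, self.grid.shape[1] * self.step_um)


@dataclass
class Section:
    """One physical tissue section: in-plane neuron reference points."""

    index: int
    sampled: bool
    points_um: np.ndarray  # (n, 2) array of (x, y) positions

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float).reshape(-1, 2)


@dataclass
class SectionSeries:
    """A serial-section series through a 3-D region, with sampling flags."""

    sections: list[Section]
    thickness_um: float
    region_size_um: tuple[float, float]  # in-plane (x, y) extent
    section_period: int = 1

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def sampled_sections(self) -> list[Section]:
        return [s for s in self.sections if s.sampled]

    @property
    def total_points(self) -> int:
        return int(sum(s.points_um.shape[0] for s in self.sections))


@dataclass
class PunctumTruth:
    """One generated punctum: the catalogue entry used as detection oracle."""

    centre_um: tuple[float, float]  # (y, x) physical position
    radius_um: float
    compartment: str  # "perinuclear" | "cytosolic"


@dataclass
class GroundTruth:
    """The generator's catalogue, consumed only by tests and validation."""

    puncta_catalog: list[PunctumTruth] = field(default_factory=list)
    true_neuron_count: int | None = None
    true_surface_fraction: float | None = None
    target_surface_fraction: float | None = None
    true_mean_difference: float | None = None
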