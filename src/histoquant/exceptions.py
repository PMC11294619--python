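"""Exception types raised across the pipeline."""


class HistoquantError(Exception):
    """Base class for package-specific failures."""


class PlacementError(HistoquantError):
    """Rejection sampling could not place a punctum in the requested compartment."""

    def __init__(self, compartment: str, n_placed: int, n_requested: int):
        self.compartment = compartment
        super().__init__(
            f"could not place punctum {n_placed + 1}/{n_requested} in the "
            f"'{compartment}' compartment after bounded retries; "
            "geometry too crowded for the requested counts"
        )


class DegenerateHistogramError(HistoquantError):
    """Otsu thresholding is undefined on a flat histogram; use a fixed threshold."""


class DegenerateRegionError(HistoquantError):
    """A mask region is too small or collinear for moment-based ellipse fitting."""


class ZeroVarianceError(HistoquantError):
    """Pooled variance is zero with unequal means: the t statistic is infinite."""
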