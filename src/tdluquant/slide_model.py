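"""Core domain types for slide-level TDLU involution analysis.

All spatial data live on a :class:`SlideFrame`: a pixel grid with a known
physical resolution in micrometres per pixel.  The coordinate convention,
used consistently across the package, is 0-based ``(x, y)`` with ``x``
rightward and ``y`` downward, points located at pixel centres, and raster
arrays indexed ``[row=y, col=x]``.

A slide's worth of model/annotation output is bundled into
:class:`SlideObservations`: a tissue-foreground mask, an adipose estimate
(either a raster mask from an automated segmenter or a coarse percentage
bin from a human observer), a TDLU instance label mask, and a point set of
acinus detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

#: Adipose percentage bins used by manual observers, mapped to bin-centre
#: fractions (the "center bin values" used to adjust tissue area).
ADIPOSE_BIN_CENTERS = {
    "<25%": 0.125,
    "25-50%": 0.375,
    "50-75%": 0.625,
    ">75%": 0.875,
}

# En-dash spellings accepted on input and normalized to ASCII hyphen.
_BIN_ALIASES = {
    "25–50%": "25-50%",
    "50–75%": "50-75%",
}


def _canonical_bin(name: str) -> str:
    name = name.strip()
    return _BIN_ALIASES.get(name, name)


@dataclass(frozen=True)
class SlideFrame:
    """Pixel-grid geometry plus physical resolution.

    Parameters
    ----------
    width_px, height_px : int
        Grid dimensions in pixels; both must be >= 1.
    resolution_um_per_px : float
        Physical size of one pixel in micrometres.  The default, 0.16,
        corresponds to a whole-slide scan at x40 magnification.
    """

    width_px: int
    height_px: int
    resolution_um_per_px: float = 0.16

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("frame dimensions must be >= 1 pixel")
        if not (self.resolution_um_per_px > 0):
            raise ValueError("resolution_um_per_px must be positive")

    @property
    def shape(self) -> tuple:
        """Raster shape ``(height, width)`` for numpy arrays."""
        return (self.height_px, self.width_px)

    @property
    def pixel_area_mm2(self) -> float:
        """Area of a single pixel in mm^2."""
        return (self.resolution_um_per_px / 1000.0) ** 2

    def px_to_um(self, length_px: float) -> float:
        return length_px * self.resolution_um_per_px

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.resolution_um_per_px

    def area_px_to_mm2(self, n_pixels: float) -> float:
        return n_pixels * self.pixel_area_mm2

    def area_mm2_to_px(self, area_mm2: float) -> float:
        return area_mm2 / self.pixel_area_mm2

    def contains_point(self, x: float, y: float) -> bool:
        """Whether a pixel-centre point falls inside the grid.

        Valid coordinates span ``[-0.5, dim - 0.5)`` so that a point is in
        the frame iff some pixel contains it.
        """
        return (-0.5 <= x < self.width_px - 0.5 + 1e-9) and (
            -0.5 <= y < self.height_px - 0.5 + 1e-9
        )


@dataclass
class BinaryMask:
    """A boolean raster (tissue foreground, adipose, ...) on a frame."""

    frame: SlideFrame
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != self.frame.shape:
            raise ValueError(
                f"mask shape {self.pixels.shape} does not match frame "
                f"shape {self.frame.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.pixels.sum())

    def area_mm2(self) -> float:
        return self.frame.area_px_to_mm2(self.count)


@dataclass
class LabelMask:
    """TDLU instance labels: 0 = background, k >= 1 = instance k."""

    frame: SlideFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must have an integer dtype")
        if self.labels.shape != self.frame.shape:
            raise ValueError(
                f"label-mask shape {self.labels.shape} does not match frame "
                f"shape {self.frame.shape}"
            )
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def instance_labels(self) -> np.ndarray:
        """Sorted array of the nonzero labels present."""
        present = np.unique(self.labels)
        return present[present > 0]

    @property
    def n_instances(self) -> int:
        return int(self.instance_labels.size)

    def is_normalized(self) -> bool:
        present = self.instance_labels
        return bool(np.array_equal(present, np.arange(1, present.size + 1)))

    def normalized(self) -> "LabelMask":
        """Relabel instances to the gap-free set {1..K}, preserving order.

        Idempotent: normalizing a normalized mask returns an equal mask.
        """
        present = self.instance_labels
        lut = np.zeros(int(self.labels.max()) + 1 if self.labels.size else 1,
                       dtype=self.labels.dtype)
        lut[present] = np.arange(1, present.size + 1, dtype=self.labels.dtype)
        return LabelMask(self.frame, lut[self.labels])


@dataclass
class PointSet:
    """Point detections (acinus centroids) in pixel coordinates."""

    frame: SlideFrame
    points: np.ndarray  # shape (n, 2), columns (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def out_of_bounds(self) -> np.ndarray:
        """Indices of points falling outside the frame."""
        bad = [
            i
            for i, (x, y) in enumerate(self.points)
            if not self.frame.contains_point(x, y)
        ]
        return np.asarray(bad, dtype=int)

    def coords_um(self) -> np.ndarray:
        return self.points * self.frame.resolution_um_per_px


@dataclass
class AdiposeEstimate:
    """Adipose content of a slide: an exact fraction or an observer bin.

    Manual observers report adipose content only in quartile bins; the
    automated pipeline produces a pixel mask which reduces to an exact
    fraction.  Both forms reduce to a fraction via
    :func:`tdluquant.measures.adipose_fraction`.
    """

    mode: str  # "fraction" or "bin"
    fraction: Optional[float] = None
    bin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode == "fraction":
            if self.fraction is None or self.bin is not None:
                raise ValueError("fraction mode requires fraction only")
            if not (0.0 <= self.fraction <= 1.0):
                raise ValueError("fraction must be in [0, 1]")
        elif self.mode == "bin":
            if self.bin is None or self.fraction is not None:
                raise ValueError("bin mode requires bin only")
            canon = _canonical_bin(self.bin)
            if canon not in ADIPOSE_BIN_CENTERS:
                raise ValueError(
                    f"unknown adipose bin {self.bin!r}; expected one of "
                    f"{sorted(ADIPOSE_BIN_CENTERS)}"
                )
            self.bin = canon
        else:
            raise ValueError("mode must be 'fraction' or 'bin'")

    @classmethod
    def from_fraction(cls, fraction: float) -> "AdiposeEstimate":
        return cls(mode="fraction", fraction=float(fraction))

    @classmethod
    def from_bin(cls, bin_name: str) -> "AdiposeEstimate":
        return cls(mode="bin", bin=bin_name)

    @classmethod
    def bin_for_fraction(cls, fraction: float) -> "AdiposeEstimate":
        """The bin an observer would report for a true fraction."""
        if fraction < 0.25:
            name = "<25%"
        elif fraction < 0.50:
            name = "25-50%"
        elif fraction < 0.75:
            name = "50-75%"
        else:
            name = ">75%"
        return cls.from_bin(name)


@dataclass
class SlideObservations:
    """Everything the measures pipeline needs for one slide."""

    frame: SlideFrame
    tissue: BinaryMask
    adipose: Union[AdiposeEstimate, BinaryMask]
    tdlus: LabelMask
    acini: PointSet


@dataclass
class MeasureSet:
    """The five quantitative involution measures plus bookkeeping.

    Median fields are NaN when the slide contains no TDLUs; density
    fields are then 0 (count 0 over a positive area).
    ``median_acini_per_tdlu`` is on the calibrated (manual-equivalent)
    scale; ``median_acini_per_tdlu_raw`` retains the automated count.
    """

    tdlus_per_mm2: float
    median_span_um: float
    median_acini_per_tdlu: float
    acini_per_mm2: float
    median_tdlu_area_mm2: float
    n_tdlus: int
    adjusted_tissue_area_mm2: float
    median_acini_per_tdlu_raw: float = field(default=float("nan"))

    #: column order used by the measures CSV
    CSV_FIELDS = (
        "n_tdlus",
        "adjusted_tissue_area_mm2",
        "tdlus_per_mm2",
        "median_span_um",
        "median_acini_per_tdlu",
        "acini_per_mm2",
        "median_tdlu_area_mm2",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.CSV_FIELDS}


def validate_observations(obs: SlideObservations) -> list:
    """Check all cross-field invariants; return human-readable violations.

    Returns an empty list iff the observations are consistent.  Each
    violation string names the offending field and the rule broken.
    """
    violations = []
    frame = obs.frame
    if obs.tissue.frame != frame:
        violations.append(
            "tissue: BinaryMask frame does not match observations frame"
        )
    if obs.tdlus.frame != frame:
        violations.append(
            "tdlus: LabelMask frame does not match observations frame"
        )
    if isinstance(obs.adipose, BinaryMask) and obs.adipose.frame != frame:
        violations.append(
            "adipose: BinaryMask frame does not match observations frame"
        )
    if obs.acini.frame != frame:
        violations.append(
            "acini: PointSet frame does not match observations frame"
        )
    bad = obs.acini.out_of_bounds()
    if bad.size:
        coords = ", ".join(
            f"({x:g}, {y:g})" for x, y in obs.acini.points[bad[:5]]
        )
        suffix = ", ..." if bad.size > 5 else ""
        violations.append(
            f"acini: {bad.size} point(s) outside frame bounds: {coords}{suffix}"
        )
    if not obs.tdlus.is_normalized():
        violations.append(
            "tdlus: instance labels are not the gap-free set {1..K}; "
            "call LabelMask.normalized()"
        )
    if isinstance(obs.adipose, BinaryMask):
        outside = int((obs.adipose.pixels & ~obs.tissue.pixels).sum())
        if outside:
            violations.append(
                f"adipose: {outside} adipose pixel(s) outside the tissue mask"
            )
    return violations
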