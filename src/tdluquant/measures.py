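"""The five quantitative TDLU involution measures.

Given one slide's observations (tissue mask, adipose estimate, TDLU
instance labels, acinus detections) this module computes:

* TDLUs per mm^2 of adipose-adjusted tissue,
* median TDLU span (μm) — the major-axis length of the ellipse with the
  same normalized second central moments as the TDLU region,
* median number of acini per TDLU (calibrated to the manual counting
  scale by a multiplicative coefficient),
* acini per mm^2 of adipose-adjusted tissue,
* median TDLU area (mm^2).

Tissue area is adjusted for adipose content by multiplying by the
non-adipose fraction; when adipose is known only as an observer bin the
bin-centre value (12.5 / 37.5 / 62.5 / 87.5%) is used.

Calibration maps automated acinus counts onto the manual counting scale.
The default coefficient, 3.888, was derived by regression-through-origin
of manual on automated median acini-per-TDLU counts; the intercept was
not significantly different from zero, so the origin model is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np

from .slide_model import (
    ADIPOSE_BIN_CENTERS,
    AdiposeEstimate,
    BinaryMask,
    LabelMask,
    MeasureSet,
    PointSet,
    SlideFrame,
    SlideObservations,
    validate_observations,
)

#: Default multiplicative calibration from automated to manual acini counts.
DEFAULT_CALIBRATION_COEFFICIENT = 3.888


@dataclass
class TDLURecord:
    """Per-TDLU morphometry: one row of the per-TDLU output table."""

    label: int
    area_mm2: float
    span_um: float
    acini_count_raw: int
    acini_count_calibrated: float
    centroid: Tuple[float, float]  # (x, y) px


@dataclass
class CalibrationModel:
    """Multiplicative (through-origin) calibration of acinus counts.

    ``intercept_estimate``/``intercept_se`` report the free-intercept
    fit's diagnostics for display; the model itself always passes
    through the origin.
    """

    coefficient: float = DEFAULT_CALIBRATION_COEFFICIENT
    n_pairs: int = 0
    source: str = "default"
    intercept_estimate: float = float("nan")
    intercept_se: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.coefficient > 0):
            raise ValueError("calibration coefficient must be positive")
        if self.source not in ("default", "fitted"):
            raise ValueError("source must be 'default' or 'fitted'")

    @property
    def intercept(self) -> float:
        """Fixed at zero: the calibration passes through the origin."""
        return 0.0


def tissue_area_mm2(tissue: BinaryMask) -> float:
    """Total tissue area: foreground pixel count x pixel area."""
    return tissue.area_mm2()


def adipose_fraction(
    adipose: Union[AdiposeEstimate, BinaryMask], tissue: BinaryMask
) -> float:
    """Reduce any adipose estimate to a fraction of tissue in [0, 1].

    Mask mode divides adipose-and-tissue pixels by tissue pixels; bin
    mode returns the bin-centre value; fraction mode is the identity.
    """
    if isinstance(adipose, BinaryMask):
        if adipose.frame != tissue.frame:
            raise ValueError("adipose and tissue masks must share a frame")
        n_tissue = tissue.count
        if n_tissue == 0:
            raise ValueError(
                "adipose fraction undefined: tissue mask is empty"
            )
        overlap = int((adipose.pixels & tissue.pixels).sum())
        return overlap / n_tissue
    if adipose.mode == "bin":
        return ADIPOSE_BIN_CENTERS[adipose.bin]
    return float(adipose.fraction)


def adjusted_tissue_area_mm2(area_mm2: float, adipose_frac: float) -> float:
    """Tissue area x (1 - adipose fraction)."""
    if not (0.0 <= adipose_frac <= 1.0):
        raise ValueError("adipose fraction must be in [0, 1]")
    return area_mm2 * (1.0 - adipose_frac)


def _span_px(xs: np.ndarray, ys: np.ndarray) -> float:
    """Major-axis length (px) of the second-central-moments ellipse.

    The span is 4 * sqrt(lambda_max) where lambda_max is the largest
    eigenvalue of the population covariance matrix of the region's
    pixel-centre coordinates.  For an ideal filled disc of radius r the
    coordinate variance is r^2/4 in every direction, so the span is 2r —
    the diameter; for an ellipse with semi-axes a >= b it is 2a.  No
    pixel-extent variance correction is applied, so a single pixel has
    span 0 and rasterized shapes agree with the continuous closed form
    to within about one pixel.
    """
    if xs.size == 0:
        raise ValueError("cannot compute span of an empty instance")
    cov = np.cov(np.stack([xs, ys]), ddof=0)
    lam_max = float(np.linalg.eigvalsh(cov)[-1])
    lam_max = max(lam_max, 0.0)
    return 4.0 * np.sqrt(lam_max)


def tdlu_span_um(
    instance_pixels: Union[np.ndarray, Sequence[Tuple[float, float]]],
    frame: SlideFrame,
) -> float:
    """Span (μm) of one TDLU instance given its (x, y) pixel coordinates."""
    pts = np.asarray(instance_pixels, dtype=float)
    if pts.size == 0:
        raise ValueError("cannot compute span of an empty instance")
    pts = pts.reshape(-1, 2)
    return _span_px(pts[:, 0], pts[:, 1]) * frame.resolution_um_per_px


def tdlu_area_mm2(
    instance_pixels: Union[np.ndarray, Sequence[Tuple[float, float]]],
    frame: SlideFrame,
) -> float:
    """Area (mm^2) of one TDLU instance: pixel count x pixel area."""
    pts = np.asarray(instance_pixels)
    if pts.size == 0:
        raise ValueError("cannot compute area of an empty instance")
    n = pts.reshape(-1, 2).shape[0]
    return frame.area_px_to_mm2(n)


def assign_acini(
    acini: PointSet, tdlus: LabelMask
) -> Tuple[dict, int]:
    """Assign each acinus to the TDLU instance containing its centroid.

    A point belongs to the pixel whose centre is nearest (round to the
    containing pixel); label 0 means unassigned.  Returns a dict mapping
    every instance label to its count (zero-count instances included)
    and the number of unassigned acini.
    """
    if acini.frame != tdlus.frame:
        raise ValueError("acini and TDLU mask must share a frame")
    counts = {int(lab): 0 for lab in tdlus.instance_labels}
    n_unassigned = 0
    h, w = tdlus.labels.shape
    if len(acini):
        cols = np.clip(np.rint(acini.points[:, 0]).astype(int), 0, w - 1)
        rows = np.clip(np.rint(acini.points[:, 1]).astype(int), 0, h - 1)
        labs = tdlus.labels[rows, cols]
        for lab in labs:
            lab = int(lab)
            if lab == 0:
                n_unassigned += 1
            else:
                counts[lab] = counts.get(lab, 0) + 1
    return counts, n_unassigned


def calibrate(count_raw: float, model: CalibrationModel) -> float:
    """Map an automated acinus count onto the manual counting scale."""
    if count_raw < 0:
        raise ValueError("acinus count must be non-negative")
    return count_raw * model.coefficient


def fit_calibration(
    pairs: Sequence[Tuple[float, float]]
) -> CalibrationModel:
    """Fit the through-origin regression of manual on automated counts.

    ``coefficient = sum(auto * manual) / sum(auto^2)``, the least-squares
    slope with no intercept.  The free-intercept fit's intercept estimate
    and standard error are also reported (diagnostics only; the returned
    model passes through the origin).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (auto, manual) pairs")
    auto, manual = arr[:, 0], arr[:, 1]
    denom = float(np.sum(auto ** 2))
    if denom == 0.0:
        raise ValueError(
            "degenerate design: all automated counts are zero"
        )
    coefficient = float(np.sum(auto * manual) / denom)

    # free-intercept diagnostics (ordinary least squares with intercept)
    intercept_est = float("nan")
    intercept_se = float("nan")
    n = arr.shape[0]
    sxx = float(np.sum((auto - auto.mean()) ** 2))
    if sxx > 0 and n > 2:
        slope_free = float(
            np.sum((auto - auto.mean()) * (manual - manual.mean())) / sxx
        )
        intercept_est = float(manual.mean() - slope_free * auto.mean())
        resid = manual - (intercept_est + slope_free * auto)
        sigma2 = float(np.sum(resid ** 2) / (n - 2))
        intercept_se = float(
            np.sqrt(sigma2 * (1.0 / n + auto.mean() ** 2 / sxx))
        )
    return CalibrationModel(
        coefficient=coefficient,
        n_pairs=n,
        source="fitted",
        intercept_estimate=intercept_est,
        intercept_se=intercept_se,
    )


def instance_coordinates(tdlus: LabelMask) -> dict:
    """(x, y) pixel-centre coordinate arrays for each instance label."""
    out = {}
    labels = tdlus.labels
    for lab in tdlus.instance_labels:
        rows, cols = np.nonzero(labels == lab)
        out[int(lab)] = np.stack([cols, rows], axis=1).astype(float)
    return out


def label_connected_components(
    semantic: BinaryMask, connectivity: int = 1
) -> LabelMask:
    """Instance labels from a semantic TDLU mask via connected components.

    4-connected by default: diagonal contact does not merge TDLUs.
    """
    from scipy import ndimage

    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, _ = ndimage.label(semantic.pixels, structure=structure)
    return LabelMask(semantic.frame, labels.astype(np.int32))


def compute_measures(
    obs: SlideObservations,
    model: CalibrationModel = None,
    min_tdlu_area_mm2: float = 0.0,
) -> Tuple[MeasureSet, List[TDLURecord]]:
    """All five quantitative measures plus per-TDLU records for one slide.

    Instances with area below ``min_tdlu_area_mm2`` are excluded before
    any statistic is computed (default: no filtering).  Densities divide
    by the adipose-adjusted tissue area; ``acini_per_mm2`` counts every
    detection, including acini outside any TDLU.  The median acini count
    is taken over raw per-TDLU counts and then calibrated — by linearity
    this equals calibrating each count first.  With zero TDLUs the
    medians are NaN and a warning is emitted.
    """
    if model is None:
        model = CalibrationModel()
    problems = validate_observations(obs)
    if problems:
        raise ValueError(
            "invalid observations: " + "; ".join(problems)
        )
    frame = obs.frame
    area = tissue_area_mm2(obs.tissue)
    frac = adipose_fraction(obs.adipose, obs.tissue)
    adj_area = adjusted_tissue_area_mm2(area, frac)
    if adj_area <= 0:
        raise ValueError(
            "adjusted tissue area is zero; densities are undefined"
        )

    coords = instance_coordinates(obs.tdlus)
    counts, _ = assign_acini(obs.acini, obs.tdlus)

    records: List[TDLURecord] = []
    for lab, pts in coords.items():
        area_i = tdlu_area_mm2(pts, frame)
        if area_i < min_tdlu_area_mm2:
            continue
        raw = counts.get(lab, 0)
        records.append(
            TDLURecord(
                label=lab,
                area_mm2=area_i,
                span_um=tdlu_span_um(pts, frame),
                acini_count_raw=raw,
                acini_count_calibrated=calibrate(raw, model),
                centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
            )
        )

    n_tdlus = len(records)
    if n_tdlus:
        median_span = float(np.median([r.span_um for r in records]))
        median_raw = float(np.median([r.acini_count_raw for r in records]))
        median_cal = calibrate(median_raw, model)
        median_area = float(np.median([r.area_mm2 for r in records]))
    else:
        warnings.warn(
            "slide contains no TDLUs; median measures are undefined",
            stacklevel=2,
        )
        median_span = median_raw = median_cal = median_area = float("nan")

    measures = MeasureSet(
        tdlus_per_mm2=n_tdlus / adj_area,
        median_span_um=median_span,
        median_acini_per_tdlu=median_cal,
        acini_per_mm2=len(obs.acini) / adj_area,
        median_tdlu_area_mm2=median_area,
        n_tdlus=n_tdlus,
        adjusted_tissue_area_mm2=adj_area,
        median_acini_per_tdlu_raw=median_raw,
    )
    return measures, records
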