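"""Synthetic slides with exact ground truth.

Real whole-slide images of benign breast biopsies cannot be
redistributed, so the test harness generates pseudo-H&E slides with
known geometry: a tissue region (pink stroma) containing bright adipose
blobs and K TDLUs.  Each TDLU is a disc of denser, slightly
basophilic intralobular stroma filled with a cluster of non-overlapping
acini, each acinus drawn as an annulus — a purple epithelial ring
around a pale lumen — mirroring the histologic definition of acini as
small spherical structures lined by epithelial cells.

Every generated slide carries its exact ground truth: the rasters and
point set (a :class:`~tdluquant.slide_model.SlideObservations`), the
true measure set (computed from planted geometry; areas and spans agree
with the rasters to within ~2% rasterization error), and the true
Russo/Baer classification of the planted acinus counts.

The generator is deterministic given the spec's seed.

The default spec works at 2 μm/pixel — a coarser grid than a x40 scan —
so that TDLUs with realistic spans (300–700 μm) and densities
(~0.3–2 /mm²) fit a 2048² frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk

from .measures import assign_acini, instance_coordinates, tdlu_span_um
from .qualitative import QualitativeResult, russo_type
from .slide_model import (
    AdiposeEstimate,
    BinaryMask,
    LabelMask,
    MeasureSet,
    PointSet,
    SlideFrame,
    SlideObservations,
)

# Pseudo-H&E palette (RGB).  The reference backend's thresholds are
# derived from these values; change them together.
BACKGROUND_RGB = (255, 255, 255)
STROMA_RGB = (236, 186, 206)
ADIPOSE_RGB = (247, 245, 248)
TDLU_STROMA_RGB = (206, 166, 216)
ACINUS_RING_RGB = (112, 58, 138)
ACINUS_LUMEN_RGB = (238, 230, 242)

#: distribution spec: scalar, explicit list, or (name, *params) tuple
DistSpec = Union[float, Sequence[float], Tuple]


def _draw_values(rng: np.random.Generator, spec: DistSpec, n: int) -> np.ndarray:
    """Realize n values from a distribution spec.

    Accepted forms: scalar (constant), explicit sequence of length n,
    ``("uniform", lo, hi)``, or ``("lognormal", mu, sigma)`` on the log
    scale.
    """
    if isinstance(spec, (int, float)):
        return np.full(n, float(spec))
    if isinstance(spec, tuple) and spec and isinstance(spec[0], str):
        name = spec[0]
        if name == "uniform":
            return rng.uniform(spec[1], spec[2], size=n)
        if name == "lognormal":
            return rng.lognormal(mean=spec[1], sigma=spec[2], size=n)
        raise ValueError(f"unknown distribution {name!r}")
    vals = np.asarray(list(spec), dtype=float)
    if vals.size != n:
        raise ValueError(f"expected {n} explicit values, got {vals.size}")
    return vals


@dataclass(frozen=True)
class SlideSpec:
    """Recipe for one synthetic slide.

    Defaults plant TDLUs at realistic magnitudes: spans ~300–700 μm,
    roughly 5–80 acini per TDLU, and densities of order 1 /mm².
    """

    frame: SlideFrame = field(
        default_factory=lambda: SlideFrame(2048, 2048, 2.0)
    )
    n_tdlus: int = 12
    acini_per_tdlu: DistSpec = ("lognormal", 3.0, 0.7)
    tdlu_radius_um: DistSpec = ("uniform", 150.0, 350.0)
    acinus_radius_um: DistSpec = ("uniform", 12.0, 20.0)
    adipose_fraction_target: float = 0.30
    tissue_shape: str = "rectangle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tdlus < 0:
            raise ValueError("n_tdlus must be >= 0")
        if not (0.0 <= self.adipose_fraction_target <= 1.0):
            raise ValueError("adipose_fraction_target must be in [0, 1]")
        if self.tissue_shape not in ("rectangle", "blob"):
            raise ValueError("tissue_shape must be 'rectangle' or 'blob'")


@dataclass
class SyntheticSlide:
    """A rendered pseudo-H&E image plus its exact ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: SlideObservations
    true_measures: MeasureSet
    true_types: QualitativeResult
    spec: SlideSpec
    tdlu_centers_px: np.ndarray  # (K, 2) (x, y)
    tdlu_radii_px: np.ndarray  # (K,)
    acini_counts: np.ndarray  # (K,) planted per-TDLU counts


def _tissue_mask(spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.frame.shape
    if spec.tissue_shape == "rectangle":
        m = np.zeros((h, w), dtype=bool)
        margin = max(8, min(h, w) // 64)
        m[margin : h - margin, margin : w - margin] = True
        return m
    # blob: ellipse with a smooth sinusoidal boundary perturbation
    cy, cx = h / 2.0, w / 2.0
    ry, rx = 0.42 * h, 0.42 * w
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2((yy - cy) / ry, (xx - cx) / rx)
    n_lobes = int(rng.integers(3, 6))
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.05, 0.12)
    wobble = 1.0 + amp * np.cos(n_lobes * theta + phase)
    r = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    return r <= wobble


def _place_tdlus(
    tissue: np.ndarray,
    radii_px: np.ndarray,
    min_radii_px: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 3000,
) -> np.ndarray:
    """Non-overlapping disc centers fully inside the tissue, or raise.

    Random sequential placement, largest disc first.  When a disc
    cannot be placed after ``max_tries`` attempts its radius is shrunk
    by 8% (``radii_px`` is updated in place) and placement retries,
    down to the per-disc floor that still packs the requested acini;
    only then is the packing declared infeasible.
    """
    edt = ndimage.distance_transform_edt(tissue)
    t_rows, t_cols = np.nonzero(tissue)
    order = np.argsort(radii_px)[::-1]
    placed = np.zeros((len(radii_px), 2))
    done: List[int] = []  # indices already placed, in order
    for idx in order:
        while True:
            r = radii_px[idx]
            success = False
            for _ in range(max_tries):
                j = rng.integers(t_rows.size)
                y, x = float(t_rows[j]), float(t_cols[j])
                if edt[int(y), int(x)] < r + 2:
                    continue
                if all(
                    math.hypot(x - placed[k, 0], y - placed[k, 1])
                    >= r + radii_px[k] + 8
                    for k in done
                ):
                    placed[idx] = (x, y)
                    done.append(idx)
                    success = True
                    break
            if success:
                break
            shrunk = r * 0.92
            if shrunk < min_radii_px[idx]:
                raise ValueError(
                    "infeasible packing: could not place all TDLUs "
                    "without overlap; reduce n_tdlus or TDLU radii"
                )
            radii_px[idx] = shrunk
    return placed


def _place_acini(
    center: Tuple[float, float],
    tdlu_r: float,
    n: int,
    acinus_r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """n non-overlapping acinus centers inside one TDLU disc, or raise."""
    cx, cy = center
    r_max = tdlu_r - acinus_r - 2.0
    if r_max <= 0:
        raise ValueError("acinus radius too large for TDLU radius")
    pts: List[Tuple[float, float]] = []
    min_sep = 2.0 * acinus_r + 2.0
    tries = 0
    limit = 400 * max(n, 1)
    while len(pts) < n and tries < limit:
        tries += 1
        rho = r_max * math.sqrt(rng.random())
        ang = rng.uniform(0.0, 2.0 * math.pi)
        x, y = cx + rho * math.cos(ang), cy + rho * math.sin(ang)
        if all(math.hypot(x - px, y - py) >= min_sep for px, py in pts):
            pts.append((x, y))
    if len(pts) < n:
        raise ValueError(
            f"could not pack {n} acini of radius {acinus_r:.1f} px into a "
            f"TDLU of radius {tdlu_r:.1f} px"
        )
    return np.asarray(pts)


def _min_tdlu_radius_px(n_acini: int, acinus_r_px: float) -> float:
    """Radius guaranteeing comfortable random packing of n acini.

    Acinus centers must sit 2(r+1) px apart, i.e. random sequential
    addition of discs of radius r+1; a 1.8*sqrt(n) factor keeps the
    packing fraction near 30%, well below the ~55% jamming limit.
    """
    eff = acinus_r_px + 1.0
    return eff * 1.8 * math.sqrt(max(n_acini, 1)) + acinus_r_px + 4.0


def _place_adipose(
    tissue: np.ndarray,
    forbidden: np.ndarray,
    target: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bright adipose blobs approximating the target tissue fraction.

    Blobs are discs placed in tissue away from TDLUs; placement stops
    once the achieved fraction is within 0.01 of the target or the
    attempt budget runs out (final fraction within ±0.05 of target for
    feasible specs).
    """
    adipose = np.zeros_like(tissue)
    if target <= 0.0:
        return adipose
    n_tissue = int(tissue.sum())
    allowed = tissue & ~forbidden
    edt = ndimage.distance_transform_edt(allowed)
    a_rows, a_cols = np.nonzero(allowed)
    if a_rows.size == 0:
        return adipose
    h, w = tissue.shape
    n_adipose = 0
    attempts = 0
    while attempts < 4000:
        attempts += 1
        deficit = target - n_adipose / n_tissue
        if deficit <= 0.01:
            break
        r_cap = math.sqrt(1.25 * deficit * n_tissue / math.pi)
        r = min(rng.uniform(25.0, 110.0), max(r_cap, 8.0))
        j = rng.integers(a_rows.size)
        if edt[a_rows[j], a_cols[j]] < r + 1:
            continue
        rr, cc = draw_disk(
            (float(a_rows[j]), float(a_cols[j])), r, shape=(h, w)
        )
        adipose[rr, cc] = True
        n_adipose = int(adipose.sum())  # blobs may overlap: recount
    return adipose & tissue


def generate_slide(spec: SlideSpec) -> SyntheticSlide:
    """Render one synthetic slide and its exact ground truth.

    Deterministic given ``spec.seed``.  Raises when the requested TDLUs
    cannot be packed into the tissue without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    frame = spec.frame
    h, w = frame.shape
    res = frame.resolution_um_per_px

    tissue = _tissue_mask(spec, rng)

    k = spec.n_tdlus
    if k:
        counts = np.rint(_draw_values(rng, spec.acini_per_tdlu, k)).astype(int)
        counts = np.clip(counts, 1, 150)  # >= 1 acinus; cap for packability
    else:
        counts = np.zeros(0, dtype=int)
    acinus_r_px = _draw_values(rng, spec.acinus_radius_um, k) / res if k else np.zeros(0)
    tdlu_r_px = _draw_values(rng, spec.tdlu_radius_um, k) / res if k else np.zeros(0)
    min_r_px = np.zeros(k)
    for i in range(k):
        min_r_px[i] = _min_tdlu_radius_px(counts[i], acinus_r_px[i])
        tdlu_r_px[i] = max(tdlu_r_px[i], min_r_px[i])
    n_tissue_px = int(tissue.sum())
    if k and np.pi * float((min_r_px ** 2).sum()) > 0.5 * n_tissue_px:
        raise ValueError(
            "infeasible packing: requested TDLU area exceeds half the "
            "tissue area"
        )
    # pre-scale towards a packable total disc area; placement shrinks
    # individual discs further if needed
    if k:
        total = np.pi * float((tdlu_r_px ** 2).sum())
        budget = 0.30 * n_tissue_px
        if total > budget:
            tdlu_r_px = np.maximum(
                tdlu_r_px * math.sqrt(budget / total), min_r_px
            )

    centers = (
        _place_tdlus(tissue, tdlu_r_px, min_r_px, rng)
        if k
        else np.zeros((0, 2))
    )

    labels = np.zeros((h, w), dtype=np.int32)
    acini_pts: List[Tuple[float, float]] = []
    acini_geoms: List[Tuple[np.ndarray, float]] = []
    for i in range(k):
        rr, cc = draw_disk(
            (centers[i, 1], centers[i, 0]), tdlu_r_px[i], shape=(h, w)
        )
        labels[rr, cc] = i + 1
        pts = _place_acini(
            (centers[i, 0], centers[i, 1]),
            tdlu_r_px[i],
            int(counts[i]),
            float(acinus_r_px[i]),
            rng,
        )
        acini_pts.extend(map(tuple, pts))
        acini_geoms.append((pts, float(acinus_r_px[i])))

    tdlu_region = labels > 0
    grown = (
        ndimage.binary_dilation(tdlu_region, iterations=4)
        if k
        else tdlu_region
    )
    adipose = _place_adipose(
        tissue, grown, spec.adipose_fraction_target, rng
    )

    # --- render ---------------------------------------------------------
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = BACKGROUND_RGB
    image[tissue] = STROMA_RGB
    image[adipose] = ADIPOSE_RGB
    image[tdlu_region] = TDLU_STROMA_RGB
    for pts, a_r in acini_geoms:
        ring_w = max(2.0, a_r / 4.0)
        for x, y in pts:
            rr, cc = draw_disk((y, x), a_r, shape=(h, w))
            image[rr, cc] = ACINUS_RING_RGB
            rr, cc = draw_disk((y, x), a_r - ring_w, shape=(h, w))
            image[rr, cc] = ACINUS_LUMEN_RGB

    truth = SlideObservations(
        frame=frame,
        tissue=BinaryMask(frame, tissue),
        adipose=BinaryMask(frame, adipose),
        tdlus=LabelMask(frame, labels),
        acini=PointSet(frame, np.asarray(acini_pts).reshape(-1, 2)),
    )

    # --- true measures (planted geometry; areas from the same rasters
    #     the pipeline sees, so densities match exactly) -----------------
    n_tissue = int(tissue.sum())
    frac = float((adipose & tissue).sum()) / n_tissue
    adj_area = frame.area_px_to_mm2(n_tissue) * (1.0 - frac)
    if k:
        spans_um = 2.0 * tdlu_r_px * res
        areas_mm2 = np.pi * tdlu_r_px ** 2 * frame.pixel_area_mm2
        median_span = float(np.median(spans_um))
        median_raw = float(np.median(counts))
        median_area = float(np.median(areas_mm2))
    else:
        median_span = median_raw = median_area = float("nan")
    true_measures = MeasureSet(
        tdlus_per_mm2=k / adj_area,
        median_span_um=median_span,
        median_acini_per_tdlu=median_raw,  # truth is on the raw scale
        acini_per_mm2=len(acini_pts) / adj_area,
        median_tdlu_area_mm2=median_area,
        n_tdlus=k,
        adjusted_tissue_area_mm2=adj_area,
        median_acini_per_tdlu_raw=median_raw,
    )
    true_types = QualitativeResult.from_types(
        [russo_type(int(c)) for c in counts]
    )
    return SyntheticSlide(
        image=image,
        truth=truth,
        true_measures=true_measures,
        true_types=true_types,
        spec=spec,
        tdlu_centers_px=centers,
        tdlu_radii_px=tdlu_r_px,
        acini_counts=counts,
    )


def perturb_observations(
    truth: SlideObservations,
    drop_rate: float = 0.0,
    spurious_rate: float = 0.0,
    jitter_um: float = 0.0,
    seed: int = 0,
) -> SlideObservations:
    """Degrade the true acinus detections to emulate an imperfect model.

    Each true acinus is dropped independently with ``drop_rate``;
    ``spurious_rate`` false detections per mm² of tissue are added
    uniformly over the tissue (Poisson count); surviving points are
    jittered by an isotropic Gaussian of SD ``jitter_um``.  Masks are
    passed through unchanged.
    """
    if not (0.0 <= drop_rate < 1.0):
        raise ValueError("drop_rate must be in [0, 1)")
    if spurious_rate < 0 or jitter_um < 0:
        raise ValueError("spurious_rate and jitter_um must be >= 0")
    rng = np.random.default_rng(seed)
    frame = truth.frame
    pts = truth.acini.points
    if drop_rate > 0 and len(pts):
        keep = rng.random(len(pts)) >= drop_rate
        pts = pts[keep]
    else:
        pts = pts.copy()
    if jitter_um > 0 and len(pts):
        pts = pts + rng.normal(
            0.0, jitter_um / frame.resolution_um_per_px, size=pts.shape
        )
    if spurious_rate > 0:
        area = truth.tissue.area_mm2()
        n_new = rng.poisson(spurious_rate * area)
        if n_new:
            rows, cols = np.nonzero(truth.tissue.pixels)
            idx = rng.integers(rows.size, size=n_new)
            offs = rng.uniform(-0.5, 0.5, size=(n_new, 2))
            new = np.stack(
                [cols[idx] + offs[:, 0], rows[idx] + offs[:, 1]], axis=1
            )
            pts = np.vstack([pts, new]) if len(pts) else new
    if len(pts):
        pts[:, 0] = np.clip(pts[:, 0], -0.499, frame.width_px - 0.501)
        pts[:, 1] = np.clip(pts[:, 1], -0.499, frame.height_px - 0.501)
    return SlideObservations(
        frame=frame,
        tissue=truth.tissue,
        adipose=truth.adipose,
        tdlus=truth.tdlus,
        acini=PointSet(frame, pts),
    )


@dataclass
class ObserverMeasurement:
    """A simulated manual assessment of one slide."""

    roi_origin_px: Tuple[int, int]  # (x, y) of ROI top-left
    roi_area_mm2: float
    adipose_bin: str
    n_tdlus: int
    tdlus_per_mm2: float
    measured_labels: List[int]
    spans_um: List[float]
    acini_counts: List[float]
    median_span_um: float
    median_acini_per_tdlu: float
    flag: Optional[str] = None


def simulate_observer(
    truth: SlideObservations,
    roi_area_mm2: float = 50.0,
    max_tdlus: int = 10,
    count_scale: float = 1.0,
    span_noise_um: float = 0.0,
    count_noise_cv: float = 0.0,
    seed: int = 0,
) -> ObserverMeasurement:
    """Emulate the manual assessment protocol on a slide's ground truth.

    The observer selects a square region of interest of about
    ``roi_area_mm2`` containing at least one TDLU, estimates adipose
    content as a quartile bin, counts TDLUs in the ROI, and measures
    span and acinus count on up to ``max_tdlus`` randomly chosen TDLUs.
    ``count_scale`` models a systematic counting-scale difference
    between observers and the automated detector (the quantity the
    calibration coefficient corrects); ``span_noise_um`` and
    ``count_noise_cv`` add Gaussian measurement noise.  With zero noise,
    unit scale, and ``max_tdlus`` >= the number of TDLUs in the ROI, the
    observer reproduces the truth exactly.
    """
    rng = np.random.default_rng(seed)
    frame = truth.frame
    h, w = frame.shape
    side_px = int(round(math.sqrt(roi_area_mm2) * 1000.0 / frame.resolution_um_per_px))
    flag = None
    coords = instance_coordinates(truth.tdlus)
    centroids = {
        lab: (pts[:, 0].mean(), pts[:, 1].mean())
        for lab, pts in coords.items()
    }
    if side_px >= min(h, w):
        x0, y0 = 0, 0
        side_x, side_y = w, h
        flag = "roi_exceeds_slide"
    else:
        side_x = side_y = side_px
        x0 = y0 = 0
        found = False
        for _ in range(200):
            x0 = int(rng.integers(0, w - side_px + 1))
            y0 = int(rng.integers(0, h - side_px + 1))
            if any(
                x0 <= cx < x0 + side_px and y0 <= cy < y0 + side_px
                for cx, cy in centroids.values()
            ):
                found = True
                break
        if not found:
            flag = "no_tdlu_in_roi"

    roi_tissue = truth.tissue.pixels[y0 : y0 + side_y, x0 : x0 + side_x]
    n_roi_tissue = int(roi_tissue.sum())
    if isinstance(truth.adipose, BinaryMask):
        roi_adip = truth.adipose.pixels[y0 : y0 + side_y, x0 : x0 + side_x]
        frac = (roi_adip & roi_tissue).sum() / max(n_roi_tissue, 1)
    else:
        from .measures import adipose_fraction

        frac = adipose_fraction(truth.adipose, truth.tissue)
    adipose_bin = AdiposeEstimate.bin_for_fraction(float(frac)).bin

    in_roi = [
        lab
        for lab, (cx, cy) in sorted(centroids.items())
        if x0 <= cx < x0 + side_x and y0 <= cy < y0 + side_y
    ]
    tissue_area = frame.area_px_to_mm2(n_roi_tissue)
    from .slide_model import ADIPOSE_BIN_CENTERS

    adj = tissue_area * (1.0 - ADIPOSE_BIN_CENTERS[adipose_bin])
    n_tdlus = len(in_roi)

    counts_map, _ = assign_acini(truth.acini, truth.tdlus)
    chosen = (
        in_roi
        if n_tdlus <= max_tdlus
        else sorted(rng.choice(in_roi, size=max_tdlus, replace=False).tolist())
    )
    spans, meas_counts = [], []
    for lab in chosen:
        span = tdlu_span_um(coords[lab], frame)
        if span_noise_um > 0:
            span += rng.normal(0.0, span_noise_um)
        spans.append(max(span, 0.0))
        c = counts_map.get(lab, 0) * count_scale
        if count_noise_cv > 0:
            c *= 1.0 + rng.normal(0.0, count_noise_cv)
        meas_counts.append(max(c, 0.0))

    return ObserverMeasurement(
        roi_origin_px=(x0, y0),
        roi_area_mm2=frame.area_px_to_mm2(side_x * side_y),
        adipose_bin=adipose_bin,
        n_tdlus=n_tdlus,
        tdlus_per_mm2=n_tdlus / adj if adj > 0 else float("nan"),
        measured_labels=list(chosen),
        spans_um=spans,
        acini_counts=meas_counts,
        median_span_um=float(np.median(spans)) if spans else float("nan"),
        median_acini_per_tdlu=(
            float(np.median(meas_counts)) if meas_counts else float("nan")
        ),
        flag=flag,
    )
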