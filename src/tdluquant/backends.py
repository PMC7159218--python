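"""Pluggable segmentation/detection backends.

A backend turns an RGB slide image into
:class:`~tdluquant.slide_model.SlideObservations` (tissue mask, adipose
mask, TDLU instance labels, acinus points).  The measures pipeline is
backend-agnostic: swapping backends changes only the observations,
never the measure semantics.

Two backends ship with the package:

* ``reference`` — a deterministic color-threshold segmenter tuned to
  the synthetic renderer's palette.  It is a test double that enables
  end-to-end runs without data or trained models, not a histology
  segmenter.
* ``learned`` — a per-pixel logistic-regression classifier on color and
  smoothed-color features, trainable on labeled patches at desk scale.
  It demonstrates the full train / serialize / predict / evaluate loop
  of a learned segmentation model.

``tile_and_stitch`` applies any per-patch function over a large frame
with overlap and central-crop blending, so backends scale past memory
limits without visible seams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from scipy import ndimage

from .measures import label_connected_components
from .slide_model import (
    BinaryMask,
    LabelMask,
    PointSet,
    SlideFrame,
    SlideObservations,
)


@dataclass
class BackendConfig:
    """How to run a backend over a slide image."""

    backend: str = "reference"  # "reference", "learned", "external"
    patch_size_px: int = 1024
    overlap_px: int = 64
    thresholds: Dict[str, float] = field(default_factory=dict)
    model_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.overlap_px >= self.patch_size_px:
            raise ValueError("overlap_px must be smaller than patch_size_px")
        if self.backend not in ("reference", "learned", "external"):
            raise ValueError(f"unknown backend {self.backend!r}")


# Reference-backend thresholds, derived from the synthetic palette:
# background is pure white; adipose is near-white but below 252; acinus
# rings have strongly suppressed green; intralobular (TDLU) stroma has a
# blue excess over green that interlobular stroma lacks.
_REFERENCE_DEFAULTS = {
    "background_min_channel": 252.0,
    "adipose_min_channel": 240.0,
    "ring_max_green": 140.0,
    "tdlu_blue_excess": 25.0,
    "acinus_min_area_px": 6.0,
    "acinus_max_area_um2": 4000.0,
}


def reference_segment(
    image: np.ndarray, frame: SlideFrame, thresholds: Optional[dict] = None
) -> SlideObservations:
    """Deterministic color-threshold segmentation of a synthetic render.

    Pure function of the image and thresholds.  Tissue is any non-white
    pixel; adipose is near-white tissue; TDLUs are regions of
    blue-excess stroma (holes from acinus lumens filled, 4-connected
    components); acini are the centroids of purple ring components,
    size-filtered.
    """
    th = dict(_REFERENCE_DEFAULTS)
    if thresholds:
        th.update(thresholds)
    img = np.asarray(image)
    if img.shape[:2] != frame.shape or img.ndim != 3:
        raise ValueError("image does not match frame dimensions")
    r = img[..., 0].astype(np.int16)
    g = img[..., 1].astype(np.int16)
    b = img[..., 2].astype(np.int16)
    min_ch = np.minimum(np.minimum(r, g), b)

    tissue = min_ch < th["background_min_channel"]
    adipose = tissue & (min_ch >= th["adipose_min_channel"])

    tdlu_sem = (b - g) >= th["tdlu_blue_excess"]
    tdlu_sem = ndimage.binary_fill_holes(tdlu_sem)
    tdlus = label_connected_components(
        BinaryMask(frame, tdlu_sem), connectivity=1
    )

    ring = g <= th["ring_max_green"]
    lab_ring, n_ring = ndimage.label(
        ring, structure=ndimage.generate_binary_structure(2, 2)
    )
    pts: List[Tuple[float, float]] = []
    if n_ring:
        max_area_px = th["acinus_max_area_um2"] / (
            frame.resolution_um_per_px ** 2
        )
        sizes = ndimage.sum_labels(
            ring, lab_ring, index=np.arange(1, n_ring + 1)
        )
        keep = np.nonzero(
            (sizes >= th["acinus_min_area_px"]) & (sizes <= max_area_px)
        )[0] + 1
        if keep.size:
            centers = ndimage.center_of_mass(ring, lab_ring, keep.tolist())
            pts = [(cx, cy) for cy, cx in centers]

    return SlideObservations(
        frame=frame,
        tissue=BinaryMask(frame, tissue),
        adipose=BinaryMask(frame, adipose),
        tdlus=tdlus,
        acini=PointSet(frame, np.asarray(pts).reshape(-1, 2)),
    )


def run_backend(
    image: np.ndarray, frame: SlideFrame, cfg: Optional[BackendConfig] = None
) -> SlideObservations:
    """Produce SlideObservations from an RGB image with the chosen backend."""
    cfg = cfg or BackendConfig()
    if cfg.backend == "reference":
        return reference_segment(image, frame, cfg.thresholds)
    if cfg.backend == "learned":
        if not cfg.model_path:
            raise ValueError("learned backend requires model_path")
        # learned model provides the adipose mask; the remaining channels
        # come from the reference rules
        obs = reference_segment(image, frame, cfg.thresholds)
        adipose_pred = predict_mask(cfg.model_path, image)
        return SlideObservations(
            frame=frame,
            tissue=obs.tissue,
            adipose=BinaryMask(frame, adipose_pred & obs.tissue.pixels),
            tdlus=obs.tdlus,
            acini=obs.acini,
        )
    raise ValueError(
        "external backend: supply SlideObservations directly via io_formats"
    )


def tile_and_stitch(
    image: np.ndarray,
    frame: SlideFrame,
    patch_size_px: int,
    overlap_px: int,
    fn: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """Apply a per-patch raster function over a full frame, seam-free.

    Patches of ``patch_size_px`` are taken on a grid with stride
    ``patch_size_px - overlap_px``; each output patch contributes only
    its central crop (margin ``overlap_px // 2``), except at frame
    borders where the crop extends to the edge.  For any per-patch
    function whose output at a pixel depends only on an
    ``overlap_px/2`` neighborhood, the stitched result equals the
    function applied to the whole frame.
    """
    if overlap_px >= patch_size_px:
        raise ValueError("overlap must be smaller than patch size")
    h, w = frame.shape
    if image.shape[:2] != (h, w):
        raise ValueError("image does not match frame")
    probe = fn(image[: min(patch_size_px, h), : min(patch_size_px, w)])
    out_dtype = probe.dtype
    out = np.zeros(
        (h, w) + probe.shape[2:], dtype=out_dtype
    )
    margin = overlap_px // 2
    stride = patch_size_px - overlap_px
    ys = list(range(0, max(h - overlap_px, 1), stride))
    xs = list(range(0, max(w - overlap_px, 1), stride))
    for y0 in ys:
        y1 = min(y0 + patch_size_px, h)
        for x0 in xs:
            x1 = min(x0 + patch_size_px, w)
            res = fn(image[y0:y1, x0:x1])
            cy0 = 0 if y0 == 0 else margin
            cx0 = 0 if x0 == 0 else margin
            cy1 = res.shape[0] if y1 == h else res.shape[0] - margin
            cx1 = res.shape[1] if x1 == w else res.shape[1] - margin
            out[y0 + cy0 : y0 + cy1, x0 + cx0 : x0 + cx1] = res[
                cy0:cy1, cx0:cx1
            ]
    return out


# ---------------------------------------------------------------------------
# learned per-pixel classifier backend
# ---------------------------------------------------------------------------

def _pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel features: RGB plus Gaussian-smoothed RGB at two scales."""
    img = np.asarray(image, dtype=np.float32) / 255.0
    feats = [img]
    for sigma in (2.0, 4.0):
        feats.append(
            np.stack(
                [
                    ndimage.gaussian_filter(img[..., c], sigma)
                    for c in range(3)
                ],
                axis=-1,
            )
        )
    stack = np.concatenate(feats, axis=-1)
    return stack.reshape(-1, stack.shape[-1])


def train_segmenter(
    patches: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    task: str = "adipose",
    model_path: str = "segmenter.joblib",
    epochs: int = 3,
    max_pixels_per_patch: int = 20000,
    seed: int = 0,
) -> str:
    """Train the learned per-pixel segmenter on labeled patches.

    Fits a logistic-regression pixel classifier on color/smoothed-color
    features subsampled from the training patches.  Optimization runs
    ``epochs`` warm-started L-BFGS rounds, recording the training
    log-loss after each; the pixel subsample is drawn with ``seed`` and
    the whole procedure is deterministic.  The fitted model, its task
    name, and the loss curve are serialized to ``model_path`` (joblib).
    Returns the path.
    """
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import log_loss

    if len(patches) == 0:
        raise ValueError("empty training set")
    if len(patches) != len(masks):
        raise ValueError("patches and masks must pair up")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for img, m in zip(patches, masks):
        f = _pixel_features(img)
        lab = np.asarray(m, dtype=bool).ravel()
        if f.shape[0] != lab.shape[0]:
            raise ValueError("patch and mask dimensions differ")
        n = min(max_pixels_per_patch, f.shape[0])
        idx = rng.choice(f.shape[0], size=n, replace=False)
        xs.append(f[idx])
        ys.append(lab[idx])
    x = np.concatenate(xs)
    y = np.concatenate(ys).astype(int)
    if y.min() == y.max():
        raise ValueError("training set contains a single class")

    clf = LogisticRegression(
        C=1e4, solver="lbfgs", warm_start=True, max_iter=50, tol=1e-7
    )
    losses = []
    for _ in range(epochs):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(x, y)
        losses.append(float(log_loss(y, clf.predict_proba(x)[:, 1])))
    joblib.dump(
        {"model": clf, "task": task, "loss_curve": losses}, model_path
    )
    return str(model_path)


def predict_mask(model_path: str, image: np.ndarray) -> np.ndarray:
    """Apply a trained pixel segmenter to an RGB image -> boolean mask."""
    bundle = joblib.load(model_path)
    clf = bundle["model"]
    f = _pixel_features(image)
    pred = clf.predict(f).astype(bool)
    return pred.reshape(np.asarray(image).shape[:2])


def load_loss_curve(model_path: str) -> List[float]:
    return list(joblib.load(model_path)["loss_curve"])


def kfold_slide_split(
    slide_ids: Sequence[str], n_folds: int, seed: int = 0
) -> List[Tuple[List[str], List[str]]]:
    """Seeded k-fold cross-validation split by slide id.

    Returns ``n_folds`` (train_ids, test_ids) pairs; every slide
    appears in exactly one test fold.
    """
    ids = list(slide_ids)
    if n_folds < 2 or n_folds > len(ids):
        raise ValueError("need 2 <= n_folds <= number of slides")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(len(ids)))
    folds: List[List[str]] = [[] for _ in range(n_folds)]
    for i, j in enumerate(perm):
        folds[i % n_folds].append(ids[j])
    out = []
    for f in range(n_folds):
        test = sorted(folds[f])
        train = sorted(x for g in range(n_folds) if g != f for x in folds[g])
        out.append((train, test))
    return out
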