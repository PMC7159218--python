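"""Readers and writers for the pipeline's standard artifacts.

Formats handled:

* **Masks** — single-channel PNG (binary, 0/1 uint8) and TIFF (instance
  labels, uint16).  Round trips are lossless; multi-channel images are
  rejected.
* **Points** — CSV with columns ``slide_id,x,y`` (pixel units) or
  GeoJSON ``Point`` features.
* **Annotations** — the ASAP XML dialect (``Annotations/Annotation``
  elements with ``Coordinates``), as produced by the open-source ASAP
  slide-annotation tool; polygons and dot annotations, with a
  user-supplied label map onto {acinus, tdlu, adipose, tissue}.
  Acinus annotations drawn as small squares are reduced to their
  centroids — the square extents are discarded.
* **Measures** — CSV with one row per slide plus a JSON sidecar holding
  configuration provenance.
* **Config** — YAML.

Readers reject dialect violations rather than coercing them.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image
from skimage.draw import polygon2mask

from .slide_model import (
    BinaryMask,
    LabelMask,
    MeasureSet,
    PointSet,
    SlideFrame,
)

CANONICAL_LABELS = ("acinus", "tdlu", "adipose", "tissue")


@dataclass
class AnnotationSet:
    """Polygon and point annotations with canonical labels."""

    polygons: List[Tuple[str, np.ndarray]] = field(default_factory=list)
    points: List[Tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, verts in self.polygons:
            v = np.asarray(verts, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
                raise ValueError(
                    f"polygon {label!r} must have >= 3 (x, y) vertices"
                )

    def polygons_by_label(self, label: str) -> List[np.ndarray]:
        return [np.asarray(v, float) for l, v in self.polygons if l == label]

    def points_by_label(self, label: str) -> np.ndarray:
        pts = [(x, y) for l, x, y in self.points if l == label]
        return np.asarray(pts, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# ASAP XML
# ---------------------------------------------------------------------------

def read_annotation_xml(
    path: Union[str, Path], label_map: Optional[Dict[str, str]] = None
) -> AnnotationSet:
    """Parse an ASAP-dialect annotation XML file.

    ``label_map`` maps the file's annotation names/groups onto the
    canonical labels; unmapped labels raise (never silently dropped).
    Polygon-like annotations (Polygon, Rectangle, Spline) become
    polygons; Dot annotations become points.  Malformed XML raises a
    parse error that names the line.
    """
    label_map = label_map or {}
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as err:
        line, col = err.position
        raise ValueError(
            f"{path}: malformed XML at line {line}, column {col}: {err}"
        ) from err
    root = tree.getroot()
    polygons: List[Tuple[str, np.ndarray]] = []
    points: List[Tuple[str, float, float]] = []
    unmapped = set()
    for ann in root.iter("Annotation"):
        raw = ann.get("PartOfGroup") or ann.get("Name") or ""
        if raw in label_map:
            label = label_map[raw]
        elif raw.lower() in CANONICAL_LABELS:
            label = raw.lower()
        else:
            unmapped.add(raw)
            continue
        coords_el = ann.find("Coordinates")
        if coords_el is None:
            continue
        coords = sorted(
            (
                int(c.get("Order", i)),
                float(c.get("X")),
                float(c.get("Y")),
            )
            for i, c in enumerate(coords_el.findall("Coordinate"))
        )
        verts = np.asarray([(x, y) for _, x, y in coords], dtype=float)
        ann_type = (ann.get("Type") or "Polygon").lower()
        if ann_type == "dot":
            for _, x, y in coords:
                points.append((label, x, y))
        else:
            if verts.shape[0] < 3:
                raise ValueError(
                    f"{path}: polygon annotation {ann.get('Name')!r} has "
                    f"{verts.shape[0]} vertices (< 3)"
                )
            polygons.append((label, verts))
    if unmapped:
        raise ValueError(
            f"{path}: unmapped annotation labels {sorted(unmapped)}; "
            "extend label_map to cover them"
        )
    return AnnotationSet(polygons=polygons, points=points)


def write_annotation_xml(ann: AnnotationSet, path: Union[str, Path]) -> None:
    """Write an AnnotationSet in the ASAP XML dialect."""
    root = ET.Element("ASAP_Annotations")
    anns = ET.SubElement(root, "Annotations")
    for i, (label, verts) in enumerate(ann.polygons):
        el = ET.SubElement(
            anns,
            "Annotation",
            Name=f"Annotation {i}",
            Type="Polygon",
            PartOfGroup=label,
            Color="#F4FA58",
        )
        coords = ET.SubElement(el, "Coordinates")
        for order, (x, y) in enumerate(verts):
            ET.SubElement(
                coords,
                "Coordinate",
                Order=str(order),
                X=repr(float(x)),
                Y=repr(float(y)),
            )
    for i, (label, x, y) in enumerate(ann.points):
        el = ET.SubElement(
            anns,
            "Annotation",
            Name=f"Dot {i}",
            Type="Dot",
            PartOfGroup=label,
            Color="#0000FF",
        )
        coords = ET.SubElement(el, "Coordinates")
        ET.SubElement(
            coords, "Coordinate", Order="0", X=repr(float(x)), Y=repr(float(y))
        )
    groups = ET.SubElement(root, "AnnotationGroups")
    for label in sorted({l for l, _ in ann.polygons} | {l for l, *_ in ann.points}):
        ET.SubElement(
            groups, "Group", Name=label, PartOfGroup="None", Color="#64FE2E"
        )
    ET.ElementTree(root).write(
        str(path), encoding="utf-8", xml_declaration=True
    )


def rasterize_annotations(
    ann: AnnotationSet, frame: SlideFrame
) -> Tuple[BinaryMask, BinaryMask, LabelMask, PointSet]:
    """Burn annotations into rasters on the given frame.

    Polygon interiors are filled (a pixel is inside when its centre is);
    each ``tdlu`` polygon becomes one instance label, numbered in
    drawing order.  ``acinus`` points (and centroids of any acinus
    polygons) become the point set.  Vertices outside the frame raise,
    naming the offending polygons.
    """
    h, w = frame.shape
    bad = []
    for i, (label, verts) in enumerate(ann.polygons):
        v = np.asarray(verts, float)
        if (
            (v[:, 0] < -0.5).any()
            or (v[:, 0] > w - 0.5).any()
            or (v[:, 1] < -0.5).any()
            or (v[:, 1] > h - 0.5).any()
        ):
            bad.append(f"{label}[{i}]")
    if bad:
        raise ValueError(
            f"polygon vertices outside frame for: {', '.join(bad)}"
        )

    def fill(verts: np.ndarray) -> np.ndarray:
        # polygon2mask takes (row, col) = (y, x)
        return polygon2mask((h, w), verts[:, ::-1])

    tissue = np.zeros((h, w), dtype=bool)
    adipose = np.zeros((h, w), dtype=bool)
    labels = np.zeros((h, w), dtype=np.int32)
    next_label = 1
    acinus_pts: List[Tuple[float, float]] = []
    for label, verts in ann.polygons:
        v = np.asarray(verts, float)
        if label == "tissue":
            tissue |= fill(v)
        elif label == "adipose":
            adipose |= fill(v)
        elif label == "tdlu":
            m = fill(v)
            labels[m] = next_label
            next_label += 1
        elif label == "acinus":
            acinus_pts.append((float(v[:, 0].mean()), float(v[:, 1].mean())))
    for label, x, y in ann.points:
        if label == "acinus":
            acinus_pts.append((x, y))
    return (
        BinaryMask(frame, tissue),
        BinaryMask(frame, adipose),
        LabelMask(frame, labels),
        PointSet(frame, np.asarray(acinus_pts).reshape(-1, 2)),
    )


# ---------------------------------------------------------------------------
# raster masks
# ---------------------------------------------------------------------------

def write_mask(
    mask: Union[BinaryMask, LabelMask], path: Union[str, Path]
) -> None:
    """Write a mask losslessly: binary -> 0/1 uint8, labels -> uint16.

    Instance labels go to 16-bit single-channel TIFF (slide-level TDLU
    counts can exceed the 8-bit range); binary masks accept PNG or TIFF.
    """
    path = Path(path)
    if isinstance(mask, BinaryMask):
        arr = mask.pixels.astype(np.uint8)
    else:
        maxlab = int(mask.labels.max()) if mask.labels.size else 0
        if maxlab > np.iinfo(np.uint16).max:
            raise ValueError("too many instances for uint16 storage")
        arr = mask.labels.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    elif path.suffix.lower() == ".png":
        Image.fromarray(arr).save(str(path))
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")


def read_mask(
    path: Union[str, Path],
    frame: Optional[SlideFrame] = None,
    resolution_um_per_px: float = 0.16,
    kind: str = "auto",
) -> Union[BinaryMask, LabelMask]:
    """Read a single-channel mask image.

    ``kind`` is ``binary``, ``label``, or ``auto`` (labels iff any value
    exceeds 1 or the dtype is 16-bit).  Multi-channel images are
    rejected.  A ``frame`` may be supplied to pin the resolution; it
    must match the image dimensions.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(str(path)))
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel mask, got shape {arr.shape}"
        )
    h, w = arr.shape
    if frame is None:
        frame = SlideFrame(w, h, resolution_um_per_px)
    elif frame.shape != (h, w):
        raise ValueError(
            f"{path}: image shape {(h, w)} does not match frame "
            f"{frame.shape}"
        )
    if kind == "auto":
        kind = (
            "label"
            if arr.dtype.itemsize > 1 or (arr.size and arr.max() > 1)
            else "binary"
        )
    if kind == "binary":
        return BinaryMask(frame, arr > 0)
    return LabelMask(frame, arr.astype(np.int32))


# ---------------------------------------------------------------------------
# points
# ---------------------------------------------------------------------------

def write_points(
    points: PointSet, path: Union[str, Path], slide_id: str = "slide"
) -> None:
    """Write a point set as CSV (slide_id,x,y) or GeoJSON by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame(
            {
                "slide_id": slide_id,
                "x": points.points[:, 0],
                "y": points.points[:, 1],
            }
        )
        df.to_csv(path, index=False)
    elif path.suffix.lower() in (".json", ".geojson"):
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"slide_id": slide_id},
            }
            for x, y in points.points
        ]
        path.write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )
    else:
        raise ValueError(f"unsupported points format {path.suffix!r}")


def read_points(
    path: Union[str, Path],
    frame: SlideFrame,
    slide_id: Optional[str] = None,
) -> PointSet:
    """Read points from CSV (requires slide_id,x,y) or GeoJSON."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = {"slide_id", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(
                f"{path}: points CSV missing required columns "
                f"{sorted(missing)}"
            )
        if slide_id is not None:
            df = df[df["slide_id"] == slide_id]
        pts = df[["x", "y"]].to_numpy(dtype=float)
    elif path.suffix.lower() in (".json", ".geojson"):
        data = json.loads(path.read_text())
        pts = np.asarray(
            [
                f["geometry"]["coordinates"]
                for f in data.get("features", [])
                if f.get("geometry", {}).get("type") == "Point"
            ],
            dtype=float,
        ).reshape(-1, 2)
    else:
        raise ValueError(f"unsupported points format {path.suffix!r}")
    return PointSet(frame, pts)


# ---------------------------------------------------------------------------
# measures tables
# ---------------------------------------------------------------------------

def measures_to_frame(
    rows: Sequence[Tuple[str, MeasureSet]],
    qualitative: Optional[dict] = None,
) -> pd.DataFrame:
    """Assemble the per-slide measures table.

    ``qualitative`` optionally maps slide_id to a
    :class:`~tdluquant.qualitative.QualitativeResult`, adding the
    predominant-type / Baer columns.
    """
    records = []
    for slide_id, ms in rows:
        rec = {"slide_id": slide_id, **ms.as_dict()}
        if qualitative and slide_id in qualitative:
            q = qualitative[slide_id]
            rec["predominant_type"] = q.predominant_type
            rec["baer_category"] = q.baer_category
            for t in (1, 2, 3):
                rec[f"counts_type{t}"] = q.counts_by_type.get(t, 0)
        records.append(rec)
    return pd.DataFrame(records)


def write_measures(
    rows: Sequence[Tuple[str, MeasureSet]],
    path: Union[str, Path],
    config: Optional[dict] = None,
    qualitative: Optional[dict] = None,
) -> None:
    """Write the measures CSV plus a JSON sidecar with config provenance."""
    path = Path(path)
    measures_to_frame(rows, qualitative).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(config or {}, indent=2, default=str))


def read_measures(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"slide_id", *MeasureSet.CSV_FIELDS} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: measures CSV missing columns {sorted(missing)}"
        )
    return df


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_config(config: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
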