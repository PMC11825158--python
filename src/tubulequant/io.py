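"""Readers and writers for annotation exports, study designs and results.

Supported input layouts, one section per file/table group:

* GeoJSON FeatureCollection (RFC 7946), the export format of common
  annotation tools: Polygon features for the ROI and tubule outlines,
  Point features for germ-cell marks, with the role read from a
  configurable classification property (default ``classification.name``)
  and translated through a label map.
* Two plain CSV tables: a polygon table
  ``(section_id, object_id, role, vertex_index, x, y)`` and a point
  table ``(section_id, cell_id, marker, x, y)``.

Coordinates are multiplied by ``scale_mm_per_unit`` at read time so the
in-memory model is always in millimetres.  Metric tables round-trip
losslessly at 12 significant digits.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .metrics import SampleMetrics, SectionMetrics
from .model import (
    MARKERS,
    ConfigError,
    DataValidationError,
    GermCellMark,
    SectionAnnotation,
    StudyDesign,
    TubuleAnnotation,
    validate_polygon,
)

log = logging.getLogger(__name__)

#: Default translation from annotation-tool classification labels to roles.
DEFAULT_LABEL_MAP = {
    "ROI": "roi",
    "Region": "roi",
    "Tubule": "tubule",
    "AP2G": "cell:AP2G",
    "AP2y": "cell:AP2G",
    "MAGEA4": "cell:MAGEA4",
    "MAGE-A4": "cell:MAGEA4",
}

_ROLES = {"roi", "tubule", "cell:AP2G", "cell:MAGEA4"}


def _get_property(props: dict, dotted_path: str):
    cur = props
    for key in dotted_path.split("."):
        if not isinstance(cur, dict) or key not in cur:
            return None
        cur = cur[key]
    return cur


def _hull_roi(tubules: list[TubuleAnnotation], section_id: str):
    pts = np.concatenate(
        [np.asarray(t.outline.exterior.coords) for t in tubules], axis=0
    )
    log.info("section %s: no ROI feature; using convex hull of tubule outlines", section_id)
    return MultiPoint(pts).convex_hull


def read_section_geojson(
    path: str | Path,
    scale_mm_per_unit: float = 1.0,
    label_map: dict[str, str] | None = None,
    *,
    classification_property: str = "classification.name",
    sample_id: str | None = None,
) -> SectionAnnotation:
    """Read one annotated section from a GeoJSON FeatureCollection.

    Features with classification labels absent from ``label_map`` (or
    with unsupported geometry types) are skipped with a logged warning.
    When no ROI polygon is present, the convex hull of all tubule
    outlines stands in for it.
    """
    path = Path(path)
    if scale_mm_per_unit <= 0:
        raise ConfigError("scale_mm_per_unit must be positive")
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    bad = sorted(set(label_map.values()) - _ROLES)
    if bad:
        raise ConfigError(f"label_map assigns unsupported roles: {bad}")
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataValidationError(f"{path}: cannot parse GeoJSON: {exc}") from exc
    if not isinstance(data, dict) or data.get("type") != "FeatureCollection":
        raise DataValidationError(f"{path}: not a GeoJSON FeatureCollection")

    section_id = str(data.get("section_id") or path.stem)
    sample_id = str(sample_id or data.get("sample_id") or section_id)
    s = scale_mm_per_unit
    roi = None
    tubules: list[TubuleAnnotation] = []
    cells: list[GermCellMark] = []
    skipped = 0
    for i, feat in enumerate(data.get("features", [])):
        try:
            geom = feat["geometry"]
            gtype = geom["type"]
            props = feat.get("properties") or {}
        except (TypeError, KeyError) as exc:
            raise DataValidationError(f"{path}: malformed feature at index {i}: {exc}") from exc
        label = _get_property(props, classification_property)
        role = label_map.get(label)
        if role is None:
            skipped += 1
            log.warning("%s: feature %d skipped (unmapped label %r)", path.name, i, label)
            continue
        if role == "roi" or role == "tubule":
            if gtype != "Polygon":
                skipped += 1
                log.warning("%s: feature %d skipped (%s with geometry %s)", path.name, i, role, gtype)
                continue
            try:
                ring = np.asarray(geom["coordinates"][0], dtype=float) * s
                poly = validate_polygon(ring, context=f"{path.name} feature {i}")
            except (KeyError, IndexError, ValueError) as exc:
                raise DataValidationError(f"{path}: malformed Polygon at feature index {i}: {exc}") from exc
            if role == "roi":
                roi = poly
            else:
                tid = str(props.get("name") or f"T{len(tubules):04d}")
                intact = props.get("intact")
                tubules.append(TubuleAnnotation(tid, poly, None if intact is None else bool(intact)))
        else:  # cell:<marker>
            if gtype != "Point":
                skipped += 1
                log.warning("%s: feature %d skipped (cell with geometry %s)", path.name, i, gtype)
                continue
            marker = role.split(":", 1)[1]
            cid = str(props.get("name") or f"C{len(cells):05d}")
            x, y = (float(v) * s for v in geom["coordinates"][:2])
            cells.append(GermCellMark(cid, x, y, marker))
    if skipped:
        log.warning("%s: skipped %d unmapped/unsupported feature(s)", path.name, skipped)
    if not tubules:
        raise DataValidationError(f"{path}: no tubule features found (empty section)")
    if roi is None:
        roi = _hull_roi(tubules, section_id)
    return SectionAnnotation(
        section_id=section_id,
        sample_id=sample_id,
        roi=roi,
        tubules=tubules,
        cells=cells,
        scale_mm_per_unit=s,
    )


def read_section_tables(
    polygon_table: str | Path,
    point_table: str | Path,
    scale_mm_per_unit: float = 1.0,
) -> SectionAnnotation:
    """Read one section from the two-table CSV layout.

    Vertices are ordered by ``vertex_index`` (row order is irrelevant);
    semantics are identical to the GeoJSON reader.
    """
    if scale_mm_per_unit <= 0:
        raise ConfigError("scale_mm_per_unit must be positive")
    polys = pd.read_csv(polygon_table)
    pts = pd.read_csv(point_table)
    need_p = {"section_id", "object_id", "role", "vertex_index", "x", "y"}
    need_c = {"section_id", "cell_id", "marker", "x", "y"}
    if not need_p <= set(polys.columns):
        raise DataValidationError(f"{polygon_table}: missing columns {sorted(need_p - set(polys.columns))}")
    if not need_c <= set(pts.columns):
        raise DataValidationError(f"{point_table}: missing columns {sorted(need_c - set(pts.columns))}")
    if polys.duplicated(["object_id", "vertex_index"]).any():
        dup = polys[polys.duplicated(["object_id", "vertex_index"])].iloc[0]
        raise DataValidationError(
            f"{polygon_table}: duplicate (object_id, vertex_index) = "
            f"({dup['object_id']!r}, {dup['vertex_index']!r})"
        )
    bad = pts[~pts["marker"].isin(MARKERS)]
    if len(bad):
        raise DataValidationError(
            f"{point_table}: row {bad.index[0]}: unknown marker {bad.iloc[0]['marker']!r}"
        )
    section_ids = set(polys["section_id"].astype(str)) | set(pts["section_id"].astype(str))
    if len(section_ids) != 1:
        raise DataValidationError(f"tables must describe exactly one section, got {sorted(section_ids)}")
    section_id = section_ids.pop()
    s = scale_mm_per_unit

    roi = None
    tubules: list[TubuleAnnotation] = []
    for (oid,), sub in polys.groupby(["object_id"], sort=True):
        sub = sub.sort_values("vertex_index")
        ring = sub[["x", "y"]].to_numpy(float) * s
        role = str(sub["role"].iloc[0])
        poly = validate_polygon(ring, context=f"object {oid!r}")
        if role == "roi":
            roi = poly
        elif role == "tubule":
            intact = None
            if "intact" in sub.columns and not pd.isna(sub["intact"].iloc[0]):
                raw = sub["intact"].iloc[0]
                intact = raw if isinstance(raw, bool) else str(raw).strip().lower() in ("true", "1")
            tubules.append(TubuleAnnotation(str(oid), poly, intact))
        else:
            raise DataValidationError(f"object {oid!r}: unknown role {role!r}")
    cells = [
        GermCellMark(str(r.cell_id), float(r.x) * s, float(r.y) * s, str(r.marker))
        for r in pts.itertuples()
    ]
    if not tubules:
        raise DataValidationError(f"{polygon_table}: no tubule objects found (empty section)")
    if roi is None:
        roi = _hull_roi(tubules, section_id)
    return SectionAnnotation(section_id, section_id, roi, tubules, cells, s)


def read_design(path: str | Path) -> StudyDesign:
    """Read and validate a study-design CSV
    (sample_id, subject_id, condition, tissue_type)."""
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise DataValidationError(f"{path}: cannot read design CSV: {exc}") from exc
    return StudyDesign(df)


# ---------------------------------------------------------------------------
# writers

_G12 = "{:.12g}".format


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return _G12(v)
    return str(v)


_SECTION_COLUMNS = [
    "section_id", "sample_id", "n_tubules_analysed", "n_round",
    "total_tubular_area_mm2", "round_tubular_area_mm2", "n_cells_total",
    "n_cells_in_round", "n_round_with_cells",
    "method1", "method2", "method3", "method4",
    "n_cells_AP2G", "n_cells_MAGEA4", "qc_flags",
]

_SAMPLE_COLUMNS = [
    "sample_id", "subject_id", "condition", "tissue_type", "n_sections",
    "n_round_total", "total_tubular_area_mm2",
    "method1", "method2", "method3", "method4", "qc_flags",
]


def _section_row(m: SectionMetrics) -> list[str]:
    d = dataclasses.asdict(m)
    row = [d[c] for c in _SECTION_COLUMNS[:13]]
    row += [m.cells_by_marker.get("AP2G", 0), m.cells_by_marker.get("MAGEA4", 0)]
    row.append(";".join(sorted(m.qc_flags)))
    return [_fmt(v) for v in row]


def _sample_row(m: SampleMetrics) -> list[str]:
    d = dataclasses.asdict(m)
    row = [d[c] for c in _SAMPLE_COLUMNS[:-1]]
    row.append(";".join(sorted(m.qc_flags)))
    return [_fmt(v) for v in row]


def write_metrics_table(records: list, path: str | Path) -> None:
    """Write section- or sample-level metrics to CSV (stable column order,
    missing metrics as empty fields, floats at 12 significant digits)."""
    if not records:
        raise ConfigError("write_metrics_table: no records to write")
    kinds = {type(r) for r in records}
    if kinds == {SectionMetrics}:
        columns, rowfn = _SECTION_COLUMNS, _section_row
    elif kinds == {SampleMetrics}:
        columns, rowfn = _SAMPLE_COLUMNS, _sample_row
    else:
        raise ConfigError("write_metrics_table: records must all be one level (section or sample)")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(columns)
        for r in records:
            w.writerow(rowfn(r))


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV back; empty cells become NaN."""
    return pd.read_csv(path)


def write_section_geojson(section: SectionAnnotation, path: str | Path) -> None:
    """Write a section in the GeoJSON layout the reader accepts.

    Coordinates are written in millimetres (read back with scale 1).
    Output is deterministic: fixed key order, repr-exact floats.
    """
    def classif(name: str) -> dict:
        return {"classification": {"name": name}}

    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(xy) for xy in section.roi.exterior.coords]],
            },
            "properties": {**classif("ROI"), "name": "ROI"},
        }
    ]
    for t in section.tubules:
        props = {**classif("Tubule"), "name": t.tubule_id}
        if t.intact_flag is not None:
            props["intact"] = t.intact_flag
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(xy) for xy in t.outline.exterior.coords]],
                },
                "properties": props,
            }
        )
    for c in section.cells:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [c.x, c.y]},
                "properties": {**classif(c.marker), "name": c.cell_id},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "section_id": section.section_id,
        "sample_id": section.sample_id,
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=None, separators=(",", ":")))


def write_section_tables(
    section: SectionAnnotation, polygon_path: str | Path, point_path: str | Path
) -> None:
    """Write a section in the two-table CSV layout (millimetre coordinates)."""
    with open(polygon_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["section_id", "object_id", "role", "vertex_index", "x", "y", "intact"])
        objects = [("__roi__", "roi", section.roi, None)] + [
            (t.tubule_id, "tubule", t.outline, t.intact_flag) for t in section.tubules
        ]
        for oid, role, poly, intact in objects:
            coords = list(poly.exterior.coords)[:-1]
            for k, (x, y) in enumerate(coords):
                # repr round-trips floats exactly, keeping the two export
                # formats bit-equivalent
                w.writerow([section.section_id, oid, role, k, repr(x), repr(y),
                            "" if intact is None else intact])
    with open(point_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["section_id", "cell_id", "marker", "x", "y"])
        for c in section.cells:
            w.writerow([section.section_id, c.cell_id, c.marker, repr(c.x), repr(c.y)])
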