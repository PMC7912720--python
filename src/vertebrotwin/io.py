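"""Reading and writing vessel-centerline networks.

Two plain-text formats are supported:

* VTP — VTK PolyData XML (ascii), one PolyLine cell per branch, a per-point
  ``Radius`` array, a per-cell ``BranchLabel`` string array in FieldData and
  the two landmarks (confluence, basilar tip) as FieldData float arrays.
  Only the subset needed for centerline networks is implemented.
* CSV — ``branch_label,point_index,x_mm,y_mm,z_mm,radius_mm`` with a
  mandatory header; full decimal precision via ``repr``.

``read_network`` returns a :class:`VesselNetwork` when the three canonical
labels are present, otherwise the raw list of centerlines for
:func:`~vertebrotwin.branches.identify_branches`.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .centerline import Centerline, VesselNetwork

_CANONICAL = ("left_va", "right_va", "ba")


class NetworkParseError(ValueError):
    pass


def _labelled_items(obj) -> list[tuple[str, Centerline]]:
    if isinstance(obj, VesselNetwork):
        items = list(obj.vessels().items())
        items += [(f"extra_{i}", b) for i, b in enumerate(obj.extra_branches)]
        return items
    return [(f"branch_{i}", b) for i, b in enumerate(obj)]


def _assemble(labelled: dict[str, Centerline], confluence=None, basilar_tip=None):
    if all(k in labelled for k in _CANONICAL):
        extras = tuple(v for k, v in labelled.items() if k not in _CANONICAL)
        ba = labelled["ba"]
        return VesselNetwork(
            left_va=labelled["left_va"],
            right_va=labelled["right_va"],
            ba=ba,
            confluence=ba.points[0] if confluence is None else confluence,
            basilar_tip=ba.points[-1] if basilar_tip is None else basilar_tip,
            extra_branches=extras,
        )
    return list(labelled.values())


# ---------------------------------------------------------------- CSV

def write_network_csv(obj, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["branch_label", "point_index", "x_mm", "y_mm", "z_mm", "radius_mm"])
        for label, cl in _labelled_items(obj):
            for i, (p, r) in enumerate(zip(cl.points, cl.radii)):
                w.writerow([label, i, repr(float(p[0])), repr(float(p[1])), repr(float(p[2])), repr(float(r))])


def read_network_csv(path):
    by_label: dict[str, list] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:6]] != [
            "branch_label", "point_index", "x_mm", "y_mm", "z_mm", "radius_mm",
        ]:
            raise NetworkParseError(f"{path}: missing or malformed header row")
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 6:
                raise NetworkParseError(f"{path}: row {row_no}: expected 6 columns, got {len(row)}")
            label = row[0]
            try:
                vals = [float(v) for v in row[2:6]]
            except ValueError as exc:
                raise NetworkParseError(f"{path}: row {row_no}: non-numeric value ({exc})") from None
            by_label.setdefault(label, []).append(vals)
    if not by_label:
        raise NetworkParseError(f"{path}: no centerline points")
    labelled = {
        label: Centerline(np.array(rows)[:, :3], np.array(rows)[:, 3]) for label, rows in by_label.items()
    }
    return _assemble(labelled)


# ---------------------------------------------------------------- VTP

def _fmt_floats(arr) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(arr).ravel())


def _encode_strings(strings) -> tuple[str, int]:
    """VTK ascii String arrays are NUL-terminated byte values."""
    data = b"".join(s.encode() + b"\x00" for s in strings)
    return " ".join(str(b) for b in data), len(data)


def _decode_strings(text: str) -> list[str]:
    data = bytes(int(tok) for tok in text.split())
    return [s.decode() for s in data.split(b"\x00") if s]


def write_network_vtp(obj, path) -> None:
    items = _labelled_items(obj)
    points = np.vstack([cl.points for _, cl in items])
    radii = np.concatenate([cl.radii for _, cl in items])
    counts = [cl.n_points for _, cl in items]
    offsets = np.cumsum(counts)
    connectivity = np.arange(points.shape[0])

    root = ET.Element("VTKFile", type="PolyData", version="1.0", byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    field = ET.SubElement(poly, "FieldData")
    labels_txt, labels_len = _encode_strings([label for label, _ in items])
    ET.SubElement(
        field, "DataArray", type="String", Name="BranchLabel",
        NumberOfTuples=str(labels_len), format="ascii",
    ).text = labels_txt
    if isinstance(obj, VesselNetwork):
        for name, val in (("Confluence", obj.confluence), ("BasilarTip", obj.basilar_tip)):
            ET.SubElement(
                field, "DataArray", type="Float64", Name=name,
                NumberOfTuples="3", format="ascii",
            ).text = _fmt_floats(val)
    piece = ET.SubElement(
        poly, "Piece",
        NumberOfPoints=str(points.shape[0]), NumberOfVerts="0",
        NumberOfLines=str(len(items)), NumberOfStrips="0", NumberOfPolys="0",
    )
    pdata = ET.SubElement(piece, "PointData", Scalars="Radius")
    ET.SubElement(
        pdata, "DataArray", type="Float64", Name="Radius", format="ascii"
    ).text = _fmt_floats(radii)
    pts = ET.SubElement(piece, "Points")
    ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    ).text = _fmt_floats(points)
    lines = ET.SubElement(piece, "Lines")
    ET.SubElement(
        lines, "DataArray", type="Int64", Name="connectivity", format="ascii"
    ).text = " ".join(str(i) for i in connectivity)
    ET.SubElement(
        lines, "DataArray", type="Int64", Name="offsets", format="ascii"
    ).text = " ".join(str(i) for i in offsets)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _find_array(parent, name):
    for arr in parent.iter("DataArray"):
        if arr.get("Name") == name:
            return arr
    return None


def read_network_vtp(path):
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise NetworkParseError(f"{path}: not valid XML ({exc})") from None
    piece = root.find(".//Piece")
    if piece is None:
        raise NetworkParseError(f"{path}: no PolyData Piece element")
    pts_arr = piece.find("./Points/DataArray")
    if pts_arr is None or pts_arr.text is None:
        raise NetworkParseError(f"{path}: missing Points array")
    try:
        points = np.fromstring(pts_arr.text, sep=" ").reshape(-1, 3)
    except ValueError:
        raise NetworkParseError(f"{path}: malformed Points array") from None
    rad_arr = _find_array(piece.find("PointData") or piece, "Radius")
    if rad_arr is None or rad_arr.text is None:
        raise NetworkParseError(f"{path}: missing 'Radius' point-data array")
    radii = np.fromstring(rad_arr.text, sep=" ")
    if radii.shape[0] != points.shape[0]:
        raise NetworkParseError(f"{path}: Radius length {radii.shape[0]} != point count {points.shape[0]}")
    conn_arr = _find_array(piece.find("Lines") or piece, "connectivity")
    off_arr = _find_array(piece.find("Lines") or piece, "offsets")
    if conn_arr is None or off_arr is None:
        raise NetworkParseError(f"{path}: missing PolyLine connectivity/offsets")
    connectivity = np.fromstring(conn_arr.text, sep=" ").astype(int)
    offsets = np.fromstring(off_arr.text, sep=" ").astype(int)

    field = root.find(".//FieldData")
    labels = None
    confluence = basilar_tip = None
    if field is not None:
        lab = _find_array(field, "BranchLabel")
        if lab is not None and lab.text:
            labels = _decode_strings(lab.text)
        for nm in ("Confluence", "BasilarTip"):
            arr = _find_array(field, nm)
            if arr is not None and arr.text:
                vec = np.fromstring(arr.text, sep=" ")
                if nm == "Confluence":
                    confluence = vec
                else:
                    basilar_tip = vec

    labelled: dict[str, Centerline] = {}
    start = 0
    for k, end in enumerate(offsets):
        idx = connectivity[start:end]
        label = labels[k] if labels and k < len(labels) else f"branch_{k}"
        labelled[label] = Centerline(points[idx], radii[idx])
        start = end
    return _assemble(labelled, confluence, basilar_tip)


# ---------------------------------------------------------------- dispatch

def write_network(obj, path, format: str | None = None) -> None:
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "vtp":
        write_network_vtp(obj, path)
    elif fmt == "csv":
        write_network_csv(obj, path)
    else:
        raise ValueError(f"unsupported network format {fmt!r}")


def read_network(path, format: str | None = None):
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if fmt == "vtp":
        return read_network_vtp(path)
    if fmt == "csv":
        return read_network_csv(path)
    raise ValueError(f"unsupported network format {fmt!r}")
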