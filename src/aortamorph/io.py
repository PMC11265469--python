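"""Surface and volume mesh I/O: STL (ASCII + binary), PLY (ASCII), VTP, VTU.

Readers scale coordinates by ``unit_scale`` (default 1e-3: clinical
segmentation exports are assumed to be millimeter STL; the internal unit is
meters) and merge duplicate vertices within 1e-9 m, which reconstructs shared
connectivity from per-facet formats like STL.

Region labels survive a VTP or PLY round trip (stored as an integer cell
array plus a label table); STL cannot carry them and a warning is logged.
"""

from __future__ import annotations

import logging
import os
import struct
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import TetMesh, TriSurface, merge_duplicate_vertices

logger = logging.getLogger(__name__)

_MERGE_TOL = 1e-9  # m; below segmentation resolution, above float noise


class FormatError(ValueError):
    """Raised when a file does not parse as the named format."""


def _detect_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = Path(path).suffix.lower().lstrip(".")
    if ext not in {"stl", "ply", "vtp"}:
        raise FormatError(f"cannot infer surface format from extension {ext!r}")
    return ext


def read_surface(
    path: str | os.PathLike,
    fmt: str | None = None,
    unit_scale: float = 1e-3,
    merge_tol: float = _MERGE_TOL,
) -> TriSurface:
    """Read a triangulated surface; coordinates are multiplied by ``unit_scale``."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read surface file: {path}")
    fmt = _detect_format(path, fmt)
    if fmt == "stl":
        surf = _read_stl(path)
    elif fmt == "ply":
        surf = _read_ply(path)
    elif fmt == "vtp":
        surf = _read_vtp(path)
    else:
        raise FormatError(f"unsupported surface format {fmt!r}")
    surf.vertices *= float(unit_scale)
    if merge_tol > 0:
        surf = merge_duplicate_vertices(surf, merge_tol)
    return surf


def write_surface(surface: TriSurface, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a surface; the file re-reads (with unit_scale=1) to identical connectivity."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "stl":
        if not np.all(surface.region_labels == surface.region_labels[0] if surface.n_faces else True):
            logger.warning("STL cannot store region labels; labels dropped on write to %s", path)
        _write_stl_ascii(surface, path)
    elif fmt == "ply":
        _write_ply(surface, path)
    elif fmt == "vtp":
        _write_vtp(surface, path)
    else:
        raise FormatError(f"unsupported surface format {fmt!r}")


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def _read_stl(path: Path) -> TriSurface:
    raw = path.read_bytes()
    if len(raw) >= 84:
        (ntri,) = struct.unpack("<I", raw[80:84])
        if len(raw) == 84 + 50 * ntri:
            return _parse_stl_binary(raw, ntri)
    return _parse_stl_ascii(raw, path)


def _parse_stl_binary(raw: bytes, ntri: int) -> TriSurface:
    rec = np.frombuffer(raw[84:], dtype=np.uint8).reshape(ntri, 50)
    tri = rec[:, 12:48].copy().view("<f4").reshape(ntri, 3, 3).astype(np.float64)
    verts = tri.reshape(-1, 3)
    faces = np.arange(3 * ntri, dtype=np.int64).reshape(ntri, 3)
    return TriSurface(verts, faces)


def _parse_stl_ascii(raw: bytes, path: Path) -> TriSurface:
    try:
        text = raw.decode("ascii", errors="strict")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: neither binary nor ASCII STL") from exc
    coords: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("vertex"):
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}: malformed STL vertex line {line!r}")
            coords.append([float(p) for p in parts[1:]])
    if not coords or len(coords) % 3:
        raise FormatError(f"{path}: ASCII STL with {len(coords)} vertex lines")
    verts = np.array(coords, dtype=np.float64)
    faces = np.arange(len(verts), dtype=np.int64).reshape(-1, 3)
    return TriSurface(verts, faces)


def _write_stl_ascii(surface: TriSurface, path: Path) -> None:
    tri = surface.vertices[surface.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    with np.errstate(invalid="ignore"):
        n = np.where(norms[:, None] > 0, cross / norms[:, None], 0.0)
    lines = ["solid aortamorph"]
    for f in range(surface.n_faces):
        lines.append(f"  facet normal {n[f,0]:.9e} {n[f,1]:.9e} {n[f,2]:.9e}")
        lines.append("    outer loop")
        for v in tri[f]:
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid aortamorph\n")
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# PLY (ASCII)
# ---------------------------------------------------------------------------

def _read_ply(path: Path) -> TriSurface:
    with open(path, "r") as fh:
        if fh.readline().strip() != "ply":
            raise FormatError(f"{path}: missing 'ply' magic")
        n_vert = n_face = 0
        label_table: dict[int, str] = {}
        face_props: list[str] = []
        in_face = False
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format":
                if tok[1] != "ascii":
                    raise FormatError(f"{path}: only ASCII PLY is supported")
            elif tok[0] == "comment" and len(tok) >= 4 and tok[1] == "region":
                label_table[int(tok[2])] = " ".join(tok[3:])
            elif tok[0] == "element":
                in_face = tok[1] == "face"
                if tok[1] == "vertex":
                    n_vert = int(tok[2])
                elif tok[1] == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and in_face and tok[1] != "list":
                face_props.append(tok[-1])
            elif tok[0] == "end_header":
                break
        verts = np.array(
            [[float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)]
        )
        faces = []
        regions = []
        for _ in range(n_face):
            tok = fh.readline().split()
            cnt = int(tok[0])
            if cnt != 3:
                raise FormatError(f"{path}: non-triangular face (n={cnt})")
            faces.append([int(t) for t in tok[1:4]])
            if "region" in face_props:
                regions.append(int(tok[4]))
    labels = None
    if regions and label_table:
        labels = np.array([label_table.get(r, "wall") for r in regions])
    return TriSurface(verts, np.array(faces, dtype=np.int64), labels)


def _write_ply(surface: TriSurface, path: Path) -> None:
    uniq = list(dict.fromkeys(surface.region_labels.tolist()))
    code = {lab: i for i, lab in enumerate(uniq)}
    head = ["ply", "format ascii 1.0"]
    head += [f"comment region {i} {lab}" for lab, i in code.items()]
    head += [
        f"element vertex {surface.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {surface.n_faces}",
        "property list uchar int vertex_indices",
        "property int region",
        "end_header",
    ]
    body = [f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in surface.vertices]
    body += [
        f"3 {f[0]} {f[1]} {f[2]} {code[lab]}"
        for f, lab in zip(surface.faces, surface.region_labels)
    ]
    path.write_text("\n".join(head + body) + "\n")


# ---------------------------------------------------------------------------
# VTP (XML PolyData, ASCII)
# ---------------------------------------------------------------------------

def _ascii_array(parent: ET.Element, name: str | None, values: np.ndarray, vtype: str,
                 ncomp: int | None = None) -> None:
    da = ET.SubElement(parent, "DataArray", type=vtype, format="ascii")
    if name:
        da.set("Name", name)
    if ncomp:
        da.set("NumberOfComponents", str(ncomp))
    flat = np.asarray(values).ravel()
    if vtype.startswith("Float"):
        da.text = " ".join(f"{v:.17g}" for v in flat)
    else:
        da.text = " ".join(str(int(v)) for v in flat)


def _write_vtp(surface: TriSurface, path: Path) -> None:
    uniq = list(dict.fromkeys(surface.region_labels.tolist()))
    code = {lab: i for i, lab in enumerate(uniq)}
    region_id = np.array([code[lab] for lab in surface.region_labels], dtype=np.int32)
    table = ";".join(uniq).encode()

    root = ET.Element("VTKFile", type="PolyData", version="1.0", byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        poly, "Piece",
        NumberOfPoints=str(surface.n_vertices), NumberOfVerts="0",
        NumberOfLines="0", NumberOfStrips="0", NumberOfPolys=str(surface.n_faces),
    )
    fd = ET.SubElement(piece, "FieldData")
    _ascii_array(fd, "region_table", np.frombuffer(table, dtype=np.int8), "Int8")
    if surface.phase_time is not None:
        _ascii_array(fd, "phase_time", np.array([surface.phase_time]), "Float64")
    pts = ET.SubElement(piece, "Points")
    _ascii_array(pts, None, surface.vertices, "Float64", ncomp=3)
    cd = ET.SubElement(piece, "CellData")
    _ascii_array(cd, "region_id", region_id, "Int32")
    polys = ET.SubElement(piece, "Polys")
    _ascii_array(polys, "connectivity", surface.faces, "Int64")
    _ascii_array(polys, "offsets", 3 * np.arange(1, surface.n_faces + 1), "Int64")
    ET.ElementTree(root).write(path, xml_declaration=True)


def _read_vtp(path: Path) -> TriSurface:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not a VTP/XML file") from exc
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise FormatError(f"{path}: no PolyData piece")

    def arr(xpath: str, dtype) -> np.ndarray | None:
        el = piece.find(xpath)
        if el is None or el.text is None:
            return None
        txt = el.text.split()
        return np.array(txt, dtype=dtype) if txt else np.empty(0, dtype=dtype)

    verts = arr("Points/DataArray", float)
    conn = arr("Polys/DataArray[@Name='connectivity']", np.int64)
    offs = arr("Polys/DataArray[@Name='offsets']", np.int64)
    if verts is None or conn is None or offs is None:
        raise FormatError(f"{path}: missing points or connectivity")
    if np.any(np.diff(np.concatenate([[0], offs])) != 3):
        raise FormatError(f"{path}: non-triangular polys")
    faces = conn.reshape(-1, 3)
    labels = None
    rid = arr("CellData/DataArray[@Name='region_id']", np.int64)
    tbl = arr("FieldData/DataArray[@Name='region_table']", np.int8)
    if rid is not None and tbl is not None:
        names = tbl.astype(np.uint8).tobytes().decode().split(";")
        labels = np.array([names[i] for i in rid])
    pt = arr("FieldData/DataArray[@Name='phase_time']", float)
    return TriSurface(
        verts.reshape(-1, 3), faces, labels,
        phase_time=float(pt[0]) if pt is not None and pt.size else None,
    )


# ---------------------------------------------------------------------------
# VTU (tet meshes, write-only)
# ---------------------------------------------------------------------------

def write_tetmesh(mesh: TetMesh, path: str | os.PathLike) -> None:
    """Write a tetrahedral mesh as ASCII XML VTU."""
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="1.0",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(len(mesh.nodes)),
                          NumberOfCells=str(len(mesh.tets)))
    pts = ET.SubElement(piece, "Points")
    _ascii_array(pts, None, mesh.nodes, "Float64", ncomp=3)
    cells = ET.SubElement(piece, "Cells")
    _ascii_array(cells, "connectivity", mesh.tets, "Int64")
    _ascii_array(cells, "offsets", 4 * np.arange(1, len(mesh.tets) + 1), "Int64")
    _ascii_array(cells, "types", np.full(len(mesh.tets), 10), "UInt8")
    ET.ElementTree(root).write(path, xml_declaration=True)
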