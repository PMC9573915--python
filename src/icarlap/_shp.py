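"""Minimal ESRI shapefile I/O for polygon layers.

Reads shape types 5/15/25 (Polygon, PolygonZ, PolygonM) from ``.shp`` plus
attributes from the sibling ``.dbf``; writes plain 2-D polygons with a
single character attribute.  Only what the contiguity builder needs — no
projections, no spatial index.
"""

from __future__ import annotations

import struct
from pathlib import Path

__all__ = ["read_polygon_shapefile", "write_polygon_shapefile", "ShapefileError"]

_POLYGON_TYPES = {5, 15, 25}


class ShapefileError(ValueError):
    pass


def _read_shp(path: Path) -> list[list[list[tuple[float, float]]]]:
    """Return, per record, the list of rings (each a list of (x, y))."""
    buf = path.read_bytes()
    if len(buf) < 100:
        raise ShapefileError(f"{path}: truncated header")
    magic, = struct.unpack(">i", buf[:4])
    if magic != 9994:
        raise ShapefileError(f"{path}: not a shapefile (bad magic {magic})")
    file_type, = struct.unpack("<i", buf[32:36])
    if file_type not in _POLYGON_TYPES and file_type != 0:
        raise ShapefileError(
            f"{path}: shape type {file_type} is not polygonal"
        )
    shapes: list[list[list[tuple[float, float]]]] = []
    pos = 100
    while pos + 8 <= len(buf):
        _recno, content_len = struct.unpack(">ii", buf[pos : pos + 8])
        pos += 8
        end = pos + 2 * content_len
        if end > len(buf):
            raise ShapefileError(f"{path}: truncated record at byte {pos}")
        shape_type, = struct.unpack("<i", buf[pos : pos + 4])
        if shape_type == 0:  # null shape
            shapes.append([])
        elif shape_type in _POLYGON_TYPES:
            p = pos + 4 + 32  # skip bounding box
            num_parts, num_points = struct.unpack("<ii", buf[p : p + 8])
            p += 8
            parts = struct.unpack(f"<{num_parts}i", buf[p : p + 4 * num_parts])
            p += 4 * num_parts
            xy = struct.unpack(f"<{2 * num_points}d", buf[p : p + 16 * num_points])
            rings = []
            bounds = list(parts) + [num_points]
            for a, b in zip(bounds[:-1], bounds[1:]):
                rings.append([(xy[2 * k], xy[2 * k + 1]) for k in range(a, b)])
            shapes.append(rings)
        else:
            raise ShapefileError(f"{path}: unsupported shape type {shape_type}")
        pos = end
    return shapes


def _read_dbf(path: Path) -> tuple[list[str], list[dict[str, str]]]:
    """Return (field names, records as string dicts)."""
    buf = path.read_bytes()
    if len(buf) < 32:
        raise ShapefileError(f"{path}: truncated DBF header")
    n_rec, = struct.unpack("<I", buf[4:8])
    header_size, record_size = struct.unpack("<HH", buf[8:12])
    fields: list[tuple[str, int]] = []
    pos = 32
    while pos < header_size - 1 and buf[pos] != 0x0D:
        desc = buf[pos : pos + 32]
        name = desc[:11].split(b"\x00")[0].decode("ascii", "replace")
        length = desc[16]
        fields.append((name, length))
        pos += 32
    records: list[dict[str, str]] = []
    pos = header_size
    for _ in range(n_rec):
        if pos + record_size > len(buf):
            raise ShapefileError(f"{path}: truncated DBF records")
        rec = buf[pos : pos + record_size]
        if rec[0:1] != b"*":  # not deleted
            out, off = {}, 1
            for name, length in fields:
                raw = rec[off : off + length]
                out[name] = raw.decode("latin-1").strip()
                off += length
            records.append(out)
        pos += record_size
    return [f for f, _ in fields], records


def read_polygon_shapefile(
    path: str | Path, label_field: str | None = None
) -> tuple[list[str], list[list[list[tuple[float, float]]]]]:
    """Read polygons and one label per record.

    ``label_field`` selects the DBF attribute used as the region label; when
    omitted the first DBF field is used, or the record number if no ``.dbf``
    is present.
    """
    path = Path(path)
    if not path.exists():
        raise ShapefileError(f"shapefile not found: {path}")
    shapes = _read_shp(path)
    dbf = path.with_suffix(".dbf")
    if dbf.exists():
        field_names, records = _read_dbf(dbf)
        if len(records) != len(shapes):
            raise ShapefileError(
                f"{path}: {len(shapes)} shapes but {len(records)} DBF records"
            )
        if label_field is None:
            label_field = field_names[0]
        elif label_field not in field_names:
            raise ShapefileError(
                f"{dbf}: no attribute {label_field!r}; available: {field_names}"
            )
        labels = [r[label_field] for r in records]
    else:
        if label_field is not None:
            raise ShapefileError(f"{dbf} missing, cannot resolve {label_field!r}")
        labels = [str(i) for i in range(len(shapes))]
    return labels, shapes


def write_polygon_shapefile(
    path: str | Path,
    rings_per_poly: list[list[list[tuple[float, float]]]],
    labels: list[str],
    label_field: str = "NAME",
) -> None:
    """Write 2-D polygons with a single text attribute (.shp/.shx/.dbf)."""
    path = Path(path)
    if len(labels) != len(rings_per_poly):
        raise ShapefileError("labels and polygons differ in length")

    rec_payloads = []
    for rings in rings_per_poly:
        closed = []
        for ring in rings:
            r = [(float(x), float(y)) for x, y in ring]
            if r[0] != r[-1]:
                r.append(r[0])
            closed.append(r)
        pts = [p for r in closed for p in r]
        xs, ys = [p[0] for p in pts], [p[1] for p in pts]
        parts, acc = [], 0
        for r in closed:
            parts.append(acc)
            acc += len(r)
        payload = struct.pack("<i", 5)
        payload += struct.pack("<4d", min(xs), min(ys), max(xs), max(ys))
        payload += struct.pack("<ii", len(parts), len(pts))
        payload += struct.pack(f"<{len(parts)}i", *parts)
        for x, y in pts:
            payload += struct.pack("<2d", x, y)
        rec_payloads.append(payload)

    xs = [p[0] for rings in rings_per_poly for r in rings for p in r]
    ys = [p[1] for rings in rings_per_poly for r in rings for p in r]
    bbox = (min(xs), min(ys), max(xs), max(ys))

    shp = bytearray()
    shx = bytearray()
    offset_words = 50
    for recno, payload in enumerate(rec_payloads, start=1):
        clen = len(payload) // 2
        shx += struct.pack(">ii", offset_words, clen)
        shp += struct.pack(">ii", recno, clen)
        shp += payload
        offset_words += 4 + clen

    def header(total_words: int) -> bytes:
        h = struct.pack(">i", 9994) + b"\x00" * 20 + struct.pack(">i", total_words)
        h += struct.pack("<ii", 1000, 5)
        h += struct.pack("<4d", *bbox) + struct.pack("<4d", 0, 0, 0, 0)
        return h

    path.with_suffix(".shp").write_bytes(header(50 + len(shp) // 2) + bytes(shp))
    path.with_suffix(".shx").write_bytes(header(50 + len(shx) // 2) + bytes(shx))

    width = max(1, min(254, max(len(l) for l in labels)))
    n_rec = len(labels)
    header_size = 32 + 32 + 1
    record_size = 1 + width
    dbf = bytearray()
    dbf += bytes([0x03, 95, 7, 26])
    dbf += struct.pack("<I", n_rec)
    dbf += struct.pack("<HH", header_size, record_size)
    dbf += b"\x00" * 20
    name = label_field.encode("ascii")[:10]
    dbf += name + b"\x00" * (11 - len(name)) + b"C" + b"\x00" * 4
    dbf += bytes([width]) + b"\x00" * 15
    dbf += b"\x0d"
    for lab in labels:
        dbf += b" " + lab.encode("latin-1")[:width].ljust(width)
    dbf += b"\x1a"
    path.with_suffix(".dbf").write_bytes(bytes(dbf))
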