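"""Minimal codec for the binary ImageJ ``.roi`` format.

Supports the subset needed for imported pixel-mask ROIs: rectangle, oval,
polygon and freehand outlines.  Line, polyline, angle and point ROIs carry
no interior and are rejected by name.  All fields are big-endian; the
64-byte header is followed, for polygonal types, by ``n`` x-offsets and
``n`` y-offsets (16-bit, relative to the bounding box's left/top).
"""

from __future__ import annotations

import struct

HEADER_SIZE = 64
MAGIC = b"Iout"

# ImageJ type codes
_TYPE_CODES = {
    0: "polygon",
    1: "rectangle",
    2: "oval",
    3: "line",
    4: "freeline",
    5: "polyline",
    6: "no_roi",
    7: "freehand",
    8: "traced",
    9: "angle",
    10: "point",
}
ROI_TYPE_NAMES = _TYPE_CODES

_SUPPORTED = {"polygon", "rectangle", "oval", "freehand"}


def decode_roi(blob: bytes) -> dict:
    """Decode one ``.roi`` blob into a geometry dict.

    Returns ``{"type", "top", "left", "bottom", "right"}`` plus, for
    polygonal types, absolute vertex arrays ``"xs"``/``"ys"`` (pixel-edge
    coordinates, 0-based).
    """
    if len(blob) < HEADER_SIZE or blob[:4] != MAGIC:
        raise ValueError("not an ImageJ ROI file (bad magic)")
    type_code = blob[6]
    kind = _TYPE_CODES.get(type_code, f"unknown({type_code})")
    if kind not in _SUPPORTED:
        raise ValueError(f"unsupported ImageJ ROI type: {kind!r}")
    top, left, bottom, right, n = struct.unpack(">hhhhH", blob[8:18])
    geom = {"type": kind, "top": top, "left": left, "bottom": bottom, "right": right}
    if kind in ("polygon", "freehand"):
        need = HEADER_SIZE + 4 * n
        if len(blob) < need:
            raise ValueError("truncated ImageJ ROI coordinate block")
        xs = struct.unpack(f">{n}h", blob[HEADER_SIZE:HEADER_SIZE + 2 * n])
        ys = struct.unpack(f">{n}h", blob[HEADER_SIZE + 2 * n:need])
        geom["xs"] = [left + x for x in xs]
        geom["ys"] = [top + y for y in ys]
    return geom


def encode_roi(kind: str, *, top: int = 0, left: int = 0, bottom: int = 0,
               right: int = 0, xs=None, ys=None) -> bytes:
    """Encode a geometry into a ``.roi`` blob ImageJ (and :func:`decode_roi`)
    can read.  For polygon/freehand pass absolute vertex lists ``xs``/``ys``."""
    code = {v: k for k, v in _TYPE_CODES.items()}[kind]
    if kind in ("polygon", "freehand"):
        if not xs or not ys or len(xs) != len(ys):
            raise ValueError("polygon ROIs need matching xs/ys vertex lists")
        left, top = int(min(xs)), int(min(ys))
        right, bottom = int(max(xs)), int(max(ys))
        n = len(xs)
    else:
        n = 0
    header = bytearray(HEADER_SIZE)
    header[:4] = MAGIC
    struct.pack_into(">h", header, 4, 228)  # format version
    header[6] = code
    struct.pack_into(">hhhhH", header, 8, top, left, bottom, right, n)
    blob = bytes(header)
    if n:
        blob += struct.pack(f">{n}h", *[int(x) - left for x in xs])
        blob += struct.pack(f">{n}h", *[int(y) - top for y in ys])
    return blob
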