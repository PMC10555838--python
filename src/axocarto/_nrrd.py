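"""Minimal NRRD (Nearly Raw Raster Data) reader/writer.

Supports the subset of NRRD0004 this package emits: 3-D arrays, raw or gzip
encoding, little-endian, scalar dtypes.  Per the NRRD convention ``sizes`` and
``spacings`` are listed fastest axis first, i.e. reversed with respect to the
(z, y, x) array shape used throughout the package.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_DTYPES = {
    "uint8": np.uint8,
    "uchar": np.uint8,
    "int16": np.int16,
    "short": np.int16,
    "uint16": np.uint16,
    "ushort": np.uint16,
    "int32": np.int32,
    "int": np.int32,
    "uint32": np.uint32,
    "uint": np.uint32,
    "int64": np.int64,
    "uint64": np.uint64,
    "float": np.float32,
    "float32": np.float32,
    "double": np.float64,
    "float64": np.float64,
}
_NAMES = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16",
    np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32",
    np.dtype(np.uint32): "uint32",
    np.dtype(np.int64): "int64",
    np.dtype(np.uint64): "uint64",
    np.dtype(np.float32): "float32",
    np.dtype(np.float64): "float64",
}


def read_nrrd(path):
    """Read an NRRD file, returning ``(array, header_dict)``.

    The array is C-ordered with shape reversed from the header ``sizes``
    (slowest axis first, matching this package's (z, y, x) convention).
    """
    path = Path(path)
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not an NRRD file (magic {magic!r})")
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated NRRD header")
            text = line.decode("ascii", "replace").rstrip("\r\n")
            if text == "":
                break
            if text.startswith("#"):
                continue
            if ":" not in text:
                raise ValueError(f"{path}: malformed header line {text!r}")
            key, _, value = text.partition(":")
            header[key.strip().lower()] = value.lstrip("= ").strip()
        payload = fh.read()

    try:
        dtype = np.dtype(_DTYPES[header["type"]])
    except KeyError:
        raise ValueError(f"{path}: unsupported NRRD type {header.get('type')!r}")
    sizes = tuple(int(s) for s in header["sizes"].split())
    if int(header.get("dimension", len(sizes))) != len(sizes):
        raise ValueError(f"{path}: dimension/sizes mismatch")
    encoding = header.get("encoding", "raw").lower()
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    if header.get("endian", "little") == "big" and dtype.itemsize > 1:
        dtype = dtype.newbyteorder(">")
    count = int(np.prod(sizes))
    data = np.frombuffer(payload, dtype=dtype, count=count)
    # sizes are fastest-first; a C-order array therefore has reversed shape
    data = data.reshape(sizes[::-1]).astype(dtype.newbyteorder("="), copy=False)
    return np.ascontiguousarray(data), header


def parse_spacings(header, ndim=3):
    """Extract per-axis spacing (slowest axis first) or None."""
    if "spacings" in header:
        sp = [float(v) for v in header["spacings"].split()]
        return tuple(sp[::-1])
    if "space directions" in header:
        sp = []
        for token in header["space directions"].split(")"):
            token = token.strip().lstrip(",").strip().lstrip("(")
            if not token:
                continue
            vec = [float(v) for v in token.split(",")]
            sp.append(float(np.linalg.norm(vec)))
        if len(sp) == ndim:
            return tuple(sp[::-1])
    return None


def write_nrrd(path, array, spacing=None, encoding="raw"):
    """Write a 3-D array as NRRD0004; ``spacing`` is slowest-axis-first."""
    array = np.ascontiguousarray(array)
    if array.dtype not in _NAMES:
        raise ValueError(f"unsupported dtype for NRRD: {array.dtype}")
    lines = [
        "NRRD0004",
        f"type: {_NAMES[array.dtype]}",
        f"dimension: {array.ndim}",
        "sizes: " + " ".join(str(s) for s in array.shape[::-1]),
        f"encoding: {encoding}",
    ]
    if array.dtype.itemsize > 1:
        lines.append("endian: little")
        if array.dtype.byteorder == ">":
            array = array.astype(array.dtype.newbyteorder("<"))
    if spacing is not None:
        lines.append("spacings: " + " ".join(repr(float(s)) for s in spacing[::-1]))
    payload = array.tobytes()
    if encoding in ("gzip", "gz"):
        payload = gzip.compress(payload)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        fh.write(payload)
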