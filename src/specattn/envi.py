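"""Minimal ENVI raster reader/writer (text .hdr + raw binary).

Supports BSQ/BIL/BIP interleaves, the common numeric data types, and the
``wavelength`` header list.  Enough for calibration cubes; not a general
ENVI implementation.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .preprocess import HyperCube, WavelengthGrid

__all__ = ["read_envi", "write_envi"]

# ENVI data type code -> numpy dtype
_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
           5: np.float64, 12: np.uint16, 13: np.uint32}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(path: str) -> dict:
    with open(path, "r") as fh:
        text = fh.read()
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError(f"{path}: not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(header_path: str, kind: str = "raw") -> HyperCube:
    """Read an ENVI raster given its header path; returns rows x cols x bands."""
    h = _parse_header(header_path)
    rows = int(h["lines"])
    cols = int(h["samples"])
    bands = int(h["bands"])
    dtype = np.dtype(_DTYPES[int(h["data type"])])
    interleave = h.get("interleave", "bsq").lower()
    byte_order = int(h.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    offset = int(h.get("header offset", 0))

    data_path = os.path.splitext(header_path)[0]
    if not os.path.exists(data_path):
        for ext in (".img", ".dat", ".raw", ".bsq", ".bil", ".bip"):
            if os.path.exists(data_path + ext):
                data_path = data_path + ext
                break
        else:
            raise FileNotFoundError(f"no data file found next to {header_path}")
    flat = np.fromfile(data_path, dtype=dtype, offset=offset, count=rows * cols * bands)
    if flat.size != rows * cols * bands:
        raise ValueError(f"{data_path}: expected {rows * cols * bands} values, got {flat.size}")

    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    if "wavelength" in h:
        wl = [float(x) for x in h["wavelength"].strip("{} ").split(",") if x.strip()]
        if len(wl) != bands:
            raise ValueError(f"header lists {len(wl)} wavelengths for {bands} bands")
        grid = WavelengthGrid(np.array(wl))
    else:
        grid = WavelengthGrid(np.arange(bands, dtype=float) + 1.0)
    return HyperCube(np.ascontiguousarray(data, dtype=float), grid, kind=kind)


def write_envi(cube: HyperCube, header_path: str, interleave: str = "bsq",
               dtype=np.float32) -> str:
    """Write a cube as raw binary + ENVI .hdr; returns the data file path."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    rows, cols, bands = cube.data.shape
    arr = cube.data.astype(dtype)
    if interleave == "bsq":
        flat = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = arr.transpose(0, 2, 1)
    else:
        flat = arr
    data_path = os.path.splitext(header_path)[0] + ".img"
    flat.tofile(data_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{specattn {cube.kind} cube}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(hdr)
    return data_path
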