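"""Minimal ENVI-style cube I/O: binary BSQ raw file + text header.

Layout on disk for base path ``foo``:

* ``foo.hdr``  -- ENVI text header (samples/lines/bands/data type/interleave/
  wavelength list),
* ``foo.img``  -- raw little-endian uint16, band-sequential (BSQ),
* ``foo.json`` -- sidecar with bit depth, per-band exposure, grid definition
  and free-form metadata (ENVI headers have no standard slot for these).

Round trips are bit-exact.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grids import HSCube, SpectralGrid

__all__ = ["write_cube", "read_cube"]

_ENVI_UINT16 = 12  # ENVI data type code


def _base(path) -> Path:
    p = Path(path)
    if p.suffix in (".hdr", ".img", ".json"):
        p = p.with_suffix("")
    return p


def write_cube(path, cube: HSCube) -> Path:
    """Write a cube as ENVI BSQ (header + raw + JSON sidecar).

    Returns the header path.
    """
    base = _base(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    wl = ", ".join(f"{w:.3f}" for w in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        "description = {colposim band-sequential cube}\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_UINT16}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    (base.with_suffix(".hdr")).write_text(header)
    bsq = np.ascontiguousarray(
        np.transpose(cube.data.astype("<u2"), (2, 0, 1))
    )
    bsq.tofile(base.with_suffix(".img"))
    sidecar = {
        "bit_depth": cube.bit_depth,
        "exposure_ms": [float(t) for t in cube.exposure_ms],
        "grid": cube.grid.to_dict(),
        "metadata": cube.metadata,
    }
    (base.with_suffix(".json")).write_text(json.dumps(sidecar, sort_keys=True))
    return base.with_suffix(".hdr")


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    fields: dict = {}
    lines = iter(text.splitlines())
    for line in lines:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            buf = value
            while "}" not in buf:
                buf += " " + next(lines).strip()
            inner = buf[buf.index("{") + 1 : buf.index("}")]
            fields[key] = [v.strip() for v in inner.split(",") if v.strip()]
        else:
            fields[key] = value
    return fields


def read_cube(path) -> HSCube:
    """Read a cube written by :func:`write_cube`, validating metadata."""
    base = _base(path)
    hdr = _parse_header(base.with_suffix(".hdr").read_text())
    interleave = hdr.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"unknown interleave {interleave!r} (only bsq supported)")
    dtype_code = int(hdr["data type"])
    if dtype_code != _ENVI_UINT16:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    samples = int(hdr["samples"])
    lines_n = int(hdr["lines"])
    bands = int(hdr["bands"])
    wl = np.array([float(v) for v in hdr.get("wavelength", [])])
    if wl.size != bands:
        raise ValueError(
            f"header wavelength count {wl.size} does not match bands {bands}"
        )
    raw = np.fromfile(base.with_suffix(".img"), dtype="<u2")
    if raw.size != samples * lines_n * bands:
        raise ValueError(
            f"raw file holds {raw.size} values, expected "
            f"{samples * lines_n * bands}"
        )
    data = raw.reshape(bands, lines_n, samples).transpose(1, 2, 0)

    sidecar = json.loads(base.with_suffix(".json").read_text())
    grid = SpectralGrid.from_dict(sidecar["grid"])
    if not np.allclose(grid.wavelengths, wl, atol=1e-3):
        raise ValueError("sidecar grid disagrees with header wavelengths")
    return HSCube(
        data=data.astype(np.uint16),
        grid=grid,
        bit_depth=int(sidecar["bit_depth"]),
        exposure_ms=np.asarray(sidecar["exposure_ms"], dtype=float),
        metadata=sidecar.get("metadata", {}),
    )
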