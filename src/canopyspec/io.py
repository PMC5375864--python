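"""Reading and writing the pipeline's on-disk formats.

Hyperspectral cubes and classification rasters use the ENVI header/binary
pair (plain-text ``.hdr`` plus a raw payload).  BSQ, BIL and BIP interleaves
are read; BSQ is written.  Reflectance cubes are stored as 32-bit floats,
DN cubes as 16-bit unsigned integers.  Spectral libraries and all tabular
outputs are CSV.

Spatial convention everywhere: 0-based (row, col), row 0 at the top.
Band order in memory is always ascending in wavelength, whatever the file
stored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorruptionError, FormatError
from .types import (
    CLASS_CODES,
    COMPONENT_CLASSES,
    HyperCube,
    LabelMap,
    Spectrum,
    SpectralLibrary,
)

_ENVI_DTYPES = {
    1: np.dtype("u1"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


def _base_path(path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in (".hdr", ".dat", ".img") else p


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI ``key = value`` pairs; ``{...}`` values may span lines."""
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ENVI":
        raise FormatError("not an ENVI header (missing ENVI magic)")
    fields = {}
    i = 1
    while i < len(lines):
        line = lines[i]
        if "=" not in line:
            i += 1
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value:
                i += 1
                value += " " + lines[i].strip()
            value = value[1:value.index("}")]
        fields[key] = value.strip()
        i += 1
    return fields


def read_envi_cube(header_path) -> HyperCube:
    """Read an ENVI header/binary pair into a :class:`HyperCube`.

    The header must declare dimensions, interleave (bsq/bil/bip) and a
    wavelength list; the payload size must match the declared shape.
    ``units_flag`` comes from the ``data units`` header key, defaulting
    to ``dn``.
    """
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    fields = _parse_envi_header(header_path.read_text())

    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required key {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no wavelength list")
    wavelengths = np.array(
        [float(w) for w in fields["wavelength"].replace("\n", " ").split(",") if w.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but {wavelengths.size} wavelengths"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")

    base = _base_path(header_path)
    payload = next(
        (p for p in (base, base.with_suffix(".dat"), base.with_suffix(".img")) if p.is_file()),
        None,
    )
    if payload is None:
        raise FormatError(f"no binary payload found next to {header_path}")
    dtype = _ENVI_DTYPES[dtype_code]
    raw = np.fromfile(payload, dtype=dtype)
    expected = rows * cols * bands
    if raw.size != expected:
        raise CorruptionError(
            f"payload has {raw.size} samples, header declares {expected} "
            f"({rows}x{cols}x{bands})"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(rows, cols, bands)

    # in-memory band order is ascending in wavelength, whatever the file had
    order = np.argsort(wavelengths, kind="stable")
    wavelengths = wavelengths[order]
    data = data[:, :, order]

    units = fields.get("data units", "dn")
    metadata = {
        k[5:]: v for k, v in fields.items() if k.startswith("meta ")
    }
    return HyperCube(
        data=np.ascontiguousarray(data),
        wavelengths=wavelengths,
        units_flag=units,
        metadata=metadata,
    )


def write_envi_cube(cube: HyperCube, path) -> None:
    """Write a cube as BSQ: ``<path>.hdr`` + ``<path>.dat``.

    Reflectance is stored float32, DN uint16.
    """
    base = _base_path(path)
    dtype = np.dtype("<f4") if cube.units_flag == "reflectance" else np.dtype("<u2")
    rows, cols, bands = cube.data.shape
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {canopyspec hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"data units = {cube.units_flag}",
        f"wavelength = {{ {wl} }}",
    ]
    for key, value in cube.metadata.items():
        lines.append(f"meta {key} = {value}")
    base.with_suffix(".hdr").write_text("\n".join(lines) + "\n")
    cube.data.transpose(2, 0, 1).astype(dtype).tofile(base.with_suffix(".dat"))


def read_spectral_library(path) -> SpectralLibrary:
    """Read a library CSV: ``class,stage`` columns plus one numeric-header
    column per wavelength (nm), one spectrum per row."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "class" not in df.columns or "stage" not in df.columns:
        raise FormatError("library table needs 'class' and 'stage' columns")
    wl_cols = [c for c in df.columns if c not in ("class", "stage")]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavelength header: {exc}") from exc
    order = np.argsort(wl)
    wl = wl[order]
    values = df[wl_cols].to_numpy(dtype=float)[:, order]
    if np.isnan(values).any():
        raise FormatError("library table has missing spectral values")
    bad = set(df["class"]) - set(COMPONENT_CLASSES)
    if bad:
        raise FormatError(f"unknown class labels in library: {sorted(bad)}")
    entries = [
        (cls, stage, Spectrum(wl, row))
        for cls, stage, row in zip(df["class"], df["stage"], values)
    ]
    return SpectralLibrary(entries=entries)


def write_spectral_library(library: SpectralLibrary, path) -> None:
    """Write a library to CSV at full float precision (lossless round trip)."""
    wl = library.wavelengths
    rows = [
        {"class": cls, "stage": stage, **{f"{w:.10g}": v for w, v in zip(wl, s.values)}}
        for cls, stage, s in library.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_classification_map(labels: LabelMap, path) -> None:
    """Write a label map as a single-band uint8 ENVI raster plus a JSON
    sidecar code table (``<path>.codes.json``)."""
    base = _base_path(path)
    rows, cols = labels.labels.shape
    lines = [
        "ENVI",
        "description = {canopyspec classification map}",
        f"samples = {cols}",
        f"lines = {rows}",
        "bands = 1",
        "header offset = 0",
        "file type = ENVI Classification",
        "data type = 1",
        "interleave = bsq",
        "byte order = 0",
    ]
    base.with_suffix(".hdr").write_text("\n".join(lines) + "\n")
    labels.labels.astype("u1").tofile(base.with_suffix(".dat"))
    with open(str(base) + ".codes.json", "w") as fh:
        json.dump({str(k): v for k, v in labels.code_table.items()}, fh, indent=1)


def read_classification_map(path) -> LabelMap:
    """Round-trip counterpart of :func:`write_classification_map`."""
    base = _base_path(path)
    fields = _parse_envi_header(base.with_suffix(".hdr").read_text())
    rows, cols = int(fields["lines"]), int(fields["samples"])
    raw = np.fromfile(base.with_suffix(".dat"), dtype="u1")
    if raw.size != rows * cols:
        raise CorruptionError(
            f"classification payload has {raw.size} pixels, expected {rows * cols}"
        )
    codes_path = Path(str(base) + ".codes.json")
    if codes_path.is_file():
        with open(codes_path) as fh:
            code_table = {int(k): v for k, v in json.load(fh).items()}
    else:
        code_table = {v: k for k, v in CLASS_CODES.items()}
    return LabelMap(labels=raw.reshape(rows, cols).astype(np.int32), code_table=code_table)
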