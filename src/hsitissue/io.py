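"""Readers and writers for the on-disk formats.

Hypercubes are stored as a minimal ENVI pair: a lowercase-key text header
(``.hdr``) next to a raw binary file, 32-bit little-endian float, band-sequential
(BSQ) interleave. Annotation masks are 8-bit indexed PNG images with a JSON
sidecar mapping each code to a class name. Spectra export to CSV with a
wavelength column plus one column per curve.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import (
    AnnotationMask,
    FormatError,
    HSICube,
    SpectralCurve,
    TissueClassSet,
    WavelengthGrid,
)

_DTYPE_CODES = {4: np.dtype("<f4")}  # ENVI data type 4 = 32-bit float


def _header_path(path: Path) -> Path:
    return path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")


def write_cube(cube: HSICube, path) -> None:
    """Write ``cube`` as an ENVI header/binary pair at ``path`` (binary file path).

    The header declares samples (W), lines (H), bands (B), bsq interleave and the
    full wavelength list. Identical cubes produce byte-identical files.
    """
    path = Path(path)
    h, w, b = cube.shape
    wavelengths = ", ".join(repr(float(v)) for v in cube.wavelengths.values)
    header = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"subject id = {cube.subject_id}\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    _header_path(path).write_text(header)
    # BSQ: band-major on disk
    cube.data.astype("<f4").transpose(2, 0, 1).tofile(path)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    fields: dict = {}
    body = text.lstrip()[4:]
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1 :].lstrip(" \t")
        if rest.startswith("{"):
            close = rest.find("}")
            if close < 0:
                raise FormatError(f"unterminated {{ }} value for header field '{key}'")
            value = rest[1:close].strip()
            pos = eq + 1 + (len(body[eq + 1 :]) - len(rest)) + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl].strip()
            pos = eq + 1 + (len(body[eq + 1 :]) - len(rest)) + nl
        if key:
            fields[key] = value
    return fields


def read_cube(path) -> HSICube:
    """Read an ENVI header/binary pair written by :func:`write_cube`.

    Raises :class:`FormatError` naming the offending field when the header is
    missing a required key, declares an unsupported interleave or data type, or
    when the wavelength list length disagrees with ``bands``.
    """
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    for key in ("samples", "lines", "bands", "interleave", "data type", "wavelength"):
        if key not in fields:
            raise FormatError(f"ENVI header missing required field '{key}'")
    w, h, b = (int(fields[k]) for k in ("samples", "lines", "bands"))
    interleave = fields["interleave"].lower()
    if interleave != "bsq":
        raise FormatError(f"unsupported interleave '{interleave}' (only bsq)")
    dtype_code = int(fields["data type"])
    if dtype_code not in _DTYPE_CODES:
        raise FormatError(f"unsupported data type {dtype_code} (only 4 = float32)")
    wavelengths = np.array([float(v) for v in fields["wavelength"].split(",") if v.strip()])
    if wavelengths.size != b:
        raise FormatError(
            f"header field 'wavelength' lists {wavelengths.size} values but bands = {b}"
        )
    raw = np.fromfile(path, dtype=_DTYPE_CODES[dtype_code])
    if raw.size != h * w * b:
        raise FormatError(
            f"binary size {raw.size} does not match lines x samples x bands = {h * w * b}"
        )
    data = raw.reshape(b, h, w).transpose(1, 2, 0)
    return HSICube(data, WavelengthGrid(wavelengths), subject_id=fields.get("subject id", ""))


def write_mask(mask: AnnotationMask, path, class_map_path=None) -> None:
    """Write a mask as an 8-bit indexed PNG plus a JSON code->class sidecar."""
    path = Path(path)
    class_map_path = Path(class_map_path) if class_map_path else path.with_suffix(".json")
    path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
    palette = [0, 0, 0]
    for code in mask.class_set.codes:
        palette.extend(mask.class_set.color(code))
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)
    sidecar = {"0": "unlabeled"}
    sidecar.update({str(c): mask.class_set.label(c) for c in mask.class_set.codes})
    class_map_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")


def read_mask(path, class_map_path=None) -> AnnotationMask:
    """Read an indexed-PNG mask and its JSON class-map sidecar.

    Every code present in the image must appear in the sidecar; an unknown code
    raises :class:`FormatError` listing it.
    """
    path = Path(path)
    class_map_path = Path(class_map_path) if class_map_path else path.with_suffix(".json")
    sidecar = json.loads(class_map_path.read_text())
    labels = np.asarray(Image.open(path), dtype=np.uint8)
    present = np.unique(labels)
    unknown = [int(c) for c in present if str(int(c)) not in sidecar]
    if unknown:
        raise FormatError(f"mask contains codes missing from the class map: {unknown}")
    names = [sidecar[str(c)] for c in sorted(int(k) for k in sidecar) if c != 0]
    class_set = TissueClassSet(tuple(names))
    return AnnotationMask(labels.astype(np.int64), class_set)


def write_spectra_csv(curves: dict, path) -> None:
    """Export named spectral curves to CSV: wavelength_nm column + one per curve."""
    if not curves:
        raise ValueError("no curves to export")
    first = next(iter(curves.values()))
    table = {"wavelength_nm": first.wavelengths.values}
    for name, curve in curves.items():
        if len(curve) != len(first):
            raise FormatError(f"curve '{name}' length differs from the wavelength grid")
        table[name] = curve.values
    pd.DataFrame(table).to_csv(path, index=False)


def read_spectra_csv(path) -> dict:
    """Inverse of :func:`write_spectra_csv`."""
    frame = pd.read_csv(path)
    grid = WavelengthGrid(frame["wavelength_nm"].to_numpy())
    return {
        name: SpectralCurve(frame[name].to_numpy(), grid)
        for name in frame.columns
        if name != "wavelength_nm"
    }
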