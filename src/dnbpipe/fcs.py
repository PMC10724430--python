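"""Minimal FCS 3.0/3.1 reader and writer.

Supports the subset of the standard produced by mass-cytometry software:
list-mode (``$MODE L``) float data (``$DATATYPE F`` or ``D``) with a single
data segment. Channel names are taken from the stain name ``$PnS`` when
present, falling back to the short name ``$PnN``.

The writer exists so that round-trip tests and examples can fabricate
files with known values; it always emits FCS3.0, float32, little-endian.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import FormatError

_HEADER_LEN = 58


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS file; return (events x channels array, channel names)."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = raw[0:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        try:
            return int(raw[lo:hi].decode("ascii").strip() or 0)
        except ValueError as exc:
            raise FormatError(f"{path}: bad header offsets") from exc

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_begin:
        raise FormatError(f"{path}: empty TEXT segment")

    text = raw[text_begin : text_end + 1]
    delim = text[0:1].decode("latin-1")
    parts = text.decode("latin-1").strip(delim).split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    keywords = {k.upper(): v for k, v in zip(parts[::2], parts[1::2])}

    try:
        n_par = int(keywords["$PAR"])
        n_tot = int(keywords["$TOT"])
        datatype = keywords["$DATATYPE"].upper()
        byteord = keywords["$BYTEORD"]
    except KeyError as exc:
        raise FormatError(f"{path}: missing required keyword {exc}") from exc
    if datatype not in ("F", "D"):
        raise FormatError(
            f"{path}: only float FCS data supported, got $DATATYPE={datatype}"
        )
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if datatype == "F" else 8

    # TEXT may carry the data offsets when they overflow the header fields.
    if data_begin == 0:
        data_begin = int(keywords.get("$BEGINDATA", 0))
        data_end = int(keywords.get("$ENDDATA", 0))
    n_bytes = n_par * n_tot * itemsize
    if data_end - data_begin + 1 < n_bytes:
        raise FormatError(f"{path}: DATA segment shorter than $PAR*$TOT")

    dtype = np.dtype(f"{endian}f{itemsize}")
    data = np.frombuffer(raw[data_begin : data_begin + n_bytes], dtype=dtype)
    values = data.reshape(n_tot, n_par).astype(float)

    names = []
    for i in range(1, n_par + 1):
        name = keywords.get(f"$P{i}S") or keywords.get(f"$P{i}N") or f"P{i}"
        names.append(name)
    return values, names


def write_fcs(path: str | Path, values: np.ndarray, names: list[str]) -> None:
    """Write a float32 little-endian FCS3.0 file (test/round-trip helper)."""
    values = np.asarray(values, dtype="<f4")
    if values.ndim != 2 or values.shape[1] != len(names):
        raise ValueError("values must be events x channels matching names")
    n_tot, n_par = values.shape

    delim = "/"
    kw = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}S"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"

    # Two passes: offsets depend on the TEXT length which embeds offsets.
    data_bytes = values.tobytes()

    def render(text_begin: int) -> bytes:
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items())
        return body.encode("ascii")

    text = render(0)
    text_begin = _HEADER_LEN
    for _ in range(3):
        text_end = text_begin + len(text) - 1
        data_begin = text_end + 1
        data_end = data_begin + len(data_bytes) - 1
        kw["$BEGINDATA"] = str(data_begin)
        kw["$ENDDATA"] = str(data_end)
        new_text = render(text_begin)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    else:
        raise RuntimeError("FCS offset fixed point not reached")

    header = (
        b"FCS3.0    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_begin:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == _HEADER_LEN
    Path(path).write_bytes(header + text + data_bytes)
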