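"""Minimal FCS 3.1 list-mode I/O.

Covers the subset of the flow-cytometry standard this package emits and
consumes: a single dataset per file, list mode (``$MODE L``), 32-bit
little-endian floats (``$DATATYPE F``, ``$BYTEORD 1,2,3,4``), linear
amplification, channel short names in ``$PnN``. Log-amplified or integer
data and multi-dataset files are rejected explicitly rather than guessed at.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

_DELIM = b"/"


def write_fcs(path: str | Path, events: pd.DataFrame, metadata: dict[str, str] | None = None) -> Path:
    """Write an event table to an FCS 3.1 file.

    Parameters
    ----------
    events
        One row per event, one column per channel; column names become the
        ``$PnN`` short names.
    metadata
        Extra TEXT-segment keywords (keys without the leading ``$``).
    """
    path = Path(path)
    data = np.ascontiguousarray(events.to_numpy(dtype="<f4"))
    n_events, n_par = data.shape
    if n_events == 0:
        raise ValueError("refusing to write an FCS file with zero events")

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$NEXTDATA": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(events.columns, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(data[:, i - 1])) + 1)))
    for key, value in (metadata or {}).items():
        kw[key if key.startswith("$") else key.upper()] = str(value)

    # TEXT length depends on the data offsets it must quote; iterate to a fixed point.
    data_len = data.nbytes
    begin_data = 0
    for _ in range(8):
        text = _render_text(kw, begin_data, begin_data + data_len - 1)
        new_begin = 58 + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text = _render_text(kw, begin_data, begin_data + data_len - 1)

    header = b"FCS3.1    " + _offset_field(58) + _offset_field(58 + len(text) - 1)
    header += _offset_field(begin_data) + _offset_field(begin_data + data_len - 1)
    header += _offset_field(0) + _offset_field(0)
    assert len(header) == 58

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
    return path


def read_fcs(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read a linear list-mode FCS 3.0/3.1 file.

    Returns the TEXT-segment keywords and the event table with ``$PnN``
    column names.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58 or not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError(f"{path}: not an FCS 3.0/3.1 file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    kw = _parse_text(raw[text_begin : text_end + 1])

    if kw.get("$MODE", "L") != "L":
        raise ValueError(f"{path}: only list-mode ($MODE L) files are supported")
    if int(kw.get("$NEXTDATA", "0")) != 0:
        raise ValueError(f"{path}: multi-dataset FCS files are not supported")
    dtype_code = kw.get("$DATATYPE", "F")
    if dtype_code not in ("F", "D"):
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code!r} (need F or D)")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if dtype_code == "F" else 8

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if n_tot == 0:
        raise ValueError(f"{path}: zero events")
    for i in range(1, n_par + 1):
        if kw.get(f"$P{i}E", "0,0") != "0,0":
            raise ValueError(f"{path}: log-amplified parameter P{i} not supported")

    data_begin = int(kw.get("$BEGINDATA") or int(raw[26:34]))
    data_end = int(kw.get("$ENDDATA") or int(raw[34:42]))
    buf = raw[data_begin : data_end + 1]
    expected = n_par * n_tot * itemsize
    if len(buf) < expected:
        raise ValueError(f"{path}: truncated DATA segment ({len(buf)} < {expected} bytes)")
    values = np.frombuffer(buf[:expected], dtype=f"{endian}f{itemsize}").reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return kw, pd.DataFrame(np.asarray(values, dtype=float), columns=names)


def _offset_field(value: int) -> bytes:
    if value > 99_999_999:
        raise ValueError("segment offset exceeds the 8-digit FCS header field")
    return str(value).rjust(8).encode("ascii")


def _render_text(kw: dict[str, str], begin_data: int, end_data: int) -> bytes:
    items = dict(kw)
    items["$BEGINDATA"] = str(begin_data)
    items["$ENDDATA"] = str(max(end_data, 0))
    out = [_DELIM]
    for key, value in items.items():
        for token in (key, value):
            token_b = token.encode("utf-8")
            if _DELIM in token_b:
                raise ValueError(f"TEXT token {token!r} contains the delimiter")
            out.append(token_b)
            out.append(_DELIM)
    return b"".join(out)


def _parse_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise ValueError("empty TEXT segment")
    delim = segment[0:1]
    # Escaped (doubled) delimiters inside values are not produced by this
    # writer; split-and-merge handles them if another producer used them.
    parts = segment[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    tokens = [p.decode("utf-8", errors="replace") for p in parts]
    if len(tokens) % 2 == 1:
        tokens = tokens[:-1]
    return {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens), 2)}
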