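"""FCS 3.0/3.1 reading, FCS 3.1 writing, and CSV cell-table import.

Only list-mode, single-dataset files are handled.  ``$DATATYPE`` F and D are
read natively; integer data ($DATATYPE I) is accepted when every parameter
uses a uniform 16- or 32-bit width and is promoted to float.  ``$PnE``
log-amplification keywords are deliberately ignored: inputs are expected to
be pre-scaled cytometer/segmentation exports, and values are returned exactly
as stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, TruncatedDataError

HEADER_LEN = 58
_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")

#: column names treated as cell metadata (not markers) in CSV cell tables
DEFAULT_META_COLUMNS = frozenset(
    {
        "cell_id",
        "cellid",
        "object_id",
        "objectnumber",
        "id",
        "x",
        "y",
        "x_position",
        "y_position",
        "region",
        "roi",
        "area",
        "label",
        "sample",
        "image",
    }
)


@dataclass
class RawSample:
    """One file's worth of untransformed events."""

    data: np.ndarray  # (events, parameters)
    channel_ids: list[str]  # $PnN
    channel_labels: list[str]  # $PnS (defaults to $PnN)
    source_path: str | None = None
    cell_meta: pd.DataFrame | None = None

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # a doubled delimiter escapes a literal delimiter inside a value:
    # after splitting, an empty part marks two consecutive delimiters
    tokens = body.split(delim)
    merged: list[bytes] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        while i + 2 < len(tokens) and tokens[i + 1] == b"":
            tok = tok + delim + tokens[i + 2]
            i += 2
        merged.append(tok)
        i += 1
    if len(merged) % 2 != 0:
        merged = merged[: len(merged) - 1]
    kv: dict[str, str] = {}
    for j in range(0, len(merged), 2):
        key = merged[j].decode("utf-8", "replace").strip().upper()
        val = merged[j + 1].decode("utf-8", "replace").strip()
        if key:
            kv[key] = val
    return kv


def read_fcs(path) -> RawSample:
    """Read a single-dataset list-mode FCS 3.0/3.1 file.

    Returns the event matrix untransformed, with ``$PnN`` channel ids and
    ``$PnS`` display labels (falling back to ``$PnN``).
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < HEADER_LEN:
        raise FormatError(f"{path}: file shorter than FCS header ({len(blob)} bytes)")
    version = blob[0:6].decode("ascii", "replace")
    if version not in _SUPPORTED_VERSIONS:
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _off(a: int, b: int) -> int:
        s = blob[a:b].decode("ascii", "replace").strip()
        return int(s) if s else 0

    text_start, text_end = _off(10, 18), _off(18, 26)
    data_start, data_end = _off(26, 34), _off(34, 42)
    if text_start <= 0 or text_end <= text_start:
        raise FormatError(f"{path}: invalid TEXT segment offsets in header")
    text = _parse_text_segment(blob[text_start : text_end + 1])

    nextdata = int(text.get("$NEXTDATA", "0") or 0)
    if nextdata != 0:
        raise FormatError(
            f"{path}: multi-dataset FCS files are not supported ($NEXTDATA={nextdata}); "
            "split the file into single-dataset exports first"
        )
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FormatError(f"{path}: unsupported $MODE={mode!r}; only list mode (L)")
    datatype = text.get("$DATATYPE", "").upper()
    if datatype not in ("F", "D", "I"):
        raise FormatError(f"{path}: unsupported $DATATYPE={datatype!r}")

    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing required keyword {exc}") from exc

    byteord = text.get("$BYTEORD", "1,2,3,4")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD={byteord!r}")

    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FormatError(f"{path}: $DATATYPE=F requires $PnB=32, got {sorted(set(bits))}")
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise FormatError(f"{path}: $DATATYPE=D requires $PnB=64, got {sorted(set(bits))}")
        dtype = np.dtype(endian + "f8")
    else:  # I
        widths = sorted(set(bits))
        if widths == [16]:
            dtype = np.dtype(endian + "u2")
        elif widths == [32]:
            dtype = np.dtype(endian + "u4")
        else:
            raise FormatError(
                f"{path}: $DATATYPE=I supported only with uniform $PnB of 16 or 32, "
                f"got $PnB widths {widths}"
            )

    if data_start <= 0:
        data_start = int(text.get("$BEGINDATA", "0") or 0)
        data_end = int(text.get("$ENDDATA", "0") or 0)
    if data_start <= 0:
        raise FormatError(f"{path}: no DATA segment offsets in header or TEXT")

    n_values = n_par * n_tot
    n_bytes = n_values * dtype.itemsize
    segment = blob[data_start : data_start + n_bytes]
    if len(segment) < n_bytes:
        raise TruncatedDataError(
            f"{path}: DATA segment truncated; need {n_bytes} bytes for "
            f"$TOT={n_tot} x $PAR={n_par}, found {len(segment)}"
        )
    data = np.frombuffer(segment, dtype=dtype, count=n_values).reshape(n_tot, n_par)
    data = data.astype(np.float64)

    channel_ids = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    channel_labels = [text.get(f"$P{i}S", channel_ids[i - 1]) for i in range(1, n_par + 1)]
    return RawSample(data, channel_ids, channel_labels, source_path=str(path))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_fcs(data, channel_ids, path, channel_labels=None) -> None:
    """Write a single-dataset list-mode FCS 3.1 file ($DATATYPE F).

    ``$PnS`` labels default to the ``$PnN`` channel ids.  Non-finite values
    are refused so that the file is readable by any standards-conforming
    parser.
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValueError(f"need a 2-D matrix with >=1 event, got shape {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError("refusing to write FCS with NaN/Inf values")
    n_tot, n_par = data.shape
    channel_ids = [str(c) for c in channel_ids]
    if len(channel_ids) != n_par:
        raise ValueError(
            f"{len(channel_ids)} channel ids for {n_par} data columns"
        )
    if channel_labels is None:
        channel_labels = list(channel_ids)
    channel_labels = [str(c) for c in channel_labels]

    delim = "/"

    def esc(v: str) -> str:
        return v.replace(delim, delim * 2)

    ranges = np.nanmax(np.abs(data), axis=0)

    def build_text(begin_data: int, end_data: int) -> bytes:
        kv: list[tuple[str, str]] = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(begin_data).rjust(12)),
            ("$ENDDATA", str(end_data).rjust(12)),
            ("$BYTEORD", "1,2,3,4"),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(n_par)),
            ("$TOT", str(n_tot)),
        ]
        for i in range(n_par):
            kv.append((f"$P{i+1}N", esc(channel_ids[i])))
            kv.append((f"$P{i+1}S", esc(channel_labels[i])))
            kv.append((f"$P{i+1}B", "32"))
            kv.append((f"$P{i+1}E", "0,0"))
            kv.append((f"$P{i+1}R", str(int(np.ceil(float(ranges[i]))) + 1)))
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv) + delim
        return text.encode("ascii")

    text_start = HEADER_LEN
    # $BEGINDATA/$ENDDATA are padded to fixed width, so TEXT length is stable
    text = build_text(0, 0)
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1
    text = build_text(data_start, data_end)
    assert text_start + len(text) - 1 == text_end

    def hdr_field(v: int) -> bytes:
        s = str(v) if v <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    "  # 6-byte version + 4 spaces
    header += hdr_field(text_start) + hdr_field(text_end)
    header += hdr_field(data_start if data_end <= 99_999_999 else 0)
    header += hdr_field(data_end if data_end <= 99_999_999 else 0)
    header += hdr_field(0) + hdr_field(0)
    assert len(header) == HEADER_LEN

    payload = np.ascontiguousarray(data, dtype="<f4").tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


# ---------------------------------------------------------------------------
# CSV cell tables (segmented-cell mean intensities)
# ---------------------------------------------------------------------------

def read_cell_table(path, meta_columns=None) -> RawSample:
    """Read a CSV of per-cell mean marker intensities.

    One row per segmented cell, header row of channel names.  Non-marker
    columns (cell id, coordinates, region label, ...) are split off into a
    cell-metadata side table; by default any non-numeric column plus the
    well-known bookkeeping names in :data:`DEFAULT_META_COLUMNS` are treated
    as metadata.  Pass ``meta_columns`` to override.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: could not parse CSV cell table: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty cell table")

    if meta_columns is None:
        meta_cols = [
            c
            for c in df.columns
            if str(c).strip().lower() in DEFAULT_META_COLUMNS
            or not pd.api.types.is_numeric_dtype(df[c])
        ]
    else:
        meta_cols = [c for c in df.columns if c in set(meta_columns)]
    marker_cols = [c for c in df.columns if c not in set(meta_cols)]
    if not marker_cols:
        raise ParseError(f"{path}: no numeric marker columns found")

    for c in marker_cols:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any() and not df[c].isna().any():
            row = int(col.index[col.isna() & ~df[c].isna()][0])
            raise ParseError(
                f"{path}: non-numeric value in marker column {c!r} at row {row}"
            )
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise ParseError(f"{path}: missing value in marker column {c!r} at row {row}")
        df[c] = col

    data = df[marker_cols].to_numpy(dtype=np.float64)
    meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
    ids = [str(c) for c in marker_cols]
    return RawSample(data, ids, list(ids), source_path=str(path), cell_meta=meta)
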