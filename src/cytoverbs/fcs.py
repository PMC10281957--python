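"""FCS 3.0/3.1 and delimited-text cell-table I/O.

FCS files are the binary interchange format of flow and mass cytometry: a
58-byte HEADER with segment offsets, a delimited TEXT segment of
keyword/value pairs, and a DATA segment holding the events x parameters
measurement matrix.  Only list-mode ($MODE "L") files with $DATATYPE
F (float32), D (float64) or I (unsigned integer) are supported — the
dialects produced by current mass and spectral cytometers.  FCS 2.0 and the
ANALYSIS segment are out of scope; $SPILLOVER is carried in the keyword map
but never applied.

Column naming follows analyst convention: the human-readable antigen name
($PnS) when present, else the instrument channel name ($PnN); both are kept
in the attached :class:`~cytoverbs.table.Panel`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CorruptFileError,
    EmptyInputError,
    MissingPanelError,
    UnsupportedFormatError,
    UnsupportedModeError,
)
from .table import MARKER, TECHNICAL, CytoTable, Panel, PanelEntry

_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")
_HEADER_LEN = 58

#: channel names that denote instrument/technical channels rather than
#: antibody-conjugated markers (case-insensitive match on $PnN)
TECHNICAL_CHANNELS = frozenset(
    {"time", "event_length", "center", "offset", "width", "residual",
     "beaddist", "dna1", "dna2"}
)


@dataclass
class FcsDocument:
    """Decoded FCS file: version tag, ordered TEXT keywords, event matrix."""

    version: str
    text_keywords: dict[str, str] = field(default_factory=dict)
    data: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


# ---------------------------------------------------------------------------
# TEXT segment codec (delimiter escaping = doubled delimiter)
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if len(raw) < 2:
        raise CorruptFileError("TEXT segment too short")
    delim = raw[0:1]
    body = raw[1:]
    # doubled delimiters are escaped literals; split manually
    tokens: list[str] = []
    cur = bytearray()
    i = 0
    n = len(body)
    while i < n:
        ch = body[i : i + 1]
        if ch == delim:
            if i + 1 < n and body[i + 1 : i + 2] == delim:
                cur += delim
                i += 2
                continue
            tokens.append(cur.decode("utf-8", errors="replace"))
            cur = bytearray()
            i += 1
        else:
            cur += ch
            i += 1
    if cur:
        tokens.append(cur.decode("utf-8", errors="replace"))
    # trailing delimiter leaves an empty final token; drop it
    if tokens and tokens[-1] == "":
        tokens.pop()
    if len(tokens) % 2 != 0:
        raise CorruptFileError("TEXT segment holds an odd number of tokens")
    out: dict[str, str] = {}
    for k, v in zip(tokens[0::2], tokens[1::2]):
        key = k.strip()
        key = key.upper() if key.startswith("$") else key
        out[key] = v
    return out


def _escape(value: str, delim: str) -> str:
    return value.replace(delim, delim * 2)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _segment_bounds(header: bytes, keywords: dict[str, str] | None,
                    which: str, raw_len: int) -> tuple[int, int]:
    """Begin/end byte offsets for TEXT or DATA, preferring the TEXT-segment
    $BEGINDATA/$ENDDATA keywords over the fixed-width header fields (which
    are zero when offsets overflow 8 digits)."""
    slots = {"TEXT": (10, 18, 18, 26), "DATA": (26, 34, 34, 42)}
    b0, b1, e0, e1 = slots[which]
    begin = int(header[b0:b1].decode("ascii").strip() or 0)
    end = int(header[e0:e1].decode("ascii").strip() or 0)
    if keywords is not None:
        kb, ke = f"$BEGIN{which}", f"$END{which}"
        if keywords.get(kb, "0").strip() not in ("", "0"):
            begin = int(keywords[kb])
            end = int(keywords[ke])
    if begin <= 0 or end < begin or end >= raw_len:
        raise CorruptFileError(f"invalid {which} segment offsets [{begin}, {end}]")
    return begin, end


def read_fcs_document(path: str | Path) -> FcsDocument:
    """Decode an FCS 3.0/3.1 file into keywords plus the raw event matrix."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN:
        raise UnsupportedFormatError(f"{path}: file shorter than an FCS header")
    version = raw[0:6].decode("ascii", errors="replace")
    if version not in _SUPPORTED_VERSIONS:
        raise UnsupportedFormatError(
            f"{path}: unsupported version tag {version!r} (need FCS3.0/FCS3.1)"
        )
    text_begin, text_end = _segment_bounds(raw[:_HEADER_LEN], None, "TEXT", len(raw))
    kw = _parse_text_segment(raw[text_begin : text_end + 1])

    mode = kw.get("$MODE", "").strip().upper()
    if mode != "L":
        raise UnsupportedModeError(f"{path}: $MODE {mode!r} unsupported (need list mode)")
    try:
        tot = int(kw["$TOT"])
        par = int(kw["$PAR"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:
        raise CorruptFileError(f"{path}: required keyword {exc} missing") from exc

    bits = []
    for i in range(1, par + 1):
        if f"$P{i}N" not in kw or f"$P{i}B" not in kw:
            raise CorruptFileError(f"{path}: $P{i}N/$P{i}B missing")
        bits.append(int(kw[f"$P{i}B"]))

    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2"):
        endian = ">"
    else:
        raise UnsupportedFormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    data_begin, data_end = _segment_bounds(raw[:_HEADER_LEN], kw, "DATA", len(raw))
    payload = raw[data_begin : data_end + 1]

    if datatype in ("F", "D"):
        width = 4 if datatype == "F" else 8
        if any(b != width * 8 for b in bits):
            raise CorruptFileError(f"{path}: $PnB disagrees with $DATATYPE {datatype}")
        expected = tot * par * width
        if len(payload) != expected:
            raise CorruptFileError(
                f"{path}: DATA segment holds {len(payload)} bytes, "
                f"$TOT x $PAR needs {expected}"
            )
        dtype = np.dtype(f"{endian}f{width}")
        data = np.frombuffer(payload, dtype=dtype).reshape(tot, par).astype(np.float64)
    elif datatype == "I":
        for i in range(1, par + 1):
            amp = kw.get(f"$P{i}E", "0,0").replace(" ", "")
            if amp not in ("0,0", "0.0,0.0", "0,0.0", "0.0,0"):
                raise UnsupportedFormatError(
                    f"{path}: log-amplified integer data ($P{i}E={amp!r}) is not "
                    "linearized automatically; export linear data instead"
                )
        widths = [b // 8 for b in bits]
        if any(b not in (8, 16, 32, 64) for b in bits):
            raise UnsupportedFormatError(f"{path}: unsupported integer $PnB in {bits}")
        row_bytes = sum(widths)
        expected = tot * row_bytes
        if len(payload) != expected:
            raise CorruptFileError(
                f"{path}: DATA segment holds {len(payload)} bytes, "
                f"$TOT x $PAR needs {expected}"
            )
        if len(set(widths)) == 1:
            dtype = np.dtype(f"{endian}u{widths[0]}")
            data = np.frombuffer(payload, dtype=dtype).reshape(tot, par).astype(np.float64)
        else:  # mixed widths: decode column-wise from a structured dtype
            sdtype = np.dtype([(f"p{i}", f"{endian}u{w}") for i, w in enumerate(widths)])
            rows = np.frombuffer(payload, dtype=sdtype)
            data = np.column_stack([rows[f"p{i}"] for i in range(par)]).astype(np.float64)
    else:
        raise UnsupportedFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    return FcsDocument(version=version, text_keywords=kw, data=data)


def _panel_from_keywords(kw: dict[str, str]) -> Panel:
    par = int(kw["$PAR"])
    entries = []
    seen: dict[str, int] = {}
    for i in range(1, par + 1):
        pnn = kw[f"$P{i}N"]
        pns = kw.get(f"$P{i}S", "").strip()
        name = pns if pns else pnn
        # display names must be unique table columns
        if name in seen:
            seen[name] += 1
            name = f"{name}.{seen[name]}"
        else:
            seen[name] = 0
        cls = TECHNICAL if pnn.strip().lower() in TECHNICAL_CHANNELS else MARKER
        entries.append(PanelEntry(channel_name=pnn, antigen_name=name, channel_class=cls))
    return Panel(entries)


def read_fcs(path: str | Path) -> tuple[CytoTable, Panel]:
    """Read an FCS 3.0/3.1 file into a tidy cell table plus its panel.

    One row per event, one column per parameter, named by $PnS (falling back
    to $PnN).  Values are decoded per $DATATYPE and $BYTEORD; float data is
    never re-scaled by $PnE.
    """
    doc = read_fcs_document(path)
    panel = _panel_from_keywords(doc.text_keywords)
    df = pd.DataFrame(doc.data, columns=panel.column_names)
    return CytoTable(df, panel=panel), panel


# ---------------------------------------------------------------------------
# writing (canonical FCS 3.1 dialect: float32, list mode, little-endian)
# ---------------------------------------------------------------------------

def write_fcs(table: CytoTable, path: str | Path) -> Path:
    """Write a cell table's channel columns as a canonical FCS 3.1 file.

    Always DATATYPE "F" (32-bit float), MODE "L", $BYTEORD "1,2,3,4",
    $PnB 32, $PnE "0,0", so ``read_fcs(write_fcs(t))`` reproduces channel
    values exactly at 32-bit precision.  Annotation columns are not stored
    (FCS has no text-column concept); use the CSV writer for those.
    """
    if table.panel is None:
        raise MissingPanelError("write_fcs requires a Panel on the table")
    if len(table) == 0:
        raise EmptyInputError("refusing to write an FCS file with zero cells")
    channels = table.channel_columns
    if not channels:
        raise MissingPanelError("table has no channel columns matching its panel")
    frame = pd.DataFrame(table)[channels]
    for c in channels:
        if not pd.api.types.is_numeric_dtype(frame[c]):
            raise TypeError(f"channel column {c!r} is not numeric")
    matrix = frame.to_numpy(dtype=np.float32)

    entry_by_column = {e.antigen_name: e for e in table.panel.entries}
    delim = "/"
    kw_pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "{begindata}"),
        ("$ENDDATA", "{enddata}"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(matrix.shape[1])),
        ("$TOT", str(matrix.shape[0])),
    ]
    for i, col in enumerate(channels, start=1):
        entry = entry_by_column[col]
        # $PnR: dynamic range; informational for float data
        rng = float(np.nanmax(matrix[:, i - 1])) if matrix.size else 0.0
        kw_pairs += [
            (f"$P{i}N", entry.channel_name),
            (f"$P{i}S", entry.antigen_name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(max(1, int(np.ceil(rng)) + 1))),
        ]

    def render(begindata: int, enddata: int) -> bytes:
        parts = [delim]
        for k, v in kw_pairs:
            v = v.format(begindata=begindata, enddata=enddata) if "{" in v else v
            parts.append(_escape(k, delim) + delim + _escape(v, delim) + delim)
        return "".join(parts).encode("utf-8")

    # offsets depend on TEXT length; fixed-width placeholders make one
    # re-render sufficient
    placeholder = render(10**9, 10**9)
    data_begin = _HEADER_LEN + len(placeholder)
    data_end = data_begin + matrix.nbytes - 1
    text = render(data_begin, data_end)
    while len(text) != len(placeholder):  # width drift: re-anchor
        placeholder = text
        data_begin = _HEADER_LEN + len(placeholder)
        data_end = data_begin + matrix.nbytes - 1
        text = render(data_begin, data_end)

    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1

    def hfield(v: int) -> bytes:
        s = str(v) if v <= 99999999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + hfield(text_begin) + hfield(text_end)
    header += hfield(data_begin if data_end <= 99999999 else 0)
    header += hfield(data_end if data_end <= 99999999 else 0)
    header += hfield(0) + hfield(0)
    assert len(header) == _HEADER_LEN

    payload = matrix.astype("<f4").tobytes(order="C")
    out = Path(path)
    out.write_bytes(header + text + payload)
    return out


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

def read_csv_cells(path: str | Path, panel: Panel | None = None) -> CytoTable:
    """Read a header-row CSV of cells into a CytoTable.

    Without an explicit panel, every numeric column whose name does not mark
    it as an annotation (a leading "." as used by augmenting verbs, or
    ``sample_id``) becomes a marker-class panel entry.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    try:
        df = pd.read_csv(p)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{p}: no data") from exc
    except pd.errors.ParserError as exc:
        raise CorruptFileError(f"{p}: {exc}") from exc
    if len(df) == 0:
        raise EmptyInputError(f"{p}: header only, no cells")
    if panel is None:
        numeric = [
            c for c in df.columns
            if pd.api.types.is_numeric_dtype(df[c])
            and not str(c).startswith(".")
            and c != "sample_id"
        ]
        panel = Panel.from_columns(numeric)
    else:
        for c in panel.column_names:
            if c in df.columns and not pd.api.types.is_numeric_dtype(df[c]):
                raise CorruptFileError(f"{p}: channel column {c!r} is not numeric")
    return CytoTable(df, panel=panel)


def write_csv_cells(table: CytoTable, path: str | Path) -> Path:
    """Write all columns (channels and annotations) as RFC-4180-style CSV.

    Floats are printed with 17 significant digits so 64-bit values survive
    the round trip bit-exactly.
    """
    if len(table) == 0:
        raise EmptyInputError("refusing to write an empty cell table")
    out = Path(path)
    pd.DataFrame(table).to_csv(out, index=False, float_format="%.17g")
    return out
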