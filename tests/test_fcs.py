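"""FCS and CSV I/O: round trips, dialect rules, malformed-file handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cytoverbs as cv
from cytoverbs.errors import (
    CorruptFileError,
    EmptyInputError,
    MissingPanelError,
    UnsupportedFormatError,
    UnsupportedModeError,
)

from conftest import make_table
from fcs_oracle import read_fcs_oracle


def test_roundtrip_known_matrix(tmp_path):
    """A written 2x3 float matrix reads back value-identical, columns in
    panel order, and the independent struct-based reader agrees."""
    t = make_table([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], ["x", "y", "z"])
    path = cv.write_fcs(t, tmp_path / "m.fcs")
    back, panel = cv.read_fcs(path)
    assert back.columns.tolist() == ["x", "y", "z"]
    np.testing.assert_array_equal(back.to_numpy(), t[["x", "y", "z"]].to_numpy())
    names, rows, kw = read_fcs_oracle(path)
    assert names == ["x", "y", "z"]
    np.testing.assert_allclose(np.array(rows), t.to_numpy(), rtol=0, atol=0)
    assert kw["$DATATYPE"] == "F" and kw["$MODE"] == "L" and kw["$PAR"] == "3"


def test_single_value_byte_level(tmp_path):
    """A 1-cell, 1-channel file's DATA segment decodes to the single
    float 7.5 by byte-level inspection."""
    import struct

    path = cv.write_fcs(make_table([[7.5]], ["a"]), tmp_path / "one.fcs")
    raw = path.read_bytes()
    begin = int(raw[26:34].decode().strip())
    end = int(raw[34:42].decode().strip())
    assert end - begin + 1 == 4
    assert struct.unpack("<f", raw[begin : end + 1]) == (7.5,)


def test_panel_names_survive_roundtrip(tmp_path):
    panel = cv.Panel(
        [
            cv.PanelEntry("Yb171Di", "CD3", "marker"),
            cv.PanelEntry("Time", "Time", "technical"),
        ]
    )
    t = cv.CytoTable(pd.DataFrame({"CD3": [1.0], "Time": [2.0]}), panel=panel)
    back, p2 = cv.read_fcs(cv.write_fcs(t, tmp_path / "p.fcs"))
    assert [e.channel_name for e in p2.entries] == ["Yb171Di", "Time"]
    assert [e.antigen_name for e in p2.entries] == ["CD3", "Time"]
    assert [e.channel_class for e in p2.entries] == ["technical", "marker"][::-1]


@given(
    st.integers(1, 30),
    st.integers(1, 6),
    st.integers(0, 2**31 - 1),
)
def test_roundtrip_random_tables(tmp_path_factory, n_rows, n_cols, seed):
    """Property: read_fcs(write_fcs(t)) == t at 32-bit precision."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 1000, size=(n_rows, n_cols))
    t = make_table(vals, [f"ch{i}" for i in range(n_cols)])
    path = tmp_path_factory.mktemp("fcs") / "r.fcs"
    back, _ = cv.read_fcs(cv.write_fcs(t, path))
    np.testing.assert_array_equal(back.to_numpy(), vals.astype(np.float32))


def test_big_endian_twin_decodes_identically(tmp_path):
    """A big-endian DATA segment ($BYTEORD 4,3,2,1) decodes to the same
    matrix as its little-endian twin."""
    t = make_table([[1.5, -2.25], [3.0, 4e5]], ["a", "b"])
    little = cv.write_fcs(t, tmp_path / "le.fcs")
    raw = bytearray(little.read_bytes())
    # flip the payload and the $BYTEORD keyword by hand
    begin = int(raw[26:34].decode().strip())
    end = int(raw[34:42].decode().strip())
    payload = np.frombuffer(bytes(raw[begin : end + 1]), dtype="<f4")
    raw[begin : end + 1] = payload.astype(">f4").tobytes()
    idx = raw.find(b"1,2,3,4")
    raw[idx : idx + 7] = b"4,3,2,1"
    big = tmp_path / "be.fcs"
    big.write_bytes(bytes(raw))
    t_le, _ = cv.read_fcs(little)
    t_be, _ = cv.read_fcs(big)
    np.testing.assert_array_equal(t_le.to_numpy(), t_be.to_numpy())


def test_tot_mismatch_is_corrupt(tmp_path):
    path = cv.write_fcs(
        make_table(np.arange(30.0).reshape(10, 3), ["a", "b", "c"]),
        tmp_path / "c.fcs",
    )
    raw = bytearray(path.read_bytes())
    idx = raw.find(b"$TOT/10/")
    raw[idx : idx + 8] = b"$TOT/11/"  # claims 11 rows, holds 10
    bad = tmp_path / "bad.fcs"
    bad.write_bytes(bytes(raw))
    with pytest.raises(CorruptFileError):
        cv.read_fcs(bad)


def test_pns_fallback_to_pnn(tmp_path):
    """Missing $PnS for a parameter names its column by $PnN."""
    panel = cv.Panel([cv.PanelEntry("Ch1", "CD4"), cv.PanelEntry("Raw2", "Pretty2")])
    t = cv.CytoTable(pd.DataFrame({"CD4": [1.0], "Pretty2": [2.0]}), panel=panel)
    path = cv.write_fcs(t, tmp_path / "s.fcs")
    # blank out parameter 2's $PnS keyword with an equal-length custom key
    raw = path.read_bytes().replace(b"$P2S/Pretty2/", b"$P2X/Pretty2/")
    nopns = tmp_path / "nopns.fcs"
    nopns.write_bytes(raw)
    back, _ = cv.read_fcs(nopns)
    assert back.columns.tolist() == ["CD4", "Raw2"]


def test_unsupported_version_and_mode(tmp_path):
    path = cv.write_fcs(make_table([[1.0]], ["a"]), tmp_path / "v.fcs")
    raw = bytearray(path.read_bytes())
    raw[0:6] = b"FCS2.0"
    bad = tmp_path / "v2.fcs"
    bad.write_bytes(bytes(raw))
    with pytest.raises(UnsupportedFormatError):
        cv.read_fcs(bad)

    raw = bytearray(path.read_bytes())
    idx = raw.find(b"$MODE/L/")
    raw[idx : idx + 8] = b"$MODE/U/"
    bad2 = tmp_path / "mode.fcs"
    bad2.write_bytes(bytes(raw))
    with pytest.raises(UnsupportedModeError):
        cv.read_fcs(bad2)


def test_write_fcs_contract_errors(tmp_path):
    t = make_table([[1.0]], ["a"])
    object.__setattr__(t, "panel", None)
    with pytest.raises(MissingPanelError):
        cv.write_fcs(t, tmp_path / "x.fcs")
    empty = make_table(np.empty((0, 1)), ["a"])
    with pytest.raises(EmptyInputError):
        cv.write_fcs(empty, tmp_path / "y.fcs")


# -- CSV ------------------------------------------------------------------

def test_csv_roundtrip_with_annotations(tmp_path):
    t = make_table([[0.1, 2.0], [3.0, 4.0]], ["a", "b"],
                   annotations={".cluster": ["1", "2"], "sample_id": "s1"})
    path = cv.write_csv_cells(t, tmp_path / "c.csv")
    back = cv.read_csv_cells(path)
    assert back[".cluster"].astype(str).tolist() == ["1", "2"]
    assert back.marker_columns == ["a", "b"]
    # 0.1 survives bit-exactly at 64-bit precision
    assert back["a"].iloc[0] == 0.1
    np.testing.assert_array_equal(back[["a", "b"]].to_numpy(),
                                  t[["a", "b"]].to_numpy())


def test_csv_inline_parse():
    import io

    df = pd.read_csv(io.StringIO("a,b\n1,2\n3,4"))
    assert df.shape == (2, 2)  # sanity for the fixture below


def test_csv_small_table(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("a,b\n1,2\n3,4\n")
    t = cv.read_csv_cells(p)
    assert t.shape == (2, 2)
    assert t.panel.column_names == ["a", "b"]


def test_csv_header_only_and_missing(tmp_path):
    p = tmp_path / "h.csv"
    p.write_text("a,b\n")
    with pytest.raises(EmptyInputError):
        cv.read_csv_cells(p)
    with pytest.raises(FileNotFoundError):
        cv.read_csv_cells(tmp_path / "nope.csv")


def test_csv_ragged_rows(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text("a,b\n1,2\n3,4,5\n")
    with pytest.raises(CorruptFileError):
        cv.read_csv_cells(p)
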