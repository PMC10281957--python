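"""Minimal independent FCS 3.x reader used as a cross-check oracle.

Written directly from the FCS byte layout using only the standard library
``struct`` module; deliberately shares no code with the package's parser.
Supports what the package's writer emits (float32, list mode) — enough to
verify files independently.
"""

import struct


def read_fcs_oracle(path):
    raw = open(path, "rb").read()
    version = raw[0:6].decode("ascii")
    assert version in ("FCS3.0", "FCS3.1"), version
    text_begin = int(raw[10:18].decode("ascii").strip())
    text_end = int(raw[18:26].decode("ascii").strip())
    text = raw[text_begin : text_end + 1].decode("latin-1")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens.pop()
    kw = dict(zip(tokens[0::2], tokens[1::2]))

    tot = int(kw["$TOT"])
    par = int(kw["$PAR"])
    begin = int(kw.get("$BEGINDATA") or raw[26:34].decode("ascii").strip())
    end = int(kw.get("$ENDDATA") or raw[34:42].decode("ascii").strip())
    assert kw["$DATATYPE"] == "F"
    assert kw["$MODE"] == "L"
    endian = "<" if kw["$BYTEORD"].startswith("1") else ">"
    payload = raw[begin : end + 1]
    assert len(payload) == 4 * tot * par, (len(payload), tot, par)
    flat = struct.unpack(f"{endian}{tot * par}f", payload)
    names = [kw.get(f"$P{i}S") or kw[f"$P{i}N"] for i in range(1, par + 1)]
    rows = [list(flat[r * par : (r + 1) * par]) for r in range(tot)]
    return names, rows, kw
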