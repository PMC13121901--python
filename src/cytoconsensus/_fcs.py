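"""Minimal FCS 3.0/3.1 list-mode reader and fixture writer.

Supports the subset of the standard this package needs: list-mode
(``$MODE/L``), float/double/integer data, the two common byte orders,
``$PnE`` log-amplification and ``$PnG`` gain de-scaling so returned
values are on the linear scale. Anything else is rejected loudly rather
than guessed. The writer emits simple float32 FCS 3.1 files and exists
to produce round-trippable fixtures, not production exports.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError

_SUPPORTED_VERSIONS = (b"FCS3.0", b"FCS3.1")


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of tokens")
    kw: dict[str, str] = {}
    for key, value in zip(parts[0::2], parts[1::2]):
        kw[key.decode("ascii", "replace").strip().upper()] = value.decode(
            "ascii", "replace"
        ).strip()
    return kw


def read_fcs(path: str) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS 3.0/3.1 list-mode file.

    Returns ``(values, channel_names, keywords)`` with values on the
    linear scale (``$PnE`` and ``$PnG`` applied).
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = raw[0:6]
    if version not in _SUPPORTED_VERSIONS:
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(a: int, b: int) -> int:
        field = raw[a:b].decode("ascii", "replace").strip()
        return int(field) if field else 0

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    kw = _parse_text_segment(raw[text_start : text_end + 1])

    if kw.get("$MODE", "L") != "L":
        raise FormatError(f"{path}: only list-mode ($MODE/L) is supported")
    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FormatError(f"{path}: $DATATYPE/F requires 32-bit parameters")
        dtype = np.dtype(f"{endian}f4")
        data = np.frombuffer(raw[data_start : data_end + 1], dtype=dtype,
                             count=n_par * n_tot)
        values = data.reshape(n_tot, n_par).astype(np.float64)
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise FormatError(f"{path}: $DATATYPE/D requires 64-bit parameters")
        dtype = np.dtype(f"{endian}f8")
        data = np.frombuffer(raw[data_start : data_end + 1], dtype=dtype,
                             count=n_par * n_tot)
        values = data.reshape(n_tot, n_par).astype(np.float64)
    elif datatype == "I":
        if any(b not in (8, 16, 32, 64) for b in bits):
            raise FormatError(f"{path}: integer widths must be 8/16/32/64 bits")
        fields = [(f"p{i}", f"{endian}u{b // 8}") for i, b in enumerate(bits)]
        rec = np.dtype(fields)
        data = np.frombuffer(raw[data_start : data_start + rec.itemsize * n_tot],
                             dtype=rec, count=n_tot)
        values = np.column_stack(
            [data[f"p{i}"].astype(np.float64) for i in range(n_par)]
        )
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    names: list[str] = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}"
        names.append(name)

    # De-scale to linear: $PnE/f1,f2/ is log amplification over $PnR decades;
    # $PnG is a linear gain divisor.
    for i in range(1, n_par + 1):
        pne = kw.get(f"$P{i}E", "0,0")
        try:
            f1, f2 = (float(x) for x in pne.split(","))
        except ValueError as exc:
            raise FormatError(f"{path}: malformed $P{i}E {pne!r}") from exc
        if f1 > 0:
            f2 = f2 if f2 > 0 else 1.0  # FCS3.0 quirk: f2=0 means 1
            rng = float(kw.get(f"$P{i}R", "1024"))
            values[:, i - 1] = f2 * 10.0 ** (f1 * values[:, i - 1] / rng)
        else:
            gain = float(kw.get(f"$P{i}G", "1") or "1")
            if gain not in (0.0, 1.0):
                values[:, i - 1] = values[:, i - 1] / gain
    return values, names, kw


def write_fcs(path: str, values: np.ndarray, names: list[str]) -> None:
    """Write a float32 little-endian FCS 3.1 fixture file."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2 or values.shape[1] != len(names):
        raise FormatError("values must be 2-D with one column per channel")
    n_tot, n_par = values.shape
    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        ("$MODE", "L"), ("$DATATYPE", "F"), ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)), ("$TOT", str(n_tot)), ("$NEXTDATA", "0"),
    ]
    for i, name in enumerate(names, start=1):
        kw += [(f"$P{i}N", name), (f"$P{i}B", "32"), (f"$P{i}E", "0,0"),
               (f"$P{i}R", str(int(max(1024, np.ceil(values[:, i - 1].max(initial=0)) + 1)))) ]

    delim = "/"

    def render(begin_data: int, end_data: int) -> bytes:
        pairs = kw + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs) + delim
        return text.encode("ascii")

    header_len = 58
    # Fixed-point iteration: offsets depend on the rendered TEXT length.
    begin_data = end_data = 0
    for _ in range(8):
        text = render(begin_data, end_data)
        new_begin = header_len + len(text)
        new_end = new_begin + values.nbytes - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = render(begin_data, end_data)
    text_start = header_len
    text_end = text_start + len(text) - 1
    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{begin_data:>8d}".encode()
        + f"{end_data:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.astype("<f4").tobytes())
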