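"""Minimal FCS 3.1 list-mode reader/writer.

Supports the subset produced by kinetic (continuous) acquisitions:
float32 list-mode data, little-endian, one TIME parameter scaled by
$TIMESTEP, linear amplification.  This is not a general FCS library —
log-amplified or integer data and analysis segments are out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trace_processing import CHANNELS, EventStream

_DELIM = "/"


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [""]
    for k, v in keywords.items():
        parts.append(k)
        parts.append(str(v))
    parts.append("")
    return _DELIM.join(parts).encode("ascii")


def write_fcs(stream: EventStream, path: str | Path,
              timestep_s: float = 1.0) -> None:
    """Write an event stream as an FCS 3.1 file with a TIME parameter."""
    names = ["TIME", *CHANNELS]
    data = np.column_stack(
        [stream.events["time_s"].to_numpy() / timestep_s]
        + [stream.events[c].to_numpy() for c in CHANNELS]
    ).astype("<f4")
    n_events, n_par = data.shape

    keywords = {
        "$FCSversion": "3.1",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$TIMESTEP": repr(timestep_s),
        "$CYT": "platekin synthetic",
    }
    for i, name in enumerate(names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(float(data[:, i - 1].max()), 1.0))
                                  + 1)

    header_len = 58
    # two-pass: offsets depend on the text length, which contains them
    for _ in range(3):
        text = _text_segment({**keywords})
        data_start = header_len + len(text)
        data_end = data_start + data.nbytes - 1
        keywords["$BEGINDATA"] = str(data_start)
        keywords["$ENDDATA"] = str(data_end)
        new_text = _text_segment(keywords)
        if len(new_text) == len(text):
            text = new_text
            break
        header_len = 58  # recompute with updated offset widths
    text = _text_segment(keywords)
    data_start = header_len + len(text)
    data_end = data_start + data.nbytes - 1
    keywords["$BEGINDATA"] = str(data_start)
    keywords["$ENDDATA"] = str(data_end)
    text = _text_segment(keywords)

    text_start = header_len
    text_end = text_start + len(text) - 1
    header = (f"FCS3.1    "
              f"{text_start:>8d}{text_end:>8d}"
              f"{data_start:>8d}{data_end:>8d}"
              f"{0:>8d}{0:>8d}").encode("ascii")
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path: str | Path, donor_id: str | None = None) -> EventStream:
    """Read a float32 list-mode FCS 3.0/3.1 file with a TIME parameter."""
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError("not an FCS 3.0/3.1 file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start:text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    fields = text.strip(delim).split(delim)
    kw = {fields[i].strip(): fields[i + 1]
          for i in range(0, len(fields) - 1, 2)}

    if kw.get("$DATATYPE", "F").upper() != "F":
        raise ValueError("only float ($DATATYPE F) data supported")
    if kw.get("$MODE", "L").upper() != "L":
        raise ValueError("only list mode ($MODE L) supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if byteord.startswith("1") else ">f4"

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    data_end = int(kw.get("$ENDDATA") or raw[34:42])
    data = np.frombuffer(raw[data_start:data_end + 1], dtype=dtype,
                         count=n_par * n_tot).reshape(n_tot, n_par)

    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    df = pd.DataFrame(np.asarray(data, dtype=float), columns=names)
    if "TIME" not in df.columns:
        raise ValueError("FCS file lacks a TIME parameter")
    timestep = float(kw.get("$TIMESTEP", 1.0))
    df["time_s"] = df.pop("TIME") * timestep
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"FCS file lacks channels {missing}")
    df = df[["time_s", *CHANNELS]].sort_values("time_s",
                                               ignore_index=True)
    return EventStream(donor_id=donor_id or Path(path).stem, events=df)
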