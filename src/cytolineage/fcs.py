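"""Minimal FCS 3.1 input/output.

Only the subset of the standard this pipeline needs: list-mode ($MODE L)
float32 data ($DATATYPE F, $PnB 32, $PnE 0,0) in a single data segment with
little-endian byte order.  Values round-trip within float32 precision.
Sample-level metadata travels in a TSV sidecar (``samples.tsv``) rather than
in FCS keywords, keeping the event files plain and tool-agnostic.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventMatrix, concat_events

_DELIM = "/"
_HEADER_VERSION = b"FCS3.1"

#: Sidecar columns describing each written sample.
SIDECAR_COLUMNS = ["sample_id", "batch_id", "tissue", "is_anchor"]


class FCSError(ValueError):
    pass


def write_fcs_file(path: str | os.PathLike, values: np.ndarray,
                   channels: list[str]) -> None:
    """Write one events x channels matrix as a float32 FCS 3.1 file."""
    values = np.asarray(values, dtype="<f4")
    if values.ndim != 2 or values.shape[0] == 0:
        raise FCSError("FCS data must be a non-empty 2-D events x channels array")
    n_events, n_par = values.shape
    if n_par != len(channels):
        raise FCSError("channel name count does not match data columns")
    if len(set(channels)) != len(channels) or any(not c for c in channels):
        raise FCSError("channel names must be non-empty and unique")

    data = values.tobytes()
    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        # zero-padded so the TEXT length is independent of the final offsets
        ("$BEGINDATA", "%012d"), ("$ENDDATA", "%012d"),
        ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"), ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)), ("$TOT", str(n_events)),
    ]
    for i, name in enumerate(channels, start=1):
        if _DELIM in name:
            raise FCSError(f"channel name {name!r} contains the delimiter {_DELIM!r}")
        keywords += [(f"$P{i}N", name), (f"$P{i}B", "32"), (f"$P{i}E", "0,0"),
                     (f"$P{i}R", str(int(max(1.0, float(np.nanmax(values[:, i - 1])) + 1)))) ]

    def render(begin: int, end: int) -> bytes:
        parts = [_DELIM]
        for key, val in keywords:
            if key == "$BEGINDATA":
                val = "%012d" % begin
            elif key == "$ENDDATA":
                val = "%012d" % end
            parts += [key, _DELIM, val, _DELIM]
        return "".join(parts).encode("ascii")

    header_len = 58  # 6 version + 4 spaces + 6 offsets x 8 chars
    text = render(0, 0)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1
    text = render(data_start, data_end)

    def off(x: int) -> bytes:
        # header offset fields hold at most 8 digits; larger go to 0 with the
        # true value carried in $BEGINDATA/$ENDDATA
        return (b"%8d" % x) if x <= 99_999_999 else b"%8d" % 0

    header = (_HEADER_VERSION + b"    " + off(text_start) + off(text_end)
              + off(data_start) + off(data_end) + off(0) + off(0))
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def _parse_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise FCSError("empty TEXT segment")
    delim = segment[:1].decode("latin-1")
    tokens = segment.decode("latin-1").split(delim)[1:]
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise FCSError("TEXT segment has an odd number of tokens")
    return {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def read_fcs_file(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Read a float32/float64 list-mode FCS file -> (values, channel names)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58 or not raw[:3] == b"FCS":
        raise FCSError(f"{path} is not an FCS file")
    offs = [raw[10 + 8 * i: 18 + 8 * i].decode("ascii").strip() for i in range(4)]
    text_start, text_end, data_start, data_end = (int(o or 0) for o in offs)
    text = _parse_text(raw[text_start: text_end + 1])
    if not data_start:
        data_start = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype = text.get("$DATATYPE", "F").upper()
    if dtype not in ("F", "D"):
        raise FCSError(f"unsupported $DATATYPE {dtype!r} (only float data handled)")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if dtype == "F" else 8
    data = raw[data_start: data_end + 1]
    expected = n_par * n_tot * itemsize
    if len(data) < expected:
        raise FCSError(f"truncated data segment in {path}")
    values = np.frombuffer(data[:expected], dtype=f"{endian}f{itemsize}")
    values = values.reshape(n_tot, n_par).astype(np.float64)
    channels = [text.get(f"$P{i}N", f"ch{i}") for i in range(1, n_par + 1)]
    return values, channels


# ---------------------------------------------------------------------------
# EventMatrix-level IO
# ---------------------------------------------------------------------------

def write_fcs(events: EventMatrix, directory: str | os.PathLike) -> list[Path]:
    """Write one FCS file per sample plus a ``samples.tsv`` metadata sidecar.

    Returns the written FCS paths.  Truth columns, if present, are written to
    ``truth.tsv`` alongside so simulations stay fully reconstructable.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sample_ids = events.meta["sample_id"]
    paths: list[Path] = []
    rows = []
    for sample_id, idx in sample_ids.groupby(sample_ids).groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise FCSError(f"sample {sample_id} has zero events")
        path = directory / f"{sample_id}.fcs"
        write_fcs_file(path, events.values[idx], events.channels)
        paths.append(path)
        first = events.meta.iloc[idx[0]]
        rows.append({
            "sample_id": sample_id,
            "batch_id": first["batch_id"],
            "tissue": first["tissue"],
            "is_anchor": bool(first.get("is_anchor", False)),
        })
    sidecar = pd.DataFrame(rows, columns=SIDECAR_COLUMNS).sort_values("sample_id")
    sidecar.to_csv(directory / "samples.tsv", sep="\t", index=False)
    truth_cols = [c for c in ("population", "branch", "latent_time")
                  if c in events.meta.columns]
    if truth_cols:
        events.meta[["sample_id", *truth_cols]].to_csv(
            directory / "truth.tsv", sep="\t", index=False)
    return sorted(paths)


def read_fcs_set(paths: list[str | os.PathLike],
                 metadata: pd.DataFrame | str | os.PathLike) -> EventMatrix:
    """Read and concatenate FCS files, attaching per-sample metadata.

    ``metadata`` is a DataFrame (or TSV path) with one row per sample id and
    at least the sidecar columns.  Channel order is harmonized to the first
    file; a missing channel in any file is an error naming the channel.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t")
    metadata = metadata.set_index("sample_id", drop=False)
    parts: list[EventMatrix] = []
    ref_channels: list[str] | None = None
    for path in paths:
        values, channels = read_fcs_file(path)
        sample_id = Path(path).stem
        if sample_id not in metadata.index:
            raise FCSError(f"no metadata row for sample {sample_id!r}")
        if ref_channels is None:
            ref_channels = channels
        else:
            missing = set(ref_channels) ^ set(channels)
            if missing:
                raise FCSError(
                    f"channel-set mismatch at {Path(path).name}: {sorted(missing)}")
        row = metadata.loc[sample_id]
        meta = pd.DataFrame({
            "sample_id": sample_id,
            "batch_id": row["batch_id"],
            "tissue": row["tissue"],
            "is_anchor": bool(row.get("is_anchor", False)),
        }, index=range(values.shape[0]))
        parts.append(EventMatrix(values, channels, meta, scale="raw"))
    return concat_events(parts)
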