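"""Flow-cytometry event tables: FCS/CSV input, CSV output, and debris gating.

An :class:`EventTable` is an ``n_events x n_channels`` matrix of per-cell
intensities in arbitrary units, together with unique channel names and sample
metadata. A :class:`ChannelMap` names which channels play which analysis role
(volume proxy components, reporter fluorescence, DNA stain).

CSV dialect: comma-separated, ``.`` decimal, mandatory header row of channel
names, metadata as ``#key=value`` comment lines before the header. FCS support
covers list-mode FCS 3.0/3.1 with linearly scaled parameters ($PnE = 0,0);
log-amplified channels are rejected rather than silently converted.
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FcsFormatError, MissingChannelError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMeta",
    "EventTable",
    "ChannelMap",
    "load_events",
    "write_events",
    "gate_debris",
]

_META_FIELDS = ("sample_id", "strain_id", "dose_atc", "medium", "time_h")


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level annotations carried alongside the event matrix."""

    sample_id: str = "sample"
    strain_id: str = ""
    dose_atc: float = 0.0
    medium: str = ""
    time_h: float = 0.0

    def __post_init__(self):
        if self.dose_atc < 0:
            raise ParameterError(f"dose_atc must be >= 0, got {self.dose_atc}")
        if self.time_h < 0:
            raise ParameterError(f"time_h must be >= 0, got {self.time_h}")


@dataclass
class EventTable:
    """Per-cell multichannel intensity matrix with sample metadata.

    Intensities are float64 and must be finite; values <= 0 (possible after
    instrument baseline subtraction) are retained at load and handled by each
    downstream operation.
    """

    events: np.ndarray
    channel_names: tuple[str, ...]
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self):
        ev = np.asarray(self.events, dtype=np.float64)
        if ev.ndim != 2:
            raise ParameterError(f"events must be 2-D, got shape {ev.shape}")
        if ev.shape[0] < 1:
            raise ParameterError("EventTable requires n_events >= 1")
        if not np.all(np.isfinite(ev)):
            raise ParameterError("event intensities must all be finite")
        names = tuple(str(n) for n in self.channel_names)
        if len(names) != ev.shape[1]:
            raise ParameterError(
                f"{len(names)} channel names for {ev.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            raise ParameterError(f"channel names must be unique: {names}")
        self.events = ev
        self.channel_names = names

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D array; raises MissingChannelError."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise MissingChannelError(name, self.channel_names) from None
        return self.events[:, idx]

    def take(self, row_index: np.ndarray) -> "EventTable":
        return EventTable(self.events[row_index], self.channel_names, self.meta)


@dataclass(frozen=True)
class ChannelMap:
    """Names of the channels playing each analysis role."""

    volume_x: str = "FSC-W"
    volume_y: str = "SSC-H"
    reporter: str = "FL1"
    dna: str = "DNA"

    def __post_init__(self):
        if self.volume_x == self.volume_y:
            raise ParameterError(
                "volume_x and volume_y must name different channels"
            )

    def validate(self, t: EventTable, roles=("volume_x", "volume_y", "reporter", "dna")):
        """Check that every listed role resolves on ``t``."""
        for role in roles:
            t.channel(getattr(self, role))


def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    # Escaped delimiters (doubled) are not supported; plain split suffices for
    # instrument files with sane keyword values.
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FcsFormatError("FCS TEXT segment has an odd number of tokens")
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def _read_fcs(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58:
            raise FcsFormatError(f"{path}: truncated FCS header")
        version = header[:6].decode("latin-1")
        if version not in ("FCS3.0", "FCS3.1"):
            raise FcsFormatError(
                f"{path}: unsupported FCS version {version!r} (need 3.0/3.1)"
            )
        text_begin = int(header[10:18])
        text_end = int(header[18:26])
        data_begin = int(header[26:34])
        data_end = int(header[34:42])
        fh.seek(text_begin)
        text = _parse_fcs_text(fh.read(text_end - text_begin + 1))

        if text.get("$MODE", "L") != "L":
            raise FcsFormatError(f"{path}: only list-mode ($MODE=L) supported")
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text["$DATATYPE"]
        byteord = text["$BYTEORD"]
        if byteord in ("1,2,3,4", "1,2"):
            endian = "<"
        elif byteord in ("4,3,2,1", "2,1"):
            endian = ">"
        else:
            raise FcsFormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

        names, widths = [], []
        for i in range(1, n_par + 1):
            pne = text.get(f"$P{i}E", "0,0").replace(" ", "")
            if pne not in ("0,0", "0.0,0.0", "0,0.0", "0.0,0"):
                raise FcsFormatError(
                    f"{path}: channel $P{i}N is log-amplified ($P{i}E={pne}); "
                    "only linear-scaled parameters ($PnE=0,0) are supported"
                )
            names.append(text.get(f"$P{i}N", f"P{i}"))
            widths.append(int(text[f"$P{i}B"]))

        if datatype == "F":
            if any(w != 32 for w in widths):
                raise FcsFormatError(f"{path}: $DATATYPE=F requires 32-bit $PnB")
            dtype = np.dtype(endian + "f4")
        elif datatype == "D":
            if any(w != 64 for w in widths):
                raise FcsFormatError(f"{path}: $DATATYPE=D requires 64-bit $PnB")
            dtype = np.dtype(endian + "f8")
        elif datatype == "I":
            if len(set(widths)) != 1 or widths[0] not in (16, 32):
                raise FcsFormatError(
                    f"{path}: $DATATYPE=I needs uniform 16- or 32-bit $PnB"
                )
            dtype = np.dtype(endian + ("u2" if widths[0] == 16 else "u4"))
        else:
            raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

        if data_begin == 0:
            data_begin = int(text["$BEGINDATA"])
            data_end = int(text["$ENDDATA"])
        fh.seek(data_begin)
        n_bytes = n_tot * n_par * dtype.itemsize
        if data_end and data_end - data_begin + 1 < n_bytes:
            raise FcsFormatError(f"{path}: DATA segment shorter than $TOT*$PAR")
        buf = fh.read(n_bytes)
        if len(buf) < n_bytes:
            raise FcsFormatError(f"{path}: truncated DATA segment")

    arr = np.frombuffer(buf, dtype=dtype).reshape(n_tot, n_par)
    return arr.astype(np.float64), tuple(names)


def _meta_from_comments(lines: list[str]) -> dict:
    kv = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, val = body.split("=", 1)
            key = key.strip()
            if key in _META_FIELDS:
                kv[key] = val.strip()
    for key in ("dose_atc", "time_h"):
        if key in kv:
            kv[key] = float(kv[key])
    return kv


def load_events(
    path,
    format: str | None = None,
    channel_map: ChannelMap | None = None,
    meta: SampleMeta | None = None,
) -> EventTable:
    """Load an event table from an FCS 3.0/3.1 or CSV file.

    Parameters
    ----------
    path : path-like
    format : {"fcs", "csv"}, optional
        Inferred from the file suffix when omitted.
    channel_map : ChannelMap, optional
        When given, every mapped role is checked to resolve on the loaded
        table; a missing channel raises :class:`MissingChannelError`.
    meta : SampleMeta, optional
        Overrides any metadata found in the file.
    """
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format not in ("fcs", "csv"):
        raise ParameterError(f"format must be 'fcs' or 'csv', got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "fcs":
        events, names = _read_fcs(path)
        file_meta = {}
    else:
        comments = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    comments.append(line)
                else:
                    break
        df = pd.read_csv(path, comment="#", dtype=np.float64,
                         float_precision="round_trip")
        if df.shape[0] == 0:
            raise ParameterError(f"{path}: no event rows")
        events = df.to_numpy(dtype=np.float64)
        names = tuple(df.columns)
        file_meta = _meta_from_comments(comments)

    if meta is None:
        meta = SampleMeta(**file_meta) if file_meta else SampleMeta()
    table = EventTable(events, names, meta)
    if channel_map is not None:
        channel_map.validate(table)
    return table


def write_events(t: EventTable, path, format: str = "csv") -> Path:
    """Write an event table as CSV with ``#key=value`` metadata comments.

    Values are written with 17 significant digits so the write/load
    round-trip is bit-exact on float64 intensities.
    """
    if format != "csv":
        raise ParameterError(f"only 'csv' output is supported, got {format!r}")
    if not str(path):
        raise OSError("empty output path")
    path = Path(path)
    buf = io.StringIO()
    for key in _META_FIELDS:
        buf.write(f"#{key}={getattr(t.meta, key)}\n")
    buf.write(",".join(t.channel_names) + "\n")
    np.savetxt(buf, t.events, fmt="%.17g", delimiter=",")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def gate_debris(
    t: EventTable, frac: float, channel_map: ChannelMap | None = None
) -> EventTable:
    """Remove putative debris: events below the ``frac`` quantile of FSC-A.

    Falls back to the ``volume_x`` channel when FSC-A is absent. ``frac=0``
    returns the table unchanged (the default policy: ungated). Ties are kept:
    events exactly at the threshold are retained.
    """
    if not 0 <= frac < 0.5:
        raise ParameterError(
            f"debris fraction must be in [0, 0.5), got {frac}"
        )
    if frac == 0:
        return t
    cmap = channel_map or ChannelMap()
    if "FSC-A" in t.channel_names:
        vals = t.channel("FSC-A")
    else:
        vals = t.channel(cmap.volume_x)
    threshold = np.quantile(vals, frac)
    keep = vals >= threshold
    logger.info(
        "gate_debris: kept %d of %d events (frac=%g, threshold=%g)",
        int(keep.sum()), t.n_events, frac, threshold,
    )
    return t.take(keep)


def with_meta(t: EventTable, **kwargs) -> EventTable:
    """Return a copy of ``t`` with updated metadata fields."""
    return EventTable(t.events, t.channel_names, replace(t.meta, **kwargs))
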