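"""Event sinks and file formats: ``firing.csv`` and ``burning.csv``.

``firing.csv`` holds one row per spike emission (``t,node,neuron,external``;
external = 1 marks fictive input sources, whose id is in the neuron column).
``burning.csv`` holds one row per pulse delivery
(``t_burn,node_burn,neuron_burn,node_fire,neuron_fire,t_fire,weight``),
with ``t_burn = t_fire + delay`` exactly, and ``node_fire = 'ext'`` for
external pulses.  Values are comma-separated with '.' decimals; floats are
written with the shortest round-tripping representation, so
write -> read -> write is byte-stable.

Sinks buffer at most ``S_b`` records between flushes (the serialization
buffer), so file output never holds more than one buffer in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FIRING_HEADER",
    "BURNING_HEADER",
    "CsvSink",
    "EventLog",
    "write_event_files",
    "read_event_files",
    "sort_event_file",
]

FIRING_HEADER = ("t", "node", "neuron", "external")
BURNING_HEADER = ("t_burn", "node_burn", "neuron_burn",
                  "node_fire", "neuron_fire", "t_fire", "weight")

_FIRING_DTYPES = {"t": np.float64, "node": str, "neuron": np.int64, "external": np.int8}
_BURNING_DTYPES = {"t_burn": np.float64, "node_burn": str, "neuron_burn": np.int64,
                   "node_fire": str, "neuron_fire": np.int64,
                   "t_fire": np.float64, "weight": np.float64}


class FormatError(ValueError):
    """Event file does not match the expected schema."""


def _fmt(x) -> str:
    # shortest repr for floats; plain str otherwise
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    return str(x)


class CsvSink:
    """Buffered CSV writer flushing every ``S_b`` records.

    ``max_buffered`` exposes the peak buffer occupancy (for memory-bound
    checks); ``n_flushes`` counts physical writes.
    """

    def __init__(self, path, header: Tuple[str, ...], S_b: int = 100_000):
        if S_b < 1:
            raise ValueError("S_b must be >= 1")
        self.path = Path(path)
        self.header = tuple(header)
        self.S_b = int(S_b)
        self._buf: List[str] = []
        self.max_buffered = 0
        self.n_flushes = 0
        self.n_records = 0
        try:
            self._fh = open(self.path, "w")
        except OSError as e:
            raise OSError(f"cannot open sink {self.path}: {e}") from e
        self._fh.write(",".join(self.header) + "\n")

    def write_row(self, row) -> None:
        self._buf.append(",".join(_fmt(x) for x in row) + "\n")
        self.n_records += 1
        if len(self._buf) > self.max_buffered:
            self.max_buffered = len(self._buf)
        if len(self._buf) >= self.S_b:
            self.flush()

    def write_frame(self, df: pd.DataFrame) -> None:
        for tup in df.itertuples(index=False, name=None):
            self.write_row(tup)

    def flush(self) -> None:
        if self._buf:
            try:
                self._fh.writelines(self._buf)
                self._fh.flush()
            except OSError as e:
                raise OSError(f"flush to {self.path} failed; file is partial: {e}") from e
            self._buf.clear()
            self.n_flushes += 1

    def close(self) -> None:
        self.flush()
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False


@dataclass
class EventLog:
    """In-memory twin of the firing/burning CSV pair."""

    firing: pd.DataFrame
    burning: Optional[pd.DataFrame] = None

    @classmethod
    def from_result(cls, result) -> "EventLog":
        return cls(firing=result.firing, burning=result.burning)

    def write(self, out_dir, S_b: int = 100_000) -> Tuple[Path, Optional[Path]]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fpath = out / "firing.csv"
        with CsvSink(fpath, FIRING_HEADER, S_b) as sink:
            sink.write_frame(self.firing)
        bpath = None
        if self.burning is not None:
            bpath = out / "burning.csv"
            with CsvSink(bpath, BURNING_HEADER, S_b) as sink:
                sink.write_frame(self.burning)
        return fpath, bpath

    @classmethod
    def read(cls, firing_path, burning_path=None) -> "EventLog":
        firing = _read_checked(firing_path, FIRING_HEADER, _FIRING_DTYPES)
        burning = None
        if burning_path is not None and Path(burning_path).exists():
            burning = _read_checked(burning_path, BURNING_HEADER, _BURNING_DTYPES)
        return cls(firing=firing, burning=burning)


def _read_checked(path, header, dtypes) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if tuple(first.split(",")) != tuple(header):
        raise FormatError(
            f"{path}: header {first!r} does not match expected {','.join(header)!r}")
    df = pd.read_csv(path, dtype=dtypes)
    return df


def write_event_files(log: EventLog, out_dir, S_b: int = 100_000):
    """Write ``firing.csv`` (and ``burning.csv`` if present) under ``out_dir``."""
    return log.write(out_dir, S_b=S_b)


def read_event_files(firing_path, burning_path=None) -> EventLog:
    """Read event files produced by :func:`write_event_files` (schema-checked)."""
    return EventLog.read(firing_path, burning_path)


def sort_event_file(path, out_path=None) -> Path:
    """Globally sort an event file by its time column (first column).

    Files written with periodic flushing are time-sorted within flush blocks;
    this utility produces a fully sorted copy.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    cols = tuple(first.split(","))
    if cols == FIRING_HEADER:
        dtypes = _FIRING_DTYPES
    elif cols == BURNING_HEADER:
        dtypes = _BURNING_DTYPES
    else:
        raise FormatError(f"{path}: unrecognized header {first!r}")
    df = pd.read_csv(path, dtype=dtypes).sort_values(cols[0], kind="stable")
    out_path = Path(out_path) if out_path is not None else path
    with CsvSink(out_path, cols) as sink:
        sink.write_frame(df)
    return out_path
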