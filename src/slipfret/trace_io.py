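"""Reading, writing and basic transforms of smFRET trace artifacts.

A *trace* is one immobilized molecule's donor/acceptor intensity time
series after photobleach trimming, sampled on a uniform camera clock
(50 ms frames by default).  FRET efficiency is the uncorrected proximity
ratio ``E = I_A / (I_D + I_A)``; gamma and crosstalk corrections are
assumed to have happened upstream.

On-disk formats (all plain text):

* trace file — whitespace- or comma-delimited columns ``time_s donor
  acceptor``, optional ``#`` header lines;
* idealized-path file — TSV with header ``trace_id frame fret state
  ideal_fret``;
* matrices (TDP, FES) — dense CSV with one header row of bin centers;
* reports — JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("slipfret")

#: default camera exposure time in seconds (50 ms frames)
DEFAULT_DT = 0.05

#: numeric formatting used for every text artifact (6 significant digits)
FLOAT_FMT = "%.6g"

_DT_RTOL = 1e-9


class TraceIOError(RuntimeError):
    """Fatal error while reading or writing trace artifacts."""


def compute_fret(donor, acceptor):
    """FRET proximity ratio ``acceptor / (donor + acceptor)``.

    Frames with zero total intensity get the sentinel value 0 and a
    warning (bulk processing must not abort on isolated dropouts).
    Scale-invariant: ``compute_fret(c*d, c*a) == compute_fret(d, a)``
    for any ``c > 0``.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if np.any(donor < 0) or np.any(acceptor < 0):
        raise ValueError("intensities must be non-negative")
    total = donor + acceptor
    zero = total == 0
    if np.any(zero):
        n = int(np.count_nonzero(zero))
        warnings.warn(f"{n} frame(s) with zero total intensity; fret set to 0")
        logger.warning("%d zero-intensity frame(s) flagged", n)
    with np.errstate(invalid="ignore", divide="ignore"):
        fret = np.where(zero, 0.0, acceptor / np.where(zero, 1.0, total))
    if fret.ndim == 0:
        return float(fret)
    return fret


@dataclass
class Trace:
    """Donor/acceptor/FRET time series for one molecule.

    All four series share the same length; ``time`` is uniformly spaced.
    """

    trace_id: str
    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    fret: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        n = len(self.time)
        if n < 1:
            raise ValueError(f"trace {self.trace_id!r}: empty")
        for name in ("donor", "acceptor", "fret"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace {self.trace_id!r}: length mismatch in {name}")
        if n > 1:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError(f"trace {self.trace_id!r}: time not increasing")
            if not np.allclose(steps, steps[0], rtol=_DT_RTOL, atol=0):
                raise ValueError(f"trace {self.trace_id!r}: non-uniform dt")

    @property
    def dt(self) -> float:
        if len(self.time) > 1:
            return float(self.time[1] - self.time[0])
        return DEFAULT_DT

    def __len__(self) -> int:
        return len(self.time)

    @classmethod
    def from_intensities(cls, trace_id, time, donor, acceptor) -> "Trace":
        return cls(trace_id, np.asarray(time, float), np.asarray(donor, float),
                   np.asarray(acceptor, float),
                   np.atleast_1d(compute_fret(donor, acceptor)))


@dataclass
class TraceSet:
    """An ordered collection of traces from one sample, sharing dt."""

    sample_name: str
    traces: list[Trace]
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if not self.traces:
            raise ValueError("TraceSet must contain at least one trace")
        ids = [t.trace_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate trace_ids in TraceSet")
        for t in self.traces:
            if len(t) > 1 and not np.isclose(t.dt, self.dt, rtol=1e-6):
                raise ValueError(
                    f"trace {t.trace_id!r} dt {t.dt} != sample dt {self.dt}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    @property
    def n_frames(self) -> int:
        return sum(len(t) for t in self.traces)

    def fret_series(self) -> list[np.ndarray]:
        return [t.fret for t in self.traces]


# ---------------------------------------------------------------------------
# trace files
# ---------------------------------------------------------------------------

def _parse_trace_file(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise TraceIOError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not rows:
        raise TraceIOError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] < 3:
        raise TraceIOError(f"{path}: expected >= 3 columns (time, donor, acceptor)")
    return arr


def read_traces(path, layout: str = "per-file", sample_name: str | None = None) -> TraceSet:
    """Read a TraceSet from disk.

    ``layout='per-file'``: *path* is a directory, one text file per
    molecule.  ``layout='multi-column'``: *path* is a single file with
    columns ``time d1 a1 d2 a2 ...``.  FRET is computed on read; frames
    with zero total intensity get fret 0 and are logged.
    """
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"no such path: {path}")
    traces: list[Trace] = []
    if layout == "per-file":
        files = sorted(p for p in path.iterdir()
                       if p.is_file() and p.suffix in {".txt", ".dat", ".csv", ".tsv"})
        if not files:
            raise TraceIOError(f"no trace files (*.txt/*.dat/*.csv/*.tsv) in {path}")
        for f in files:
            arr = _parse_trace_file(f)
            traces.append(Trace.from_intensities(f.stem, arr[:, 0], arr[:, 1], arr[:, 2]))
        name = sample_name or path.name
    elif layout == "multi-column":
        arr = _parse_trace_file(path)
        n_pairs = (arr.shape[1] - 1) // 2
        if n_pairs < 1:
            raise TraceIOError(f"{path}: multi-column layout needs time + donor/acceptor pairs")
        for i in range(n_pairs):
            traces.append(Trace.from_intensities(
                f"{path.stem}_{i:04d}", arr[:, 0], arr[:, 1 + 2 * i], arr[:, 2 + 2 * i]))
        name = sample_name or path.stem
    else:
        raise ValueError(f"unknown layout {layout!r}; use 'per-file' or 'multi-column'")
    dt = traces[0].dt if len(traces[0]) > 1 else DEFAULT_DT
    return TraceSet(name, traces, dt=dt)


def write_traces(path, traceset: TraceSet) -> None:
    """Write one ``<trace_id>.txt`` per trace under directory *path*."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for t in traceset:
        out = path / f"{t.trace_id}.txt"
        with open(out, "w") as fh:
            fh.write("# time_s donor acceptor\n")
            for i in range(len(t)):
                fh.write(f"{FLOAT_FMT % t.time[i]} {FLOAT_FMT % t.donor[i]} "
                         f"{FLOAT_FMT % t.acceptor[i]}\n")


# ---------------------------------------------------------------------------
# idealized paths
# ---------------------------------------------------------------------------

IDEAL_HEADER = "trace_id\tframe\tfret\tstate\tideal_fret"


def write_idealized(path, discretized: Sequence) -> None:
    """Write idealized (Viterbi) paths as TSV.

    Columns: trace_id, 0-based frame index, raw fret, 1-based state
    index, idealized fret.  Round-trips losslessly through
    :func:`read_idealized` at the package's 6-significant-digit
    formatting.
    """
    if not discretized:
        raise ValueError("no discretized traces to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        with open(path, "w") as fh:
            fh.write(IDEAL_HEADER + "\n")
            for d in discretized:
                for i, (s, f_raw, f_id) in enumerate(
                        zip(d.state_path, d.fret, d.ideal_fret)):
                    fh.write(f"{d.trace_id}\t{i}\t{FLOAT_FMT % f_raw}\t{int(s)}\t"
                             f"{FLOAT_FMT % f_id}\n")
    except OSError as exc:
        raise TraceIOError(f"cannot write {path}: {exc}") from exc


def read_idealized(path) -> list:
    """Read an idealized-path TSV back into DiscretizedTrace objects."""
    from .hmm import DiscretizedTrace  # local import avoids a cycle

    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"no such file: {path}")
    per_trace: dict[str, list[tuple[int, float, int, float]]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != IDEAL_HEADER.strip():
            raise TraceIOError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise TraceIOError(f"{path}:{lineno}: expected 5 columns")
            tid = parts[0]
            if tid not in per_trace:
                per_trace[tid] = []
                order.append(tid)
            per_trace[tid].append(
                (int(parts[1]), float(parts[2]), int(parts[3]), float(parts[4])))
    out = []
    for tid in order:
        rows = sorted(per_trace[tid])
        out.append(DiscretizedTrace(
            trace_id=tid,
            state_path=np.array([r[2] for r in rows], dtype=int),
            ideal_fret=np.array([r[3] for r in rows], dtype=float),
            fret=np.array([r[1] for r in rows], dtype=float),
        ))
    return out


# ---------------------------------------------------------------------------
# matrices and reports
# ---------------------------------------------------------------------------

def write_matrix(path, grid: np.ndarray, axis: np.ndarray,
                 axis2: np.ndarray | None = None) -> None:
    """Dense CSV grid with one header row of bin centers.

    Rows follow *axis* (first dimension), columns *axis2* (defaults to
    *axis* for square grids such as TDPs).
    """
    grid = np.asarray(grid, dtype=float)
    cols = axis if axis2 is None else axis2
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(FLOAT_FMT % c for c in cols) + "\n")
        for row in grid:
            fh.write(",".join(FLOAT_FMT % v for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a CSV grid written by :func:`write_matrix` → (grid, col centers)."""
    path = Path(path)
    with open(path) as fh:
        cols = np.array([float(v) for v in fh.readline().split(",")])
        grid = np.array([[float(v) for v in line.split(",")]
                         for line in fh if line.strip()])
    return grid, cols


def write_report(path, report: dict) -> None:
    """JSON report writer; floats pass through python's repr (17 sig digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
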