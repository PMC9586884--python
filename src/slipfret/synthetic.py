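"""Synthetic smFRET trajectory generator for 3WJ slip-out dynamics.

Emulates camera-based (50 ms frame) smFRET recordings of DNA three-way
junctions whose slipped-out hairpin undergoes branch migration.  The
hidden kinetics are a continuous-time Markov chain over positional
isomers × branchpoint conformations; the observable is the FRET
efficiency, one Gaussian-noise level per hidden state.  A mobile 3WJ
with four positional isomers and two conformations per isomer has eight
hidden states; two pairs of them share a FRET level, so only six
distinct FRET values are observable — the degeneracy the TDP-BIC
analysis is expected to collapse.

Presets
-------
``cag10`` / ``ctg30`` / ``cag40``
    mobile 3WJs: 8 hidden states on a 4-isomer × 2-conformation grid,
    six distinct emission means taken from the measured state tables;
    the middle two levels are doubly degenerate.  ``cag40`` halves every
    transition rate of ``cag10`` (longer slip-outs migrate more slowly).
``hairpin2`` / ``static3wj`` / ``fullcomp3wj``
    two-state controls (hairpin dynamics, branchpoint conformers of an
    immobile junction, fully complementary junction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .trace_io import DEFAULT_DT, Trace, TraceSet

__all__ = [
    "KineticScheme", "GroundTruth", "build_preset", "simulate_traces",
    "stitch", "PRESET_NAMES",
]

#: total (donor + acceptor) intensity used to back-compute counts
TOTAL_INTENSITY = 1000.0

#: observed-FRET clipping range; wider than [0, 1] so the HMM sees the
#: realistic out-of-range excursions camera data contains
FRET_CLIP = (-0.2, 1.2)

# default kinetic parameters of the mobile-3WJ presets (s^-1)
FLIP_RATE = 2.0       # branchpoint conformational flip within an isomer
MIGRATION_RATE = 0.5  # branchpoint migration between neighboring isomers
#: outgoing rates of the second degenerate isomer are slowed by this
#: factor, so dwells pooled over a degenerate FRET level are genuinely
#: biexponential
DEGENERACY_RATE_FACTOR = 4.0

DEFAULT_BLEACH_MEAN_S = 30.0   # exponential pre-bleach trace length
DEFAULT_MAX_DURATION_S = 60.0
DEFAULT_MIN_FRAMES = 100
DEFAULT_N_TRACES = 300         # "several hundred" molecules per sample


@dataclass
class KineticScheme:
    """Hidden-state rate matrix plus FRET emission map for one sample.

    ``rate_matrix[i, j]`` (i != j) is the i→j transition rate in s⁻¹;
    diagonals are the negative row sums.  ``emission_mean`` may repeat
    values: distinct hidden states are allowed to share a FRET level.
    """

    name: str
    rate_matrix: np.ndarray
    emission_mean: np.ndarray
    emission_sd: np.ndarray
    bleach_rate: float = 1.0 / DEFAULT_BLEACH_MEAN_S
    dt: float = DEFAULT_DT
    #: sd of the per-molecule FRET offset applied to every level of a
    #: trace (dye environment heterogeneity); the unstitched analysis
    #: absorbs it per molecule, the stitched analysis sees extra states.
    #: Together with the TDP smoothing width and the HMM estimation
    #: scatter this puts the cluster widths near the measured 0.05–0.06
    #: state errors.
    level_offset_sd: float = 0.03

    def __post_init__(self):
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.emission_mean = np.asarray(self.emission_mean, dtype=float)
        self.emission_sd = np.asarray(self.emission_sd, dtype=float)
        q = self.rate_matrix
        n = self.n_states
        if q.shape != (n, n):
            raise ValueError("rate_matrix must be square and match emissions")
        off = q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.any(np.abs(q.sum(axis=1)) > 1e-12 * max(1.0, np.abs(q).max())):
            raise ValueError("rate_matrix rows must sum to 0")
        if np.any(self.emission_mean < 0) or np.any(self.emission_mean > 1):
            raise ValueError("emission means must lie in [0, 1]")
        if np.any(self.emission_sd <= 0) or np.any(self.emission_sd >= 0.5):
            raise ValueError("emission sds must lie in (0, 0.5)")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.level_offset_sd < 0:
            raise ValueError("level_offset_sd must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.emission_mean)

    @property
    def distinct_means(self) -> np.ndarray:
        return np.unique(self.emission_mean)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution π with πQ = 0, Σπ = 1."""
        n = self.n_states
        if n == 1:
            return np.ones(1)
        a = np.vstack([self.rate_matrix.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0, None)
        return pi / pi.sum()

    def mean_dwell(self) -> np.ndarray:
        """Expected dwell time per hidden state, 1 / exit rate (inf if absorbing)."""
        exit_rates = -np.diag(self.rate_matrix)
        with np.errstate(divide="ignore"):
            return np.where(exit_rates > 0, 1.0 / np.where(exit_rates > 0, exit_rates, 1.0),
                            np.inf)

    def to_yaml(self, path) -> None:
        """Write the scheme to a YAML file (editable preset override)."""
        import yaml
        data = {
            "name": self.name,
            "rate_matrix": self.rate_matrix.tolist(),
            "emission_mean": self.emission_mean.tolist(),
            "emission_sd": self.emission_sd.tolist(),
            "bleach_rate": float(self.bleach_rate),
            "dt": float(self.dt),
            "level_offset_sd": float(self.level_offset_sd),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KineticScheme":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# measured six-state FRET tables: (mean, sd) per distinct level, ascending
_STATE_TABLES = {
    "cag10": [(0.08, 0.05), (0.26, 0.06), (0.43, 0.05),
              (0.62, 0.06), (0.79, 0.05), (0.93, 0.05)],
    "ctg30": [(0.09, 0.05), (0.21, 0.06), (0.37, 0.05),
              (0.59, 0.05), (0.78, 0.06), (0.92, 0.05)],
    "cag40": [(0.08, 0.05), (0.26, 0.06), (0.42, 0.05),
              (0.58, 0.05), (0.77, 0.06), (0.91, 0.05)],
}

PRESET_NAMES = ("hairpin2", "static3wj", "fullcomp3wj", "cag10", "ctg30", "cag40")


def _mobile_scheme(name: str, rate_scale: float = 1.0) -> KineticScheme:
    """8-state mobile-3WJ scheme: 4 positional isomers × 2 conformations.

    State index s = 2*p + c (isomer p, conformation c).  Conformational
    flips exchange c within an isomer; migration moves p by ±1 keeping
    c.  Isomers 1 and 2 share the two middle FRET levels; isomer 2's
    outgoing rates are slowed ``DEGENERACY_RATE_FACTOR``-fold.
    """
    table = _STATE_TABLES[name]
    # isomer -> (low-FRET conf level, high-FRET conf level), by table index
    isomer_levels = [(0, 1), (2, 3), (2, 3), (4, 5)]
    f = DEGENERACY_RATE_FACTOR
    # Every edge carries the same rate in both directions, so the
    # stationary distribution is exactly uniform over the 8 hidden
    # states (each FRET level equally informative; the degenerate middle
    # levels carry twice the occupancy of the outer ones).  Edges
    # touching the slow degenerate isomer (2) are scaled by 1/f and the
    # fast partner's (1) flip rate is raised so the two isomers' total
    # exit rates differ by exactly f.
    flip = [FLIP_RATE, 0.0, FLIP_RATE / f, FLIP_RATE]
    mig = {(0, 1): MIGRATION_RATE,
           (1, 2): MIGRATION_RATE / f,
           (2, 3): MIGRATION_RATE / f}
    exit2 = FLIP_RATE / f + mig[(1, 2)] + mig[(2, 3)]
    flip[1] = f * exit2 - MIGRATION_RATE - mig[(1, 2)]
    n = 8
    q = np.zeros((n, n))
    for p in range(4):
        for c in range(2):
            s = 2 * p + c
            q[s, 2 * p + (1 - c)] += flip[p]
            for p2 in (p - 1, p + 1):
                if 0 <= p2 < 4:
                    q[s, 2 * p2 + c] += mig[(min(p, p2), max(p, p2))]
    q *= rate_scale
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    means = np.array([table[isomer_levels[p][c]][0]
                      for p in range(4) for c in range(2)])
    sds = np.array([table[isomer_levels[p][c]][1]
                    for p in range(4) for c in range(2)])
    return KineticScheme(name=name, rate_matrix=q, emission_mean=means,
                         emission_sd=sds)


def _two_state_scheme(name: str, means, k12: float, k21: float,
                      sd: float = 0.05) -> KineticScheme:
    # controls are clean two-state systems: no molecule-to-molecule
    # level offsets (those were measured on the mobile constructs)
    q = np.array([[-k12, k12], [k21, -k21]], dtype=float)
    return KineticScheme(name=name, rate_matrix=q,
                         emission_mean=np.asarray(means, float),
                         emission_sd=np.full(2, sd),
                         level_offset_sd=0.0)


def build_preset(name: str) -> KineticScheme:
    """Return the KineticScheme for one of the study's constructs."""
    if name == "cag10":
        return _mobile_scheme("cag10")
    if name == "ctg30":
        return _mobile_scheme("ctg30")
    if name == "cag40":
        # identical topology; every off-diagonal rate of cag10 divided by 2
        return _mobile_scheme("cag40", rate_scale=0.5)
    if name == "hairpin2":
        return _two_state_scheme("hairpin2", (0.25, 0.75), k12=2.0, k21=2.0)
    if name == "static3wj":
        # branchpoint conformers only, no migration
        return _two_state_scheme("static3wj", (0.43, 0.62), k12=2.0, k21=2.0)
    if name == "fullcomp3wj":
        return _two_state_scheme("fullcomp3wj", (0.30, 0.50), k12=2.0, k21=2.0)
    raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Hidden-state truth for a simulated TraceSet, for validation only.

    ``segments[i]`` lists ``(t_start, t_end, state)`` continuous-time
    occupancy intervals of trace i; ``frame_states[i]`` gives the
    dominant (largest-occupancy) hidden state per frame.
    """

    scheme: KineticScheme
    segments: list[list[tuple[float, float, int]]]
    frame_states: list[np.ndarray]

    def complete_dwells(self, state: int | None = None) -> np.ndarray:
        """Durations of dwells that begin and end inside the observation.

        The first and last segment of every trace are censored.  With
        ``state`` given, restrict to that hidden state; otherwise pool.
        """
        out = []
        for segs in self.segments:
            for (t0, t1, s) in segs[1:-1]:
                if state is None or s == state:
                    out.append(t1 - t0)
        return np.asarray(out)

    def frame_occupancy(self) -> np.ndarray:
        """Fraction of frames spent in each hidden state (dominant-state count)."""
        counts = np.zeros(self.scheme.n_states)
        for fs in self.frame_states:
            counts += np.bincount(fs, minlength=self.scheme.n_states)
        return counts / counts.sum()


def _gillespie_path(rng, q, pi, duration):
    """Exact CTMC sample path on [0, duration] → list of (t0, t1, state)."""
    n = q.shape[0]
    state = int(rng.choice(n, p=pi))
    t = 0.0
    segs = []
    while t < duration:
        exit_rate = -q[state, state]
        if exit_rate <= 0:
            segs.append((t, duration, state))
            break
        dwell = rng.exponential(1.0 / exit_rate)
        t1 = min(t + dwell, duration)
        segs.append((t, t1, state))
        if t1 >= duration:
            break
        rates = q[state].copy()
        rates[state] = 0.0
        state = int(rng.choice(n, p=rates / rates.sum()))
        t = t1
    return segs


def _frame_averages(segs, n_frames, dt, means, sds):
    """Per-frame occupancy-weighted emission mean/sd and dominant state."""
    occ = np.zeros((n_frames, len(means)))
    for (t0, t1, s) in segs:
        i0 = int(t0 / dt)
        i1 = min(int(np.ceil(t1 / dt)), n_frames)
        for i in range(i0, i1):
            lo = max(t0, i * dt)
            hi = min(t1, (i + 1) * dt)
            if hi > lo:
                occ[i, s] += hi - lo
    occ /= dt
    ideal = occ @ means
    sd = occ @ sds
    dominant = occ.argmax(axis=1)
    return ideal, sd, dominant


def simulate_traces(scheme: KineticScheme, n_traces: int = DEFAULT_N_TRACES,
                    seed: int = 0, min_frames: int = DEFAULT_MIN_FRAMES,
                    max_duration: float = DEFAULT_MAX_DURATION_S,
                    ) -> tuple[TraceSet, GroundTruth]:
    """Simulate a TraceSet plus its hidden ground truth.

    Each trace: initial state from the stationary distribution, exact
    Gillespie jumps, duration = min(exponential bleach time, max
    duration) rounded down to whole frames (redrawn if shorter than
    ``min_frames``).  Frame FRET is the time-weighted average of state
    means over the frame (camera integration) plus Gaussian noise with
    the occupancy-weighted sd, clipped to ``FRET_CLIP``.  Donor and
    acceptor counts are back-computed from a total intensity of
    ``TOTAL_INTENSITY``; frames whose noisy FRET falls outside [0, 1]
    get intensities from the clamped ratio.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    n = scheme.n_states
    if n > 1 and np.all(scheme.rate_matrix[~np.eye(n, dtype=bool)] == 0):
        raise ValueError("all transition rates are zero: no dynamics to simulate")
    if min_frames * scheme.dt > max_duration:
        raise ValueError("min_frames longer than max_duration: traces can never qualify")
    rng = np.random.default_rng(seed)
    pi = scheme.stationary_distribution()
    dt = scheme.dt
    traces: list[Trace] = []
    all_segs: list[list[tuple[float, float, int]]] = []
    all_frames: list[np.ndarray] = []
    means, sds = scheme.emission_mean, scheme.emission_sd
    for i in range(n_traces):
        for _attempt in range(1000):
            if scheme.bleach_rate > 0:
                duration = min(rng.exponential(1.0 / scheme.bleach_rate), max_duration)
            else:
                duration = max_duration
            n_frames = int(duration / dt)
            if n_frames >= min_frames:
                break
        else:  # pragma: no cover - astronomically unlikely under valid params
            raise RuntimeError("could not draw a trace longer than min_frames")
        segs = _gillespie_path(rng, scheme.rate_matrix, pi, n_frames * dt)
        offset = rng.normal(0.0, scheme.level_offset_sd) \
            if scheme.level_offset_sd > 0 else 0.0
        trace_means = np.clip(means + offset, 0.0, 1.0)
        ideal, frame_sd, dominant = _frame_averages(segs, n_frames, dt,
                                                    trace_means, sds)
        observed = ideal + rng.standard_normal(n_frames) * frame_sd
        observed = np.clip(observed, *FRET_CLIP)
        acc = np.clip(observed, 0.0, 1.0) * TOTAL_INTENSITY
        don = TOTAL_INTENSITY - acc
        traces.append(Trace(
            trace_id=f"{scheme.name}_{i:04d}",
            time=np.arange(n_frames) * dt,
            donor=don, acceptor=acc, fret=observed))
        all_segs.append(segs)
        all_frames.append(dominant)
    ts = TraceSet(sample_name=scheme.name, traces=traces, dt=dt)
    return ts, GroundTruth(scheme=scheme, segments=all_segs, frame_states=all_frames)


def stitch(traceset: TraceSet, trace_id: str | None = None) -> Trace:
    """Concatenate all traces of a sample into one long trace.

    Frames keep their order; time is re-indexed contiguously at dt.  The
    frame-to-frame joins introduce the artefactual transitions that make
    stitched-trace model selection prone to overfitting.
    """
    if len(traceset) == 0:
        raise ValueError("cannot stitch an empty TraceSet")
    donor = np.concatenate([t.donor for t in traceset])
    acceptor = np.concatenate([t.acceptor for t in traceset])
    fret = np.concatenate([t.fret for t in traceset])
    n = len(fret)
    return Trace(
        trace_id=trace_id or f"{traceset.sample_name}_stitched",
        time=np.arange(n) * traceset.dt,
        donor=donor, acceptor=acceptor, fret=fret)
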