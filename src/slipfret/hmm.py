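"""Gaussian-emission HMM idealization of FRET trajectories.

Maximum-likelihood fitting by Baum–Welch EM (scaled forward–backward)
at a user-chosen state count K, followed by Viterbi decoding into a
discrete state path with idealized FRET values.  This is the stage that
turns noisy per-frame FRET efficiencies into the transition events the
TDP/BIC model selection consumes.

Conventions: states are sorted by ascending emission mean (canonical
label order); state indices in a :class:`DiscretizedTrace` are 1-based;
per-frame transition probabilities live in a row-stochastic K×K matrix.
Out-of-range FRET values (< 0 or > 1) are legitimate inputs — the
Gaussian emission model absorbs them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["HmmModel", "DiscretizedTrace", "fit_hmm", "viterbi_path"]

VAR_FLOOR = 1e-4      # emission-variance floor; prevents collapse onto points
DEFAULT_TOL = 1e-6    # relative log-likelihood convergence tolerance
DEFAULT_MAX_ITER = 500
DEFAULT_RESTARTS = 10
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class HmmModel:
    """Fitted Gaussian-emission HMM in canonical (mean-sorted) order."""

    K: int
    means: np.ndarray
    variances: np.ndarray
    transition_probs: np.ndarray
    initial_probs: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    degenerate: bool = False
    #: log-likelihood at the start of each EM iteration (monotone)
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        # canonicalize: permute states into ascending-mean order
        order = np.argsort(self.means, kind="stable")
        self.means = self.means[order]
        self.variances = self.variances[order]
        self.transition_probs = self.transition_probs[np.ix_(order, order)]
        self.initial_probs = self.initial_probs[order]
        if np.any(self.variances < VAR_FLOOR * (1 - 1e-12)):
            raise ValueError("variances below floor")
        if np.any(np.abs(self.transition_probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if abs(self.initial_probs.sum() - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")


@dataclass
class DiscretizedTrace:
    """Viterbi state path of one trace with idealized FRET values.

    ``state_path`` holds 1-based state indices; ``transitions`` lists
    ``(frame, state_before, state_after, fret_before, fret_after)`` at
    every frame where the path changes state.
    """

    trace_id: str
    state_path: np.ndarray
    ideal_fret: np.ndarray
    fret: np.ndarray

    def __post_init__(self):
        self.state_path = np.asarray(self.state_path, dtype=int)
        self.ideal_fret = np.asarray(self.ideal_fret, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        if not (len(self.state_path) == len(self.ideal_fret) == len(self.fret)):
            raise ValueError("state_path, ideal_fret and fret must share length")
        if len(self.state_path) == 0:
            raise ValueError("empty discretized trace")
        if self.state_path.min() < 1:
            raise ValueError("state indices are 1-based")

    @property
    def transitions(self) -> list[tuple[int, int, int, float, float]]:
        out = []
        sp, fi = self.state_path, self.ideal_fret
        for i in range(1, len(sp)):
            if sp[i] != sp[i - 1]:
                out.append((i, int(sp[i - 1]), int(sp[i]),
                            float(fi[i - 1]), float(fi[i])))
        return out

    @property
    def n_transitions(self) -> int:
        return int(np.count_nonzero(np.diff(self.state_path)))


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_ll(x, starts, ends, means, variances, log_a, log_pi):
    """Total log-likelihood over all sequences at fixed parameters."""
    k = means.shape[0]
    ll = 0.0
    for s in range(starts.shape[0]):
        t0, t1 = starts[s], ends[s]
        alpha = np.empty(k)
        for t in range(t0, t1):
            lb = np.empty(k)
            for j in range(k):
                d = x[t] - means[j]
                lb[j] = -0.5 * (_LOG2PI + np.log(variances[j]) + d * d / variances[j])
            m = lb[0]
            for j in range(1, k):
                if lb[j] > m:
                    m = lb[j]
            if t == t0:
                for j in range(k):
                    alpha[j] = np.exp(log_pi[j] + lb[j] - m)
            else:
                new = np.zeros(k)
                for i in range(k):
                    ai = alpha[i]
                    if ai > 0.0:
                        for j in range(k):
                            new[j] += ai * np.exp(log_a[i, j])
                for j in range(k):
                    new[j] *= np.exp(lb[j] - m)
                alpha = new
            c = 0.0
            for j in range(k):
                c += alpha[j]
            ll += np.log(c) + m
            for j in range(k):
                alpha[j] /= c
    return ll


@njit(cache=True)
def _baum_welch(x, starts, ends, means0, vars0, a0, pi0, tol, max_iter,
                var_floor):
    """Baum–Welch EM over one or more sequences (scaled, numerically shifted).

    Returns (means, variances, A, pi, ll_history, n_iter, converged);
    ll_history[i] is the log-likelihood under the parameters entering
    iteration i, hence non-decreasing.
    """
    k = means0.shape[0]
    n_seq = starts.shape[0]
    means = means0.copy()
    variances = vars0.copy()
    a = a0.copy()
    pi = pi0.copy()
    ll_history = np.empty(max_iter)
    ll_prev = -np.inf
    n_iter = 0
    converged = False
    t_max = 0
    for s in range(n_seq):
        if ends[s] - starts[s] > t_max:
            t_max = ends[s] - starts[s]
    alpha = np.empty((t_max, k))
    beta = np.empty((t_max, k))
    b = np.empty((t_max, k))
    shift = np.empty(t_max)
    cscale = np.empty(t_max)
    for it in range(max_iter):
        # accumulators
        ll = 0.0
        pi_acc = np.zeros(k)
        xi_acc = np.zeros((k, k))
        g_sum = np.zeros(k)        # total responsibility per state
        g_x = np.zeros(k)          # responsibility-weighted sum of x
        g_xx = np.zeros(k)         # responsibility-weighted sum of x^2
        g_trans = np.zeros(k)      # responsibility excluding last frame
        for s in range(n_seq):
            t0, t1 = starts[s], ends[s]
            n = t1 - t0
            # emissions, max-shifted per frame
            for t in range(n):
                mx = -1e308
                for j in range(k):
                    d = x[t0 + t] - means[j]
                    v = -0.5 * (_LOG2PI + np.log(variances[j]) + d * d / variances[j])
                    b[t, j] = v
                    if v > mx:
                        mx = v
                shift[t] = mx
                for j in range(k):
                    b[t, j] = np.exp(b[t, j] - mx)
            # forward
            for t in range(n):
                if t == 0:
                    for j in range(k):
                        alpha[0, j] = pi[j] * b[0, j]
                else:
                    for j in range(k):
                        acc = 0.0
                        for i in range(k):
                            acc += alpha[t - 1, i] * a[i, j]
                        alpha[t, j] = acc * b[t, j]
                c = 0.0
                for j in range(k):
                    c += alpha[t, j]
                if c <= 0.0:
                    c = 1e-300
                cscale[t] = c
                for j in range(k):
                    alpha[t, j] /= c
                ll += np.log(c) + shift[t]
            # backward
            for j in range(k):
                beta[n - 1, j] = 1.0
            for t in range(n - 2, -1, -1):
                for i in range(k):
                    acc = 0.0
                    for j in range(k):
                        acc += a[i, j] * b[t + 1, j] * beta[t + 1, j]
                    beta[t, i] = acc / cscale[t + 1]
            # accumulate gamma / xi
            for t in range(n):
                xt = x[t0 + t]
                gsum_t = 0.0
                for j in range(k):
                    g = alpha[t, j] * beta[t, j]
                    gsum_t += g
                for j in range(k):
                    g = alpha[t, j] * beta[t, j] / gsum_t
                    g_sum[j] += g
                    g_x[j] += g * xt
                    g_xx[j] += g * xt * xt
                    if t == 0:
                        pi_acc[j] += g
                    if t < n - 1:
                        g_trans[j] += g
            for t in range(n - 1):
                denom = cscale[t + 1]
                for i in range(k):
                    ai = alpha[t, i]
                    if ai > 0.0:
                        for j in range(k):
                            xi_acc[i, j] += ai * a[i, j] * b[t + 1, j] * \
                                beta[t + 1, j] / denom
        ll_history[it] = ll
        n_iter = it + 1
        if it > 0 and ll - ll_prev < tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M-step
        for j in range(k):
            if g_sum[j] > 0.0:
                means[j] = g_x[j] / g_sum[j]
                v = g_xx[j] / g_sum[j] - means[j] * means[j]
                variances[j] = v if v > var_floor else var_floor
        for j in range(k):
            pi[j] = pi_acc[j] / n_seq
        for i in range(k):
            row = 0.0
            for j in range(k):
                row += xi_acc[i, j]
            if row > 0.0:
                for j in range(k):
                    a[i, j] = xi_acc[i, j] / row
    return means, variances, a, pi, ll_history[:n_iter], n_iter, converged


@njit(cache=True)
def _viterbi(x, means, variances, log_a, log_pi):
    """Most probable state path; ties resolved toward the lowest index."""
    n = x.shape[0]
    k = means.shape[0]
    delta = np.empty(k)
    psi = np.empty((n, k), dtype=np.int64)
    for j in range(k):
        d = x[0] - means[j]
        delta[j] = log_pi[j] - 0.5 * (_LOG2PI + np.log(variances[j])
                                      + d * d / variances[j])
    for t in range(1, n):
        new = np.empty(k)
        for j in range(k):
            best = -np.inf
            arg = 0
            for i in range(k):
                v = delta[i] + log_a[i, j]
                if v > best:   # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            d = x[t] - means[j]
            new[j] = best - 0.5 * (_LOG2PI + np.log(variances[j])
                                   + d * d / variances[j])
            psi[t, j] = arg
        delta = new
    best = -np.inf
    arg = 0
    for j in range(k):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path = np.empty(n, dtype=np.int64)
    path[n - 1] = arg
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _as_sequences(traces) -> list[np.ndarray]:
    if isinstance(traces, np.ndarray) and traces.ndim == 1:
        return [np.asarray(traces, dtype=float)]
    if hasattr(traces, "fret_series"):
        return [np.asarray(f, dtype=float) for f in traces.fret_series()]
    if hasattr(traces, "fret"):
        return [np.asarray(traces.fret, dtype=float)]
    return [np.asarray(t, dtype=float) for t in traces]


def _init_params(rng, x_all, K):
    """Quantile-spaced means with Gaussian jitter; sticky uniform transitions."""
    q = (np.arange(K) + 0.5) / K
    means = np.quantile(x_all, q) + rng.normal(0.0, 0.02, size=K)
    variances = np.full(K, 0.05 ** 2)
    a = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(a, 0.9 if K > 1 else 1.0)
    pi = np.full(K, 1.0 / K)
    return np.sort(means), variances, a, pi


def fit_hmm(traces, K: int, n_restarts: int = DEFAULT_RESTARTS,
            tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
            seed: int = 0) -> HmmModel:
    """Fit a K-state Gaussian HMM by Baum–Welch from several restarts.

    ``traces`` may be a single FRET array, a list of arrays, a Trace or
    a TraceSet; multiple sequences share one model (statistics pooled
    across them).  The restart with the highest final log-likelihood is
    returned, states sorted by ascending mean.
    """
    seqs = _as_sequences(traces)
    x = np.concatenate(seqs)
    total = len(x)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > total:
        raise ValueError(f"K={K} exceeds number of frames ({total})")
    if total <= 10 * K:
        raise ValueError(f"need more than {10 * K} frames to fit K={K} "
                         f"states, got {total}")
    starts = np.cumsum([0] + [len(s) for s in seqs[:-1]]).astype(np.int64)
    ends = (starts + np.array([len(s) for s in seqs])).astype(np.int64)

    if np.ptp(x) == 0 and K > 1:
        warnings.warn("all input values identical; returning degenerate model")
        a = np.eye(K)
        return HmmModel(K=K, means=np.full(K, x[0]), variances=np.full(K, VAR_FLOOR),
                        transition_probs=a, initial_probs=np.full(K, 1.0 / K),
                        log_likelihood=float(_forward_ll(
                            x, starts, ends, np.full(K, x[0]), np.full(K, VAR_FLOOR),
                            np.log(a + 1e-300), np.log(np.full(K, 1.0 / K)))),
                        n_iterations=0, converged=True, degenerate=True)

    rng = np.random.default_rng(seed)
    best = None
    for _r in range(max(1, n_restarts)):
        m0, v0, a0, pi0 = _init_params(rng, x, K)
        m, v, a, pi, hist, n_iter, conv = _baum_welch(
            x, starts, ends, m0, v0, a0, pi0, tol, max_iter, VAR_FLOOR)
        ll = float(_forward_ll(x, starts, ends, m, v,
                               np.log(a + 1e-300), np.log(pi + 1e-300)))
        if best is None or ll > best.log_likelihood:
            best = HmmModel(K=K, means=m, variances=v, transition_probs=a,
                            initial_probs=pi, log_likelihood=ll,
                            n_iterations=n_iter, converged=bool(conv),
                            ll_history=hist)
        if K == 1:
            break  # closed form; restarts all identical
    return best


def viterbi_path(model: HmmModel, trace, trace_id: str | None = None
                 ) -> DiscretizedTrace:
    """Decode the single most probable state path under *model*.

    ``trace`` may be a FRET array or a Trace.  Idealized FRET per frame
    is the decoded state's model mean; equal-probability ties go to the
    lower state index.
    """
    if hasattr(trace, "fret"):
        x = np.asarray(trace.fret, dtype=float)
        tid = trace_id or trace.trace_id
    else:
        x = np.asarray(trace, dtype=float)
        tid = trace_id or "trace"
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("trace must be a non-empty 1-D FRET series")
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transition_probs)
        log_pi = np.log(model.initial_probs)
    path0, _ = _viterbi(x, model.means, model.variances, log_a, log_pi)
    return DiscretizedTrace(
        trace_id=tid,
        state_path=path0 + 1,
        ideal_fret=model.means[path0],
        fret=x,
    )
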