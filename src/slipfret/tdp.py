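"""Transition density plots and BIC selection of the FRET state count.

A transition density plot (TDP) bins every idealized transition at its
(FRET before, FRET after) coordinates on a 100×100 grid over [0,1]² and
smooths it with an isotropic Gaussian (variance 0.0005 in FRET² units).
A K-state interpretation of the TDP is a mixture of K×(K−1) isotropic
2D Gaussians whose centers are *tied* to K shared state means: cluster
(i, j) sits at (μᵢ, μⱼ) for every ordered pair i ≠ j.  The mixture is
fitted by EM on the binned, smoothed density (bin centers weighted by
counts), the best of several random initializations is kept, and the
state count K_opt is the K minimizing

    BIC = −2·lnL + p·ln(n_transitions),   p = K + [K(K−1) − 1] + K(K−1)

(state means + free cluster weights + per-cluster sigmas).  Selecting
K_opt per HMM state count and taking the mode across HMM K values gives
the consensus state count: the pooling over individual molecules is
what makes this selection resistant to overfitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter

__all__ = [
    "TransitionDensity", "TdpMixtureFit", "KoptResult",
    "build_tdp", "fit_tdp_mixture", "select_k_opt", "consensus_k",
]

DEFAULT_BINS = 100
DEFAULT_SIGMA2 = 0.0005   # smoothing variance, FRET^2 units
DEFAULT_N_INIT = 10
DEFAULT_K_RANGE = range(1, 11)
SIGMA_FLOOR = 1e-3        # per-cluster sd floor, FRET units
_EM_TOL = 1e-6
_EM_MAX_ITER = 300
_EM_INIT_ITERS = 40   # short-run budget per initialization; best is refined
_WEIGHT_CUT = 1e-6    # drop bins below this fraction of the peak weight


@dataclass
class TransitionDensity:
    """Binned, smoothed (FRET_before, FRET_after) transition density.

    Rows index FRET_before, columns FRET_after.  The grid total equals
    ``n_transitions`` (mass lost to smoothing at the edges is
    renormalized back in).
    """

    grid: np.ndarray
    n_transitions: int
    smoothing_sigma2: float = DEFAULT_SIGMA2
    source: str = "unstitched"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("TDP grid must be square")
        if np.any(self.grid < 0):
            raise ValueError("TDP grid must be non-negative")

    @property
    def bins(self) -> int:
        return self.grid.shape[0]

    @property
    def axis(self) -> np.ndarray:
        """Bin centers, evenly spaced on [0, 1]."""
        return (np.arange(self.bins) + 0.5) / self.bins


@dataclass
class TdpMixtureFit:
    """K×(K−1)-cluster tied-mean isotropic Gaussian mixture fit of a TDP."""

    K: int
    state_means: np.ndarray
    cluster_weights: np.ndarray
    cluster_sigma: np.ndarray
    cluster_pairs: list[tuple[int, int]]
    log_likelihood: float
    n_params: int
    BIC: float
    n_init: int
    seed: int
    converged: bool = True
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def state_uncertainties(self) -> np.ndarray:
        """Per-state error: average sigma of the clusters touching the state."""
        out = np.zeros(self.K)
        for k in range(self.K):
            sig = [self.cluster_sigma[c] for c, (i, j) in enumerate(self.cluster_pairs)
                   if i == k or j == k]
            out[k] = float(np.mean(sig)) if sig else 0.0
        return out


@dataclass
class KoptResult:
    """BIC table over K with its argmin, optionally per HMM state count."""

    per_K_BIC: dict[int, float]
    K_opt: int
    best_fit: TdpMixtureFit | None = None
    fits: dict[int, TdpMixtureFit] | None = None
    per_hmm_K: dict[int, int] | None = None
    consensus: int | None = None

    @property
    def state_means_at_Kopt(self) -> np.ndarray:
        if self.best_fit is None:
            return np.empty(0)
        return self.best_fit.state_means


# ---------------------------------------------------------------------------
# TDP construction
# ---------------------------------------------------------------------------

#: dwells shorter than this many frames are treated as camera-blur
#: artifacts of a single transition and collapsed before counting
DEFAULT_MIN_DWELL_FRAMES = 2
#: FRET jumps smaller than this are the "low-amplitude artefactual
#: jumps" that populate the TDP diagonal region and are not counted
DEFAULT_MIN_AMPLITUDE = 0.1


def iter_transitions(discretized,
                     min_dwell_frames: int = DEFAULT_MIN_DWELL_FRAMES,
                     min_amplitude: float = DEFAULT_MIN_AMPLITUDE) -> np.ndarray:
    """(n, 2) array of (fret_before, fret_after) over counted transitions.

    A dwell shorter than ``min_dwell_frames`` is indistinguishable from
    the partially integrated frame a single transition produces, so it
    is removed and its neighbors joined; a resulting jump below
    ``min_amplitude`` (idealized units) is discarded as an artifact of
    near-duplicate HMM states.  Pass ``min_dwell_frames=1,
    min_amplitude=0.0`` for the raw, unfiltered transition list.
    """
    pairs = []
    for d in discretized:
        sp = d.state_path
        f = d.ideal_fret
        change = np.nonzero(np.diff(sp))[0]
        starts = np.r_[0, change + 1]
        ends = np.r_[change + 1, len(sp)]
        kept = [(int(sp[s]), float(f[s])) for s, e in zip(starts, ends)
                if e - s >= min_dwell_frames]
        for (s1, f1), (s2, f2) in zip(kept[:-1], kept[1:]):
            if s1 != s2 and abs(f2 - f1) >= min_amplitude:
                pairs.append((f1, f2))
    return np.asarray(pairs, dtype=float).reshape(-1, 2)


def build_tdp(discretized, bins: int = DEFAULT_BINS,
              sigma2: float = DEFAULT_SIGMA2,
              source: str = "unstitched",
              min_dwell_frames: int = DEFAULT_MIN_DWELL_FRAMES,
              min_amplitude: float = DEFAULT_MIN_AMPLITUDE) -> TransitionDensity:
    """Bin all counted idealized transitions into a smoothed TDP.

    Each transition adds one count at its (before, after) bin, values
    clamped to [0, 1]; the histogram is convolved with an isotropic
    Gaussian of variance ``sigma2`` and renormalized so the grid total
    stays equal to the transition count.  See :func:`iter_transitions`
    for the artifact filters.
    """
    pairs = iter_transitions(discretized, min_dwell_frames, min_amplitude)
    n = len(pairs)
    if n == 0:
        warnings.warn("no transitions: returning an all-zero TDP")
        return TransitionDensity(np.zeros((bins, bins)), 0, sigma2, source)
    idx = np.clip((np.clip(pairs, 0.0, 1.0) * bins).astype(int), 0, bins - 1)
    grid = np.zeros((bins, bins))
    np.add.at(grid, (idx[:, 0], idx[:, 1]), 1.0)
    if sigma2 > 0:
        grid = gaussian_filter(grid, sigma=np.sqrt(sigma2) * bins,
                               mode="constant")
        grid *= n / grid.sum()
    return TransitionDensity(grid, n, sigma2, source)


# ---------------------------------------------------------------------------
# tied-mean mixture EM (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mixture_em(xy, w, before_idx, after_idx, mu0, sig2_0, pi0,
                tol, max_iter, sig2_floor):
    """EM for the tied-center isotropic 2D mixture on weighted points.

    Returns (mu, sig2, pi, ll_history, n_iter, converged).  The M-step
    is coordinate-wise (weights, then tied means at fixed sigmas, then
    sigmas at the new means), so the log-likelihood is non-decreasing.
    """
    n = w.shape[0]
    c = pi0.shape[0]
    k = mu0.shape[0]
    mu = mu0.copy()
    sig2 = sig2_0.copy()
    pi = pi0.copy()
    ll_history = np.empty(max_iter)
    ll_prev = -np.inf
    n_iter = 0
    converged = False
    logp = np.empty(c)
    ex = np.empty(c)
    log_coef = np.empty(c)
    inv2s = np.empty(c)
    for it in range(max_iter):
        for cc in range(c):
            log_coef[cc] = np.log(max(pi[cc], 1e-300)) \
                - np.log(2.0 * np.pi * sig2[cc])
            inv2s[cc] = 1.0 / (2.0 * sig2[cc])
        r_acc = np.zeros(c)
        sx = np.zeros(c)
        sy = np.zeros(c)
        sxx = np.zeros(c)   # responsibility-weighted sum of x^2+y^2
        ll = 0.0
        for i in range(n):
            x = xy[i, 0]
            y = xy[i, 1]
            mx = -1e308
            for cc in range(c):
                dx = x - mu[before_idx[cc]]
                dy = y - mu[after_idx[cc]]
                lp = log_coef[cc] - (dx * dx + dy * dy) * inv2s[cc]
                logp[cc] = lp
                if lp > mx:
                    mx = lp
            den = 0.0
            for cc in range(c):
                e = np.exp(logp[cc] - mx)
                ex[cc] = e
                den += e
            ll += w[i] * (mx + np.log(den))
            scale = w[i] / den
            for cc in range(c):
                r = scale * ex[cc]
                r_acc[cc] += r
                sx[cc] += r * x
                sy[cc] += r * y
                sxx[cc] += r * (x * x + y * y)
        ll_history[it] = ll
        n_iter = it + 1
        if it > 0 and ll - ll_prev < tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M-step 1: weights
        tot = 0.0
        for cc in range(c):
            tot += r_acc[cc]
        for cc in range(c):
            pi[cc] = r_acc[cc] / tot
        # M-step 2: tied means, precision-weighted over every cluster
        # in which the state appears as before- or after-coordinate
        num = np.zeros(k)
        den_k = np.zeros(k)
        for cc in range(c):
            inv = 1.0 / sig2[cc]
            kb = before_idx[cc]
            ka = after_idx[cc]
            num[kb] += sx[cc] * inv
            den_k[kb] += r_acc[cc] * inv
            num[ka] += sy[cc] * inv
            den_k[ka] += r_acc[cc] * inv
        for kk in range(k):
            if den_k[kk] > 0.0:
                mu[kk] = num[kk] / den_k[kk]
        # M-step 3: per-cluster isotropic variances at the new means
        for cc in range(c):
            if r_acc[cc] > 1e-300:
                cx = mu[before_idx[cc]]
                cy = mu[after_idx[cc]]
                e2 = sxx[cc] - 2.0 * (cx * sx[cc] + cy * sy[cc]) \
                    + r_acc[cc] * (cx * cx + cy * cy)
                v = e2 / (2.0 * r_acc[cc])
                sig2[cc] = v if v > sig2_floor else sig2_floor
    return mu, sig2, pi, ll_history[:n_iter], n_iter, converged


def _marginal_peaks(tdp: TransitionDensity, K: int) -> np.ndarray:
    """Top-K local maxima of the row+column marginal density (FRET units)."""
    marg = tdp.grid.sum(axis=0) + tdp.grid.sum(axis=1)
    axis = tdp.axis
    peaks = [i for i in range(len(marg))
             if marg[i] > 0
             and (i == 0 or marg[i] >= marg[i - 1])
             and (i == len(marg) - 1 or marg[i] > marg[i + 1])]
    peaks.sort(key=lambda i: -marg[i])
    chosen: list[int] = []
    for i in peaks:
        if all(abs(i - j) > 2 for j in chosen):
            chosen.append(i)
        if len(chosen) == K:
            break
    vals = [axis[i] for i in chosen]
    # pad with mass quantiles if the marginal has fewer than K peaks
    if len(vals) < K:
        cum = np.cumsum(marg)
        if cum[-1] > 0:
            cum = cum / cum[-1]
            need = K - len(vals)
            qs = (np.arange(need) + 0.5) / need
            vals.extend(np.interp(qs, cum, axis))
        else:
            vals.extend(np.linspace(0.1, 0.9, K - len(vals)))
    return np.sort(np.asarray(vals[:K]))


def _n_params(K: int) -> int:
    c = K * (K - 1)
    return K + max(c - 1, 0) + c


def fit_tdp_mixture(tdp: TransitionDensity, K: int,
                    n_init: int = DEFAULT_N_INIT, seed: int = 0,
                    max_iter: int = _EM_MAX_ITER, tol: float = _EM_TOL
                    ) -> TdpMixtureFit:
    """Fit the K-state tied-mean mixture to a TDP, best of ``n_init`` EM runs.

    K = 1 has zero clusters: its log-likelihood is 0 for an empty
    transition set and −∞ (BIC = +∞) when transitions exist, so a
    one-state model can never win on dynamic data.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n_trans = tdp.n_transitions
    if K == 1:
        ll = 0.0 if n_trans == 0 else -np.inf
        bic = -2.0 * ll if n_trans == 0 else np.inf
        mean = 0.5
        if n_trans > 0 or tdp.grid.sum() > 0:
            marg = tdp.grid.sum(axis=0) + tdp.grid.sum(axis=1)
            if marg.sum() > 0:
                mean = float(np.average(tdp.axis, weights=marg))
        return TdpMixtureFit(K=1, state_means=np.array([mean]),
                             cluster_weights=np.empty(0),
                             cluster_sigma=np.empty(0), cluster_pairs=[],
                             log_likelihood=ll, n_params=_n_params(1),
                             BIC=bic, n_init=n_init, seed=seed)
    if n_trans == 0:
        raise ValueError(f"cannot fit K={K} states to a TDP with no transitions")

    w_full = tdp.grid.ravel()
    keep = w_full > w_full.max() * _WEIGHT_CUT
    w = np.ascontiguousarray(w_full[keep])
    axis = tdp.axis
    xs, ys = np.meshgrid(axis, axis, indexing="ij")
    xy = np.ascontiguousarray(
        np.column_stack([xs.ravel()[keep], ys.ravel()[keep]]))

    pairs = [(i, j) for i in range(K) for j in range(K) if i != j]
    before_idx = np.array([p[0] for p in pairs], dtype=np.int64)
    after_idx = np.array([p[1] for p in pairs], dtype=np.int64)
    c = len(pairs)
    rng = np.random.default_rng(seed)
    base_means = _marginal_peaks(tdp, K)

    # short EM runs from every initialization, then refine the best one
    best = None
    for r in range(max(1, n_init)):
        jitter = 0.0 if r == 0 else rng.normal(0.0, 0.02, size=K)
        mu0 = np.sort(np.clip(base_means + jitter, 0.0, 1.0))
        sig2_0 = np.full(c, 0.05 ** 2)
        pi0 = np.full(c, 1.0 / c)
        mu, sig2, pi, hist, n_iter, conv = _mixture_em(
            xy, w, before_idx, after_idx, mu0, sig2_0, pi0,
            tol, min(_EM_INIT_ITERS, max_iter), SIGMA_FLOOR ** 2)
        ll = float(hist[-1])
        if best is None or ll > best[0]:
            best = (ll, mu, sig2, pi, hist, conv)
    ll, mu, sig2, pi, hist, conv = best
    if not conv:
        mu, sig2, pi, hist2, n_iter, conv = _mixture_em(
            xy, w, before_idx, after_idx, mu, sig2, pi,
            tol, max_iter, SIGMA_FLOOR ** 2)
        ll = float(hist2[-1])
        hist = np.concatenate([hist, hist2])
    if not conv:
        warnings.warn(f"TDP mixture EM (K={K}) not converged after {max_iter} "
                      "iterations; returning best-so-far")
    order = np.argsort(mu, kind="stable")
    rank = np.empty(K, dtype=int)
    rank[order] = np.arange(K)
    sorted_pairs = [(int(rank[i]), int(rank[j])) for (i, j) in pairs]
    perm = sorted(range(c), key=lambda cc: sorted_pairs[cc])
    p = _n_params(K)
    return TdpMixtureFit(
        K=K, state_means=mu[order],
        cluster_weights=pi[perm],
        cluster_sigma=np.sqrt(sig2[perm]),
        cluster_pairs=[sorted_pairs[cc] for cc in perm],
        log_likelihood=ll, n_params=p,
        BIC=float(-2.0 * ll + p * np.log(n_trans)),
        n_init=n_init, seed=seed, converged=bool(conv), ll_history=hist)


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------

def select_k_opt(tdp: TransitionDensity, k_range=DEFAULT_K_RANGE,
                 n_init: int = DEFAULT_N_INIT, seed: int = 0) -> KoptResult:
    """Fit every K in ``k_range`` and return the BIC-minimizing model.

    Ties break toward the smaller K.
    """
    if tdp.n_transitions == 0:
        raise ValueError("cannot select a state count on a TDP with no transitions")
    per_k: dict[int, float] = {}
    fits: dict[int, TdpMixtureFit] = {}
    for K in k_range:
        fit = fit_tdp_mixture(tdp, K, n_init=n_init, seed=seed + K)
        per_k[K] = fit.BIC
        fits[K] = fit
    k_opt = min(per_k, key=lambda K: (per_k[K], K))
    return KoptResult(per_K_BIC=per_k, K_opt=k_opt, best_fit=fits[k_opt],
                      fits=fits)


def consensus_k(results: dict[int, KoptResult]) -> tuple[int, dict]:
    """Modal K_opt across HMM state counts; ties break toward smaller K.

    Returns (consensus, report); the report flags HMM K values whose
    K_opt deviates from the consensus.
    """
    if not results:
        raise ValueError("no KoptResults to form a consensus over")
    if len(results) < 2:
        raise ValueError("consensus needs at least 2 HMM state counts")
    kopts = {hk: r.K_opt for hk, r in sorted(results.items())}
    values = list(kopts.values())
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best_count = max(counts.values())
    consensus = min(v for v, c in counts.items() if c == best_count)
    report = {
        "per_hmm_K": kopts,
        "consensus": consensus,
        "deviating": {hk: v for hk, v in kopts.items() if v != consensus},
    }
    return consensus, report
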