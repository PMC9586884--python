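# Methods

This note documents the models, conventions and numerical choices
behind `slipfret`, and what the synthetic benchmarks do and do not
establish about real data.

## Synthetic trajectory generator

**Hidden kinetics.** A sample preset is a continuous-time Markov chain
(CTMC) over hidden states with a rate matrix Q (off-diagonal rates in
s⁻¹, rows summing to zero). The mobile 3WJ presets (`cag10`, `ctg30`,
`cag40`) place 8 states on a 4-positional-isomer × 2-conformation
grid: branchpoint conformational flips exchange the conformation
within an isomer, branch migration moves the branchpoint to a
neighboring isomer. Base rates are 2.0 s⁻¹ (flip) and 0.5 s⁻¹
(migration) — order 1 s⁻¹, consistent with the Kramers estimate for
barrier-limited migration. Every edge carries equal rates in both
directions, which makes the stationary distribution exactly uniform
over the 8 hidden states, so each FRET level is comparably sampled.

**Degeneracy.** Two of the four isomers share the two middle FRET
levels, so 8 hidden states produce only 6 distinct levels (the middle
two doubly degenerate). The two degenerate isomers are kinetically
distinct: all edges touching the slow one are scaled by 1/4 and the
fast partner's flip rate is raised so their total exit rates differ by
exactly a factor of 4. Dwells pooled over a degenerate level are
therefore genuinely biexponential — the feature the dwell-time model
comparison must detect. Emission means and per-state noise sd come
from the measured six-state tables of each construct (e.g. for the
(CAG)₁₀-like preset: 0.08, 0.26, 0.43, 0.62, 0.79, 0.93 with sd
0.05–0.06). The `cag40` preset divides every rate of `cag10` by 2
(larger slip-outs migrate more slowly), so the true per-state dwell
factor is exactly 2. Two-state control presets (`hairpin2`,
`static3wj`, `fullcomp3wj`) use a single symmetric exchange at 2 s⁻¹.

**Emission model.** Trajectories are sampled by exact Gillespie
simulation. Each 50 ms camera frame reports the time-weighted average
of the occupied states' emission means (camera integration — frames
that straddle a jump show intermediate values), plus i.i.d. Gaussian
noise with the occupancy-weighted sd, clipped to [−0.2, 1.2] so the
HMM sees realistic out-of-range excursions. Donor/acceptor counts are
back-computed from a total intensity of 1000; frames whose noisy FRET
lies outside [0, 1] get intensities from the clamped ratio, so a
round-trip through intensity files clamps those frames.

**Molecule-to-molecule heterogeneity.** Each mobile-3WJ trace draws a
single Gaussian FRET offset (sd 0.03) applied to all its levels,
emulating dye-environment variability. This value makes the TDP
cluster widths (offset ⊕ smoothing kernel ⊕ estimation scatter) come
out near the measured 0.05–0.06 state uncertainties, and it is what
drives the stitched-trace overfitting: a single model over all
molecules resolves the per-molecule sub-populations as extra states,
while per-molecule models absorb them. The two-state controls are
generated without offsets — they are clean-dynamics references.

**Trace lengths.** Pre-bleach trace length is exponential with mean
30 s, capped at 60 s and redrawn below 100 frames (5 s). Defaults: 300
traces per sample ("several hundred"); the tests and the acceptance
script use 100 (and 50 for the stitched analysis) to keep runtimes in
minutes — large enough that cluster statistics, not single molecules,
dominate the selection.

**Not modeled:** photophysics (blinking, crosstalk), shot noise,
gamma/quantum-yield corrections, ionic-condition dependence of rates.
Passing the benchmarks therefore shows the *analysis machinery* is
correct and calibrated for Markovian dynamics with Gaussian noise and
static per-molecule offsets; it does not certify robustness to
photophysical artifacts.

## HMM idealization

Gaussian-emission HMM fitted by Baum–Welch EM (scaled
forward–backward, per-frame max-shift of log emissions for numerical
robustness), best of 10 restarts. Initialization per restart: means at
evenly spaced data quantiles jittered by N(0, 0.02²), variances
(0.05)², sticky uniform transitions (0.9 self). Convergence at
relative log-likelihood change < 1e-6 or 500 iterations; variance
floor 1e-4 prevents collapse. States are canonically ordered by
ascending mean. Decoding is hard Viterbi (the TDP consumes discrete
transitions); ties go to the lower state index. In unstitched mode one
model is fitted per molecule (traces shorter than 10·K frames are
skipped for that K); in stitched mode one model is fitted to the
concatenated trace. The final reported log-likelihood is evaluated at
the final parameters with a forward pass.

## TDP construction and transition counting

Transitions are taken from idealized paths at state changes only.
Two artifact filters are applied before counting (both configurable):

* **minimum dwell 2 frames** — a one-frame visit is indistinguishable
  from the partially integrated frame a single transition produces;
  collapsing it turns "A → blur → B" into the single jump "A → B";
* **minimum amplitude 0.1 FRET** — jumps smaller than twice the
  emission noise sd are the low-amplitude artifactual transitions
  between near-duplicate HMM states that would otherwise populate the
  near-diagonal region (the true level spacing is ≥ 0.14).

Without these filters, camera-blur states and duplicate-state flicker
supply enough well-localized density that BIC prefers 7–9 states on
six-level data. Counts are binned on a 100×100 grid over [0, 1]²
(coordinates clamped), smoothed with an isotropic Gaussian of variance
0.0005 FRET², and renormalized so the grid total equals the transition
count (smoothing mass lost at the grid edges is folded back in).

## Tied-mean mixture and BIC

The K-state mixture ties all K(K−1) cluster centers to K shared state
means — cluster (i, j) sits at (μᵢ, μⱼ) — with free weights and
per-cluster isotropic sd (floor 1e-3). EM runs on the smoothed density
treated as weighted data at bin centers (bins below 1e-6 of the peak
weight are dropped). The M-step is coordinate-wise (weights; tied
means, precision-weighted over every cluster a state touches; then
sigmas), so the log-likelihood is non-decreasing. Initialization takes
the top-K local maxima of the marginal density, jittered per
initialization; 10 initializations run a 40-iteration budget and the
best is refined to convergence (tol 1e-6, max 300 iterations).

The parameter count is p = K + (K(K−1) − 1) + K(K−1) (means, free
weights, sigmas) and BIC = −2 ln L + p ln(n_transitions). K = 1 has no
clusters: log-likelihood 0 on an empty transition set, −∞ (BIC = +∞)
otherwise. K_opt is the BIC argmin over K = 1..10 (ties toward smaller
K); the consensus over HMM K = 6..10 is their mode (ties toward
smaller). Reported state uncertainties are the average sigma of the
clusters touching each state.

## Dwell-time kinetics

Maximal constant runs of the idealized path are dwells; the first and
last run of each trace are censored (their durations are truncated by
the observation window) and excluded. For pooling across molecules,
per-trace states are first relabeled to the nearest consensus state
mean (degenerate per-trace states merge, as they should). The minimum
dwell is 1 frame and no missed-event correction is applied — a known
bias at high rates.

The empirical survival S(t) = P(T > t) is evaluated at t = 0 and the
observed durations and fitted by Levenberg–Marquardt least squares
with amplitudes constrained to sum to 1 and zero offset
(grid-seeded starts; a bounded trust-region fallback if every
unconstrained start leaves the simplex; canonical order τ₁ ≤ τ₂).
τ_av = A₁τ₁ + A₂τ₂ equals the area under the fitted survival curve.
Model comparison uses a corrected Akaike score computed from the
exponential-mixture likelihood of the dwell sample itself (survival
points are strongly correlated, so residual-based scores over-reward
the extra component); the biexponential must win by more than 2 AICc
units, otherwise the monoexponential is kept.

**Known bias in the repeat-length factor.** The cag40/cag10 ratio of
τ_av is 2 by construction, but the *measured* mean factor is ≈ 1.7–1.8:
dwells comparable to the trace length are disproportionately the
(excluded) first/last dwell, which suppresses both the amplitude and
the tau of the slow component more strongly in the slower sample, and
Viterbi missed events inflate the faster sample. This is a property of
the estimator under a finite observation window, not of the
implementation; it is reported as measured.

## Landscape module

`kramers_rate(ΔG‡, k0)` evaluates k = k₀·exp(−ΔG‡/k_BT) with ΔG‡ in
k_BT (default k₀ = 10⁶ s⁻¹, the scale typical of DNA hairpin
dynamics). The order of magnitude is the nearest decade exponent, with
the log₁₀ position rounded to one decimal before integer rounding
(half-to-even), so a mid-decade rate such as 0.3 s⁻¹ counts as order
10⁰. `barrier_height` finds the watershed saddle between two basins by
sublevel-set flooding (binary search over levels with connected-
component labeling; 4-connectivity in 2D) and subtracts the deeper
basin minimum; it accepts a `FesGrid` with basin coordinates or an
explicit 1D level list with basin indices.

The toy well-tempered metadynamics engine runs overdamped Langevin
dynamics (Euler–Maruyama, k_BT = 1, diffusion constant 1, step 1e-3)
on an analytic 1D/2D potential tabulated on a grid (512 bins in 1D;
gradients by finite differences; linear/bilinear force interpolation),
with reflecting walls at the grid edges. Every 500 steps a Gaussian
hill (nominal height 0.5 k_BT, width 0.1) is deposited, scaled by
exp(−V_bias/(γ−1)k_BT) with bias factor γ = 8 (γ = ∞ gives untempered
metadynamics). The free-energy estimate is −γ/(γ−1)·V_bias,
min-shifted; convergence is declared when the mean height of the last
10% of hills falls below 20% of the nominal height. The engine
validates the reconstruction principle on analytic potentials
(harmonic well within 1 k_BT; 5 k_BT double-well barrier within 15%);
it makes no claim about molecular systems.

## Reproducibility

A pipeline run is driven by one YAML-serializable config. The master
seed is split into fixed per-stage offsets (simulate +0, HMM +10⁶,
TDP +2·10⁶, dwell +3·10⁶); per-trace HMM seeds derive deterministically
from the stage seed, trace index and K. Identical configs produce
bit-identical reports apart from wall-clock fields; floats in reports
are serialized at 9 significant digits.

## Limitations

* No photophysics or intensity-level noise model; FRET-level Gaussian
  noise only.
* Dwell-time estimates carry discretization (50 ms frames),
  missed-event and observation-window censoring biases; no
  censored-data likelihood is used.
* The TDP artifact filters (min dwell 2 frames, min amplitude 0.1) are
  appropriate for level spacings well above the noise sd; closely
  spaced states would require retuning.
* The metadynamics engine is a validation tool for the reconstruction
  and barrier→rate logic, not a molecular simulator.
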