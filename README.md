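# slipfret

Kinetic analysis of single-molecule FRET trajectories from DNA
three-way junctions (3WJs) whose triplet-repeat hairpin "slip-out"
undergoes branch migration — with a synthetic-trajectory generator so
that every stage of the analysis can be validated against known ground
truth.

## Who this is for

Single-molecule biophysicists analyzing camera-based smFRET time
traces of multi-state systems, and anyone who wants a tested,
scriptable re-implementation of the HMM → transition-density-plot →
BIC workflow for counting FRET states, plus the downstream dwell-time
kinetics.

## The problem and the method

A mobile 3WJ with a (CAG)n slip-out interconverts between four
positional isomers, each with two branchpoint conformations — eight
hidden states. Several of these states share a FRET efficiency, so
only six distinct FRET levels are observable. Deciding how many states
a noisy trajectory supports is the central model-selection problem.

The workflow, per sample:

1. **Idealization.** Each molecule's FRET trajectory
   `E(t) = I_A/(I_D + I_A)` is fitted with a Gaussian-emission hidden
   Markov model by Baum–Welch EM at a chosen state count *K* (best of
   10 restarts), then decoded with the Viterbi algorithm into a
   discrete state path.
2. **Transition density plot (TDP).** Every idealized transition
   contributes a point at (FRET before, FRET after); points are binned
   on a 100×100 grid over [0,1]² and smoothed with an isotropic
   Gaussian (σ² = 0.0005).
3. **State counting by BIC.** A *K*-state interpretation of the TDP is
   a mixture of K×(K−1) isotropic 2D Gaussians with centers tied to K
   shared state means, fitted by EM (10 initializations). The optimal
   count K_opt minimizes BIC = −2 ln L + p ln n over K = 1..10, and the
   consensus of K_opt across HMM fits at K = 6..10 is the answer.
   Fitting each molecule separately (unstitched) makes this selection
   resistant to overfitting; concatenating all molecules into one
   stitched trace makes K_opt track the HMM's K instead.
4. **Dwell-time kinetics.** Per-state dwell times (first/last dwell of
   each trace censored) are summarized as survival curves and fitted
   with mono- and biexponential decays,
   `S(t) = A₁e^(−t/τ₁) + A₂e^(−t/τ₂)`, A₁+A₂ = 1. The
   amplitude-weighted average dwell time is τ_av = A₁τ₁ + A₂τ₂.
   Comparing τ_av per state between repeat lengths quantifies how much
   larger slip-outs slow the dynamics.
5. **Landscape arithmetic.** Kramers' diffusive barrier-crossing rate
   k = k₀·exp(−ΔG‡/k_BT) connects a free-energy barrier between
   positional isomers to the observed rates; a toy well-tempered
   metadynamics engine (overdamped Langevin on analytic 1D/2D
   potentials, bias factor γ) validates the free-energy reconstruction
   machinery behind such barrier estimates.

The synthetic generator simulates the hidden kinetics as a
continuous-time Markov chain (exact Gillespie sampling), integrates
the emission over each 50 ms camera frame, adds Gaussian noise and
per-molecule FRET offsets, and truncates traces at an exponential
photobleaching time — so the full analysis can be checked against the
generator's ground truth.

## Worked example

```python
import numpy as np
from slipfret import PipelineConfig, run_pipeline, compare_runs

r10 = run_pipeline(PipelineConfig(preset="cag10", n_traces=100, seed=11,
                                  hmm_k=[6, 7, 8, 9, 10]))
print(r10.per_hmm_k_opt)
print(r10.consensus_k, np.round(np.sort(r10.state_means), 3))

r40 = run_pipeline(PipelineConfig(preset="cag40", n_traces=100, seed=11,
                                  hmm_k=[6, 7, 8, 9, 10]))
fs = compare_runs(r10, r40)
print(np.round(fs.per_state_factor, 2), round(fs.mean_factor, 2),
      round(fs.sem_factor, 2))
```

prints

```
{6: 6, 7: 6, 8: 6, 9: 6, 10: 6}
6 [0.085 0.252 0.431 0.615 0.784 0.923]
[1.56 1.58 1.59 1.68 1.91 2.17] 1.75 0.1
```

The `cag10` preset hides **eight** kinetic states behind six FRET
levels; the TDP–BIC consensus correctly reports **six** resolvable
states at every HMM K, with state means within 0.01 of the generator's
levels (0.08, 0.26, 0.43, 0.62, 0.79, 0.93). The `cag40` preset halves
every rate, and the per-state ratio of amplitude-weighted dwell times
comes out near the construction value of 2 (slightly below it, because
the finite observation window censors the longest dwells of the slower
sample — see `docs/methods.md`).

The same stages are available as a CLI:

```bash
slipfret simulate --preset cag10 --n-traces 100 --seed 11 --out run/
slipfret idealize --traces run/traces --k 6 --seed 11 --out run/ideal.tsv
slipfret tdp --idealized run/ideal.tsv --out-json run/kopt.json
slipfret pipeline --config run.yaml
slipfret landscape --potential doublewell --steps 600000 --out-json fes.json
```

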