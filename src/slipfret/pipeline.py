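"""End-to-end orchestration: simulate → idealize → TDP/K_opt → dwell fits.

One :class:`PipelineConfig` (YAML-serializable) drives a fully
reproducible run: the master seed is split into fixed per-stage seeds,
every stochastic stage derives its randomness from its stage seed, and
two runs with the same config produce identical reports up to the
wall-clock fields.

Stages
------
1. traces      — simulate a preset (or read a trace directory);
2. idealize    — per-trace Gaussian HMMs at each requested K and
                 Viterbi decoding (stitched mode: one model for the
                 concatenated trace);
3. tdp         — transition density plot per HMM K, BIC scan over the
                 TDP K range, consensus K_opt across HMM K values;
4. dwell       — per-trace paths relabeled onto the consensus state
                 means, censored dwell extraction, mono/biexponential
                 survival fits per state.

Two runs on different samples are compared with
:func:`compare_runs`, which forms the per-state τ_av ratio from the
biexponential fits (the repeat-length analysis).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dwell as dwell_mod
from . import tdp as tdp_mod
from .hmm import fit_hmm, viterbi_path
from .synthetic import (DEFAULT_MAX_DURATION_S, DEFAULT_MIN_FRAMES,
                        DEFAULT_N_TRACES, build_preset, simulate_traces,
                        stitch)
from .trace_io import (TraceSet, read_traces, write_idealized, write_matrix,
                       write_report, write_traces)

logger = logging.getLogger("slipfret")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "compare_runs"]

# fixed per-stage seed offsets, so partial reruns reproduce
STAGE_SEED_OFFSETS = {"simulate": 0, "hmm": 1_000_000, "tdp": 2_000_000,
                      "dwell": 3_000_000}


@dataclass
class PipelineConfig:
    """Everything a reproducible pipeline run needs."""

    preset: str | None = None
    input_path: str | None = None
    sample_name: str | None = None
    n_traces: int = DEFAULT_N_TRACES
    seed: int = 0
    stitched: bool = False
    hmm_k: list[int] = field(default_factory=lambda: [6, 7, 8, 9, 10])
    tdp_k_min: int = 1
    tdp_k_max: int = 10
    n_init: int = 10
    n_restarts: int = 10
    bins: int = 100
    sigma2: float = 0.0005
    min_dwell_frames: int = 2
    min_amplitude: float = 0.1
    min_frames: int = DEFAULT_MIN_FRAMES
    max_duration: float = DEFAULT_MAX_DURATION_S
    outdir: str | None = None

    def __post_init__(self):
        if not self.preset and not self.input_path:
            raise ValueError("config needs a preset or an input_path")
        if self.seed < 0 or self.seed > 2**30:
            raise ValueError("seed must be in [0, 2^30]")
        self.hmm_k = [int(k) for k in self.hmm_k]

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_SEED_OFFSETS[stage]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    sample_name: str
    config: PipelineConfig
    per_hmm_k_opt: dict[int, int]
    per_hmm_bic: dict[int, dict[int, float]]
    consensus_k: int
    consensus_report: dict
    state_means: np.ndarray
    state_uncertainties: np.ndarray
    dwell_counts: dict[int, int]
    dwell_fits: dict[int, dict]          # state -> {mono, bi, chosen}
    kopt_results: dict = field(default_factory=dict, repr=False)
    dwell_table: object = None
    timings: dict[str, float] = field(default_factory=dict)
    version: str = "1"

    def to_dict(self, include_timings: bool = True) -> dict:
        def _r(x):
            return float(f"{float(x):.9g}")
        out = {
            "schema_version": self.version,
            "sample_name": self.sample_name,
            "config": asdict(self.config),
            "per_hmm_k_opt": {int(k): int(v)
                              for k, v in self.per_hmm_k_opt.items()},
            "per_hmm_bic": {int(k): {int(kk): _r(vv) if np.isfinite(vv)
                                     else None for kk, vv in v.items()}
                            for k, v in self.per_hmm_bic.items()},
            "consensus_k": int(self.consensus_k),
            "deviating_hmm_k": {int(k): int(v) for k, v in
                                self.consensus_report["deviating"].items()},
            "state_means": [_r(m) for m in self.state_means],
            "state_uncertainties": [_r(u) for u in self.state_uncertainties],
            "dwell_counts": {int(k): int(v)
                             for k, v in self.dwell_counts.items()},
            "dwell_fits": {
                int(s): {name: None if f is None else {
                    "n_components": f.n_components,
                    "A1": _r(f.A1), "tau1": _r(f.tau1),
                    "A2": _r(f.A2),
                    "tau2": _r(f.tau2) if f.n_components == 2 else 0.0,
                    "tau_av": _r(f.tau_av), "rss": _r(f.rss),
                    "aicc": _r(f.aicc), "chosen": bool(f.chosen),
                } for name, f in fits.items()}
                for s, fits in self.dwell_fits.items()},
        }
        if include_timings:
            out["timings_s"] = {k: round(v, 3) for k, v in self.timings.items()}
        return out


def _idealize_set(traceset: TraceSet, K: int, n_restarts: int, seed: int):
    """Per-trace HMM + Viterbi; traces too short for K are skipped."""
    out = []
    for i, tr in enumerate(traceset):
        if len(tr) <= 10 * K:
            logger.warning("trace %s too short for K=%d; skipped",
                           tr.trace_id, K)
            continue
        model = fit_hmm(tr.fret, K=K, n_restarts=n_restarts,
                        seed=seed + 97 * K + i)
        out.append(viterbi_path(model, tr))
    if not out:
        raise RuntimeError(f"no trace long enough to fit K={K}")
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages of the analysis for one sample."""
    timings: dict[str, float] = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    # ---- stage 1: traces -------------------------------------------------
    t0 = time.perf_counter()
    ground_truth = None
    if config.preset:
        scheme = build_preset(config.preset)
        traceset, ground_truth = simulate_traces(
            scheme, n_traces=config.n_traces,
            seed=config.stage_seed("simulate"),
            min_frames=config.min_frames, max_duration=config.max_duration)
        logger.info("simulated %d traces (%d frames) for preset %s",
                    len(traceset), traceset.n_frames, config.preset)
    else:
        traceset = read_traces(config.input_path,
                               sample_name=config.sample_name)
        logger.info("read %d traces from %s", len(traceset), config.input_path)
    sample = config.sample_name or traceset.sample_name
    if outdir:
        write_traces(outdir / "traces", traceset)
        if ground_truth is not None:
            with open(outdir / "ground_truth.tsv", "w") as fh:
                fh.write("trace_id\tframe\thidden_state\n")
                for tr, fs in zip(traceset, ground_truth.frame_states):
                    for j, s in enumerate(fs):
                        fh.write(f"{tr.trace_id}\t{j}\t{int(s) + 1}\n")
    timings["traces"] = time.perf_counter() - t0

    # ---- stage 2: idealization ------------------------------------------
    t0 = time.perf_counter()
    hmm_seed = config.stage_seed("hmm")
    discretized: dict[int, list] = {}
    if config.stitched:
        long_trace = stitch(traceset)
        for K in config.hmm_k:
            model = fit_hmm(long_trace.fret, K=K,
                            n_restarts=config.n_restarts,
                            seed=hmm_seed + 97 * K)
            discretized[K] = [viterbi_path(model, long_trace)]
    else:
        for K in config.hmm_k:
            discretized[K] = _idealize_set(traceset, K, config.n_restarts,
                                           hmm_seed)
    if outdir:
        for K, disc in discretized.items():
            write_idealized(outdir / f"idealized_K{K}.tsv", disc)
    timings["idealize"] = time.perf_counter() - t0

    # ---- stage 3: TDP and K_opt ------------------------------------------
    t0 = time.perf_counter()
    source = "stitched" if config.stitched else "unstitched"
    tdp_seed = config.stage_seed("tdp")
    kopt_results: dict[int, tdp_mod.KoptResult] = {}
    for K in config.hmm_k:
        density = tdp_mod.build_tdp(
            discretized[K], bins=config.bins, sigma2=config.sigma2,
            source=source, min_dwell_frames=config.min_dwell_frames,
            min_amplitude=config.min_amplitude)
        kopt_results[K] = tdp_mod.select_k_opt(
            density, k_range=range(config.tdp_k_min, config.tdp_k_max + 1),
            n_init=config.n_init, seed=tdp_seed + 1009 * K)
        if outdir:
            write_matrix(outdir / f"tdp_K{K}.csv", density.grid, density.axis)
    if len(kopt_results) >= 2:
        consensus, consensus_report = tdp_mod.consensus_k(kopt_results)
    else:
        only = next(iter(kopt_results.values()))
        consensus = only.K_opt
        consensus_report = {"per_hmm_K": {k: r.K_opt
                                          for k, r in kopt_results.items()},
                            "consensus": consensus, "deviating": {}}
    # state means: fit at K = consensus from the reference HMM run
    ref_k = consensus if consensus in kopt_results else config.hmm_k[0]
    ref_fit = kopt_results[ref_k].fits.get(consensus)
    if ref_fit is None:   # consensus outside the scanned TDP range
        ref_fit = kopt_results[ref_k].best_fit
    state_means = ref_fit.state_means
    state_unc = ref_fit.state_uncertainties()
    timings["tdp"] = time.perf_counter() - t0
    if outdir:
        write_report(outdir / "kopt.json", {
            "per_hmm_K": consensus_report["per_hmm_K"],
            "consensus": consensus,
            "state_means": state_means,
            "state_uncertainties": state_unc,
        })

    # ---- stage 4: dwell kinetics -----------------------------------------
    t0 = time.perf_counter()
    relabeled = [dwell_mod.map_to_global_states(d, state_means)
                 for d in discretized[ref_k]]
    table = dwell_mod.extract_dwells(relabeled, dt=traceset.dt,
                                     K=len(state_means))
    dwell_fits: dict[int, dict] = {}
    for s in range(1, len(state_means) + 1):
        durations = table.durations(s)
        entry: dict[str, object] = {"mono": None, "bi": None, "chosen": None}
        if len(durations) >= dwell_mod.MIN_DWELLS_MONO:
            entry["mono"] = dwell_mod.fit_cpd(durations, 1, state=s)
        if len(durations) >= dwell_mod.MIN_DWELLS_BI:
            entry["bi"] = dwell_mod.fit_cpd(durations, 2, state=s)
        if entry["mono"] is not None and entry["bi"] is not None:
            entry["chosen"] = dwell_mod.choose_model(entry["mono"], entry["bi"])
        elif entry["mono"] is not None:
            entry["chosen"] = entry["mono"]
        else:
            warnings.warn(f"state {s}: too few dwells "
                          f"({len(durations)}) for a survival fit")
        dwell_fits[s] = entry
    timings["dwell"] = time.perf_counter() - t0

    report = RunReport(
        sample_name=sample, config=config,
        per_hmm_k_opt={k: r.K_opt for k, r in kopt_results.items()},
        per_hmm_bic={k: r.per_K_BIC for k, r in kopt_results.items()},
        consensus_k=consensus, consensus_report=consensus_report,
        state_means=state_means, state_uncertainties=state_unc,
        dwell_counts=table.counts(), dwell_fits=dwell_fits,
        kopt_results=kopt_results, dwell_table=table, timings=timings)
    if outdir:
        write_report(outdir / "report.json", report.to_dict())
        with open(outdir / "dwell.json", "w") as fh:
            import json
            json.dump(report.to_dict()["dwell_fits"], fh, indent=2)
    return report


def compare_runs(report_a: RunReport, report_b: RunReport,
                 use: str = "bi") -> dwell_mod.FactorSummary:
    """Per-state τ_av ratio (B over A) between two pipeline runs.

    States are aligned by ascending FRET rank; by default the
    biexponential fits are compared (as in the repeat-length analysis);
    ``use='chosen'`` compares the AICc-selected models instead.
    """
    if report_a.consensus_k != report_b.consensus_k:
        raise ValueError(
            f"state-count mismatch: {report_a.consensus_k} vs "
            f"{report_b.consensus_k}")
    fits_a, fits_b = [], []
    for s in range(1, report_a.consensus_k + 1):
        fa = report_a.dwell_fits[s][use] or report_a.dwell_fits[s]["chosen"]
        fb = report_b.dwell_fits[s][use] or report_b.dwell_fits[s]["chosen"]
        if fa is None or fb is None:
            raise ValueError(f"state {s}: missing dwell fit in one sample")
        fits_a.append(fa)
        fits_b.append(fb)
    return dwell_mod.compare_samples(fits_a, fits_b)
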