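"""Reproducible experiment running: configuration, presets, ablations, fixtures.

:class:`ExperimentConfig` carries every network, neuron and plasticity
parameter (the defaults are the standard 400 + 80 neuron model), the run
schedule and the variant flags (uniform "no topology" profile,
log-normal per-neuron target rates, scale-up, per-mechanism ablations).
Configs round-trip through YAML; trials are seeded independently from
the experiment seed via ``SeedSequence`` spawning.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plasticity as pl
from .dynamics import (
    Network,
    NeuronParams,
    SimulationResult,
    SnapshotSeries,
    STPConfig,
)
from .topology import (
    ConnectionProfile,
    UniformProfile,
    WiringSpec,
    place_neurons,
    wire_static_populations,
)

__all__ = [
    "ExperimentConfig",
    "TrialResult",
    "build_network",
    "run_experiment",
    "ABLATION_PRESETS",
    "run_ablation",
    "generate_fixtures",
    "calibrate_growth_rate",
]


@dataclass
class ExperimentConfig:
    """Complete description of one experiment (network + schedule + variants)."""

    # network
    n_exc: int = 400
    n_inh: int = 80
    sheet_width_um: float = 1000.0
    sheet_height_um: float = 1000.0
    profile_half_width_um: float = 200.0
    profile_interpretation: str = "sigma"  # "sigma" | "hwhm"
    topology: str = "gaussian"  # "gaussian" | "uniform" (no-topology variant)
    wiring: WiringSpec = field(default_factory=WiringSpec)
    # neuron / synapse dynamics
    neuron: NeuronParams = field(default_factory=NeuronParams)
    stp: STPConfig = field(default_factory=STPConfig)
    # plasticity
    stdp: pl.STDPConfig = field(default_factory=pl.STDPConfig)
    sn: pl.SNConfig = field(default_factory=pl.SNConfig)
    ip: pl.IPConfig = field(default_factory=pl.IPConfig)
    structural: pl.StructuralConfig = field(default_factory=pl.StructuralConfig)
    #: draw per-neuron IP target rates from a log-normal distribution
    #: (mean / sd in Hz) instead of the single shared target
    lognormal_targets: bool = False
    lognormal_mean_hz: float = 3.0
    lognormal_sd_hz: float = 1.0
    # schedule
    duration_s: float = 500.0
    trials: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.duration_s < 0 or self.trials < 1:
            raise ValueError("invalid schedule")
        if self.topology not in ("gaussian", "uniform"):
            raise ValueError("topology must be 'gaussian' or 'uniform'")
        # delays must sit on the step grid
        for t in self.wiring.delays_ms:
            self.wiring.delay_steps(t, self.neuron.dt)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (
            ("wiring", WiringSpec), ("neuron", NeuronParams), ("stp", STPConfig),
            ("stdp", pl.STDPConfig), ("sn", pl.SNConfig), ("ip", pl.IPConfig),
            ("structural", pl.StructuralConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path_or_text) -> "ExperimentConfig":
        text = str(path_or_text)
        if "\n" not in text:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        return cls.from_dict(yaml.safe_load(text))


def build_network(config: ExperimentConfig, seed=None) -> Network:
    """Construct the (unrun) network a config describes; seeded wiring."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    layout = place_neurons(
        config.n_exc, config.n_inh, config.sheet_width_um, config.sheet_height_um,
        seed=rng,
    )
    if config.topology == "uniform":
        profile = UniformProfile()
    else:
        profile = ConnectionProfile(
            config.profile_half_width_um, config.profile_interpretation
        )
    static = wire_static_populations(layout, profile, config.wiring, seed=rng)
    target_rates = None
    if config.lognormal_targets:
        mean, sd = config.lognormal_mean_hz, config.lognormal_sd_hz
        var_ln = np.log(1.0 + (sd / mean) ** 2)
        mu_ln = np.log(mean) - var_ln / 2.0
        target_rates = rng.lognormal(mu_ln, np.sqrt(var_ln),
                                     size=config.n_exc + config.n_inh)
    return Network(
        layout, static, profile=profile, neuron=config.neuron, stp=config.stp,
        stdp=config.stdp, sn=config.sn, ip=config.ip, structural=config.structural,
        target_rates_hz=target_rates,
    )


@dataclass
class TrialResult:
    """One trial's raw outputs plus its summary statistics."""

    trial: int
    seed: int
    result: SimulationResult
    summary: dict
    paths: dict = field(default_factory=dict)


def summarize_trial(result: SimulationResult, stable_window_s: float = 50.0) -> dict:
    """Figure-level scalars for one trial (final-window averages)."""
    log = result.per_second
    tail = log[log["t_s"] > result.duration_s - stable_window_s]
    cf = float(tail["connection_fraction"].mean())
    bi = float(tail["bidirectional_fraction"].mean())
    factor = float((tail["bidirectional_fraction"] / tail["connection_fraction"] ** 2).mean())
    return {
        "connection_fraction": cf,
        "bidirectional_fraction": bi,
        "bidirectional_factor": factor,
        "mean_rate_exc_hz": float(tail["mean_rate_exc_hz"].mean()),
        "mean_v_t_exc_mv": float(tail["mean_v_t_exc_mv"].mean()),
        "n_pruned_total": int(len(result.lifetime_log)),
    }


def _write_trial(result: SimulationResult, config, outdir: Path, trial: int) -> dict:
    tdir = outdir / f"trial_{trial:02d}"
    tdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spikes": tdir / "spikes.csv",
        "snapshots": tdir / "snapshots.csv",
        "lifetimes": tdir / "lifetimes.csv",
        "per_second": tdir / "per_second.csv",
    }
    result.spikes.to_csv(paths["spikes"])
    result.snapshots.to_dataframe().to_csv(paths["snapshots"], index=False)
    result.lifetimes_dataframe().to_csv(paths["lifetimes"], index=False)
    result.per_second.to_csv(paths["per_second"], index=False)
    return {k: str(v) for k, v in paths.items()}


def run_experiment(
    config: ExperimentConfig,
    output_dir=None,
    stable_window_s: float = 50.0,
    progress: bool = False,
) -> tuple[list[TrialResult], dict]:
    """Run the configured trials; returns per-trial results and a summary.

    The cross-trial summary gives mean and standard deviation of each
    per-trial scalar.  With ``output_dir`` set, raw outputs (spikes,
    snapshots, lifetime log, per-second scalars) are written as CSV per
    trial, plus the config and summary.
    """
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(config.seed).spawn(config.trials)]
    trials = []
    outdir = Path(output_dir) if output_dir is not None else None
    for k, s in enumerate(seeds):
        net = build_network(config, seed=s)
        res = net.run(config.duration_s, seed=s + 1, progress=progress)
        summary = summarize_trial(res, stable_window_s)
        paths = _write_trial(res, config, outdir, k) if outdir else {}
        trials.append(TrialResult(k, s, res, summary, paths))
    keys = trials[0].summary.keys()
    summary = {
        k: {
            "mean": float(np.mean([t.summary[k] for t in trials])),
            "sd": float(np.std([t.summary[k] for t in trials], ddof=1))
            if len(trials) > 1 else 0.0,
        }
        for k in keys
    }
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return trials, summary


# ----------------------------------------------------------------------
# ablations
# ----------------------------------------------------------------------

ABLATION_PRESETS = (
    "no-growth", "no-pruning", "no-topology", "no-STP", "no-STDP", "no-SN", "no-IP",
)


def _apply_preset(config: ExperimentConfig, preset: str) -> ExperimentConfig:
    c = ExperimentConfig.from_dict(config.to_dict())
    if preset == "no-growth":
        c.structural.growth_enabled = False
    elif preset == "no-pruning":
        c.structural.pruning_enabled = False
    elif preset == "no-topology":
        c.topology = "uniform"
    elif preset == "no-STP":
        c.stp.enabled = False
    elif preset == "no-STDP":
        c.stdp.enabled = False
    elif preset == "no-SN":
        c.sn.enabled = False
        # without normalization the incoming sum no longer bounds single
        # weights; the synaptic maximum (= the would-be normalization
        # target) becomes the binding ceiling
        c.stdp.w_max = (c.structural.target_fraction * c.sn.ee_mean_strength
                        * c.n_exc)
    elif preset == "no-IP":
        c.ip.enabled = False
    else:
        raise ValueError(f"unknown ablation preset {preset!r}")
    return c


def run_ablation(
    preset: str,
    duration_s: float = 60.0,
    seed: int = 0,
    base_config: ExperimentConfig | None = None,
) -> dict:
    """Short run with one mechanism disabled plus its qualitative check.

    The report contains the raw quantities and, where the expected
    outcome is desk-checkable, a boolean verdict:

    * no-growth: the E->E graph never forms (zero edges);
    * no-STDP: depression is the only route below the pruning
      threshold, so nothing is ever pruned and the graph grows without
      bound;
    * no-pruning: the connection fraction rises monotonically past the
      target instead of stabilizing;
    * no-SN: surviving weights pile up in a strongly unimodal
      distribution (mass concentrates at a single log-weight mode);
    * no-STP: loss of fast depression produces runaway ("epileptic")
      firing far above the IP target rate.
    """
    base = base_config or ExperimentConfig()
    config = _apply_preset(base, preset)
    config.duration_s = duration_s
    config.trials = 1
    config.seed = seed
    net = build_network(config, seed=seed)
    res = net.run(duration_s, seed=seed + 1)
    log = res.per_second
    cf = log["connection_fraction"].to_numpy()
    report = {
        "preset": preset,
        "duration_s": duration_s,
        "final_edges": int(net.adj.sum()),
        "final_connection_fraction": float(cf[-1]) if len(cf) else 0.0,
        "n_pruned_total": int(len(res.lifetime_log)),
        "mean_rate_exc_hz": float(log["mean_rate_exc_hz"].mean()) if len(log) else 0.0,
    }
    if preset == "no-growth":
        report["check"] = report["final_edges"] == 0
    elif preset == "no-STDP":
        report["check"] = report["n_pruned_total"] == 0
    elif preset == "no-pruning":
        target = config.structural.target_fraction
        report["check"] = bool(np.all(np.diff(cf) >= 0) and cf[-1] > target)
    elif preset == "no-SN":
        w = net.W[net.adj]
        w = w[w > 0]
        hist, edges = np.histogram(np.log10(w), bins=20)
        report["peak_bin_mass"] = float(hist.max() / hist.sum())
        report["check"] = report["peak_bin_mass"] > 0.5
    elif preset == "no-STP":
        target = config.ip.target_rate_hz
        report["check"] = report["mean_rate_exc_hz"] > 3.0 * target
    else:
        report["check"] = None  # qualitative only (motif/structure level)
    report["result"] = res
    return report


# ----------------------------------------------------------------------
# growth-rate calibration (scale-up / variant support)
# ----------------------------------------------------------------------

def calibrate_growth_rate(
    config: ExperimentConfig,
    target_cf: float = 0.1,
    probe_duration_s: float = 150.0,
    max_iter: int = 4,
    tolerance: float = 0.02,
) -> float:
    """Proportionally re-tune the growth mean until the probe-run CF matches.

    Variants that change the network size keep their stable-phase
    connection fraction at the target by scaling the growth rate; this
    runs short probe simulations and rescales the mean (sd kept equal to
    the mean) by target/measured each iteration.
    """
    c = ExperimentConfig.from_dict(config.to_dict())
    rate = c.structural.growth_mean
    for it in range(max_iter):
        c.structural.growth_mean = rate
        c.structural.growth_sd = rate
        net = build_network(c, seed=c.seed + it)
        res = net.run(probe_duration_s, seed=c.seed + 100 + it)
        tail = res.per_second[res.per_second["t_s"] > probe_duration_s - 30]
        measured = float(tail["connection_fraction"].mean())
        if abs(measured - target_cf) <= tolerance * target_cf or measured == 0:
            break
        rate *= target_cf / measured
    return rate


# ----------------------------------------------------------------------
# deterministic test fixtures
# ----------------------------------------------------------------------

def generate_fixtures(kind: str, seed: int = 0):
    """Small deterministic test inputs (networks, trains, samples, series)."""
    rng = np.random.default_rng(seed)
    if kind == "tiny-network":
        config = ExperimentConfig(n_exc=6, n_inh=2, sheet_width_um=200.0,
                                  sheet_height_um=200.0, duration_s=1.0, trials=1,
                                  seed=seed)
        config.structural.growth_mean = 3.0
        config.structural.growth_sd = 1.0
        return build_network(config, seed=seed)
    if kind == "spike-trains":
        duration_ms = 50_000.0
        rate_hz = 3.0
        n = rng.poisson(rate_hz * duration_ms / 1000.0)
        poisson = np.sort(rng.uniform(0, duration_ms, size=n))
        periodic = np.arange(0.0, duration_ms, 1000.0 / rate_hz)
        return {"poisson_ms": poisson, "periodic_ms": periodic,
                "rate_hz": rate_hz, "duration_ms": duration_ms}
    if kind == "lifetime-samples":
        from .analysis import sample_powerlaw_lifetimes

        exponent = 2.0
        return {"exponent": exponent,
                "samples": sample_powerlaw_lifetimes(exponent, 10_000, seed=rng)}
    if kind == "snapshot-series":
        # three nodes over three snapshots.  Pair trajectories:
        #   (0,1): U -> S -> S,  (0,2): S -> D -> S,  (1,2): U -> U -> U.
        # Hand count (intervals starting in each state): U intervals 3
        # with one U->S, S intervals 2 with one S->D, D intervals 1 with
        # one D->S, hence p_US = 1/3, p_SU = 0, p_SD = 1/2, p_DS = 1.
        series = SnapshotSeries(n_exc=3)
        frames = [
            [(0, 2)],                       # t=0: pair (0,2) singly connected
            [(0, 1), (0, 2), (2, 0)],       # t=1: (0,1) S, (0,2) D
            [(1, 0), (0, 2)],               # t=2: (0,1) S, (0,2) S
        ]
        for t, edges in enumerate(frames):
            w = np.zeros((3, 3))
            a = np.zeros((3, 3), dtype=bool)
            for i, j in edges:
                a[i, j] = True
                w[i, j] = 1.0
            series.append(float(t), w, a)
        expected = {"p_us": 1.0 / 3.0, "p_su": 0.0, "p_sd": 0.5, "p_ds": 1.0}
        return {"series": series, "expected": expected}
    if kind == "control-graphs":
        from .topology import generate_er_control, generate_modified_er_control

        return {
            "er": generate_er_control(12, 30, seed=rng),
            "modified_er": generate_modified_er_control(12, 20, 5, seed=rng),
        }
    raise ValueError(f"unknown fixture kind {kind!r}")
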