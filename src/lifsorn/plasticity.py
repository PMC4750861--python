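"""Long-term plasticity mechanisms acting on the recurrent excitatory synapses.

Four mechanisms shape the E->E wiring:

* nearest-neighbour exponential STDP, evaluated event-wise at each
  excitatory spike against the partner neuron's most recent spike;
* multiplicative synaptic normalization (SN), driving each neuron's
  incoming E->E weight sum toward a fixed target once per second;
* intrinsic plasticity (IP), a per-step firing-threshold nudge enforcing
  a target rate (3 Hz by default);
* structural plasticity: distance-biased insertion of new synapses at a
  near-zero strength once per second, and elimination of synapses whose
  weight has been driven below a near-zero pruning threshold.

All weight-bearing state lives in dense (n_exc, n_exc) arrays: ``W`` for
weights in mV (zero where no synapse exists), a boolean adjacency ``adj``
and a ``creation`` time array in seconds.  The functions here are the
production code path for the once-per-second mechanisms and the exact
reference for the per-step mechanisms mirrored in the compiled kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPConfig",
    "SNConfig",
    "IPConfig",
    "StructuralConfig",
    "stdp_on_spike",
    "synaptic_normalization",
    "normalize_incoming",
    "intrinsic_plasticity_step",
    "structural_growth",
    "structural_pruning",
    "build_w_total",
]


@dataclass
class STDPConfig:
    """Exponential pair STDP window (amplitudes in mV, time constants in ms)."""

    a_plus: float = 15.0
    a_minus: float = 7.5  # magnitude of the depression amplitude
    tau_plus: float = 15.0
    tau_minus: float = 30.0
    #: per-synapse weight ceiling (mV): potentiation saturates here.
    #: Unbounded by default -- with normalization active the incoming
    #: sum already bounds every weight; removing normalization exposes
    #: the ceiling (weights pile up at the synaptic maximum), so the
    #: no-SN ablation preset sets it to the normalization target.
    w_max: float = np.inf
    enabled: bool = True

    def __post_init__(self):
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("STDP amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")


@dataclass
class SNConfig:
    """Multiplicative synaptic normalization toward a target incoming sum."""

    eta_sn: float = 1.0
    period_s: float = 1.0
    #: mean E->E synapse strength entering the W_total product (mV); the
    #: fixed strengths of Table-style EI/IE/II wiring play the same role
    #: for their types.
    ee_mean_strength: float = 1.5
    enabled: bool = True

    def __post_init__(self):
        if not 0.0 < self.eta_sn <= 1.0:
            raise ValueError("eta_sn must be in (0, 1]")


@dataclass
class IPConfig:
    """Threshold homeostasis: V_T climbs on a spike, decays otherwise."""

    eta_ip: float = 0.1  # mV
    target_rate_hz: float = 3.0
    #: apply to inhibitory neurons too (thresholds are shared by default)
    include_inhibitory: bool = True
    enabled: bool = True

    def h_ip(self, dt_ms: float) -> float:
        """Target spikes per update interval, e.g. 3 Hz * 0.1 ms = 0.0003."""
        h = self.target_rate_hz * dt_ms * 1e-3
        if not 0.0 <= h <= 1.0:
            raise ValueError("target spikes per step outside [0, 1]")
        return h


@dataclass
class StructuralConfig:
    """Once-per-second synapse insertion and near-zero-weight elimination.

    The growth rate is the model's one hand-tuned constant: it is
    calibrated (see ``experiments.calibrate_growth_rate``) so that the
    growth/pruning balance holds the recurrent excitatory connection
    fraction at ``target_fraction`` in the stable phase.  The default
    below is the calibrated value for the standard 400 + 80 neuron
    network; the draw's standard deviation scales with the mean.
    """

    growth_mean: float = 3100.0  # synapses per second
    growth_sd: float = 3100.0
    insertion_strength: float = 1e-4  # mV
    pruning_threshold: float = 1e-6  # mV
    target_fraction: float = 0.1
    growth_enabled: bool = True
    pruning_enabled: bool = True

    def __post_init__(self):
        if min(self.growth_mean, self.growth_sd, self.insertion_strength,
               self.pruning_threshold) < 0:
            raise ValueError("structural parameters must be non-negative")
        if self.insertion_strength <= self.pruning_threshold:
            raise ValueError("insertion strength must exceed the pruning threshold")


def stdp_on_spike(
    W: np.ndarray,
    adj: np.ndarray,
    last_spike_step: np.ndarray,
    neuron: int,
    step: int,
    config: STDPConfig,
    dt_ms: float = 0.1,
    creation_step: np.ndarray | None = None,
) -> None:
    """Apply nearest-neighbour STDP for one excitatory spike, in place.

    The spiking neuron acts as *postsynaptic* partner for its incoming
    synapses (potentiation against each source's most recent spike) and
    as *presynaptic* partner for its outgoing synapses (depression
    against each target's most recent spike).  ``last_spike_step`` must
    hold the state *before* this step's spikes are registered, so that
    simultaneous spikes pair with the partner's previous spike; -1 marks
    a neuron that has never spiked (empty sum, no update).  A synapse
    only pairs with partner spikes at or after its ``creation_step``
    (new synapses inherit no spike history).  Weights are clipped at
    zero from below.
    """
    if not config.enabled:
        return
    n = W.shape[0]
    if not 0 <= neuron < n:
        raise IndexError("spiking neuron outside the excitatory population")
    known = last_spike_step >= 0
    # potentiation of incoming synapses: pre fired at last_spike, post now
    inc = adj[:, neuron] & known
    if creation_step is not None:
        inc &= last_spike_step >= creation_step[:, neuron]
    dt_pre = (step - last_spike_step[inc]) * dt_ms
    W[inc, neuron] = np.minimum(
        W[inc, neuron] + config.a_plus * np.exp(-dt_pre / config.tau_plus),
        config.w_max,
    )
    # depression of outgoing synapses: post fired at last_spike, pre now
    out = adj[neuron, :] & known
    if creation_step is not None:
        out &= last_spike_step >= creation_step[neuron, :]
    dt_post = (step - last_spike_step[out]) * dt_ms
    W[neuron, out] -= config.a_minus * np.exp(-dt_post / config.tau_minus)
    np.clip(W[neuron, :], 0.0, None, out=W[neuron, :])


def synaptic_normalization(weights: np.ndarray, w_total: float, eta_sn: float = 1.0):
    """Scale one neuron's incoming weights toward the target sum.

    Every weight is multiplied by the common factor
    ``1 + eta_sn (w_total / sum(w) - 1)``; with ``eta_sn = 1`` the
    post-update sum equals ``w_total`` exactly and relative proportions
    are preserved.  A zero incoming sum is the caller's guard case.
    """
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("synaptic normalization requires a positive incoming sum")
    return w * (1.0 + eta_sn * (w_total / total - 1.0))


def normalize_incoming(W: np.ndarray, w_total: float, eta_sn: float = 1.0) -> None:
    """Apply synaptic normalization column-wise (incoming per neuron), in place.

    Neurons with a zero incoming sum are skipped (no division).
    """
    sums = W.sum(axis=0)
    ok = sums > 0
    factors = np.ones_like(sums)
    factors[ok] = 1.0 + eta_sn * (w_total / sums[ok] - 1.0)
    W *= factors[None, :]


def intrinsic_plasticity_step(
    V_T: np.ndarray, spiked: np.ndarray, config: IPConfig, dt_ms: float = 0.1
) -> np.ndarray:
    """One IP update at per-step cadence: V_T += eta_ip (spiked - h_ip)."""
    h = config.h_ip(dt_ms)
    return V_T + config.eta_ip * (spiked.astype(float) - h)


def structural_growth(
    W: np.ndarray,
    adj: np.ndarray,
    creation: np.ndarray,
    prob_matrix: np.ndarray,
    t_s: float,
    config: StructuralConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Insert new E->E synapses for one growth event; returns their indices.

    The number of insertions is ``max(0, round(Normal(mean, sd)))``
    (negative draws clipped to zero).  Candidate ordered pairs are those
    currently unconnected with nonzero profile weight (self-pairs have
    zero weight by construction); pairs are drawn without replacement
    with probability proportional to the distance profile.  If the draw
    exceeds the available pairs, all available pairs are inserted.
    """
    from .topology import weighted_sample_without_replacement

    empty = np.empty(0, dtype=np.int64)
    k = int(round(rng.normal(config.growth_mean, config.growth_sd)))
    if k <= 0:
        return empty, empty
    weights = np.where(adj, 0.0, prob_matrix).ravel()
    n_avail = int((weights > 0).sum())
    if k > n_avail:
        import warnings

        warnings.warn(f"growth draw {k} exceeds {n_avail} available pairs")
        k = n_avail
    if k == 0:
        return empty, empty
    flat = weighted_sample_without_replacement(weights, k, rng)
    i, j = np.unravel_index(flat, adj.shape)
    adj[i, j] = True
    W[i, j] = config.insertion_strength
    creation[i, j] = t_s
    return i, j


def structural_pruning(
    W: np.ndarray,
    adj: np.ndarray,
    creation: np.ndarray,
    t_s: float,
    config: StructuralConfig,
) -> np.ndarray:
    """Remove synapses whose weight fell below the pruning threshold.

    Returns a structured record array with fields (source, target,
    t_create_s, t_death_s), one row per eliminated synapse.
    """
    doomed = adj & (W < config.pruning_threshold)
    i, j = np.nonzero(doomed)
    log = np.zeros(
        len(i),
        dtype=[("source", "i4"), ("target", "i4"),
               ("t_create_s", "f8"), ("t_death_s", "f8")],
    )
    log["source"], log["target"] = i, j
    log["t_create_s"] = creation[i, j]
    log["t_death_s"] = t_s
    adj[i, j] = False
    W[i, j] = 0.0
    creation[i, j] = np.nan
    return log


def build_w_total(
    fractions: dict,
    mean_strengths: dict,
    n_exc: int,
    n_inh: int,
) -> dict:
    """Per-type normalization target: CF x mean strength x incoming pool size.

    Strength magnitudes are used, so inhibitory types get positive
    targets.  Types with zero connection fraction are rejected (no
    incoming population to normalize).
    """
    n_in = {"EE": n_exc, "EI": n_exc, "IE": n_inh, "II": n_inh}
    out = {}
    for t, cf in fractions.items():
        w = cf * abs(mean_strengths[t]) * n_in[t]
        if w <= 0:
            raise ValueError(f"non-positive normalization target for type {t}")
        out[t] = w
    return out
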