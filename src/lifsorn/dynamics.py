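"""Noisy leaky integrate-and-fire network dynamics.

The membrane potential of every neuron follows

    dV/dt = -(V - E_l)/tau + noise,

integrated with the Euler-Maruyama scheme at dt = 0.1 ms, where the
noise increment ``sigma * sqrt(2 dt / tau) N(0, 1)`` realizes an
Ornstein-Uhlenbeck process on V itself with stationary standard
deviation ``sigma`` (5 mV by default).  A neuron whose potential reaches
its (plastic) threshold V_T emits a spike and is reset; the excitatory
reset sits below rest, providing effective refractoriness, while the
inhibitory reset at rest makes that population faster-refracting.

Spikes are transmitted as delta jumps of the synaptic weight added to
the target's membrane potential after the type-specific conduction
delay.  E->E transmission is additionally modulated by short-term
plasticity (fast depression, slower facilitation) shared per presynaptic
neuron.

:class:`Network` owns all state and advances it chunk-wise through the
compiled kernel (or a pure-Python reference used for cross-checking),
interleaving the once-per-second mechanisms: synaptic normalization,
structural growth, pruning and a connectivity snapshot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import plasticity as pl
from .topology import (
    ConnectionProfile,
    SpatialLayout,
    StaticWiring,
    pair_probability_matrix,
)

__all__ = [
    "NeuronParams",
    "STPConfig",
    "STPState",
    "membrane_step",
    "SpikeBuffer",
    "SpikeRecord",
    "SnapshotSeries",
    "SimulationResult",
    "Network",
]

DT_MS = 0.1


@dataclass
class NeuronParams:
    """Shared LIF parameters (mV, ms); resets differ between populations."""

    e_l: float = -60.0
    tau: float = 20.0
    sigma: float = 5.0
    v_reset_exc: float = -70.0
    v_reset_inh: float = -60.0
    v_t_init: float = -50.0  # starting threshold handed to IP
    dt: float = DT_MS

    @property
    def noise_coef(self) -> float:
        """Std of the per-step noise increment: sigma sqrt(2 dt / tau)."""
        return self.sigma * math.sqrt(2.0 * self.dt / self.tau)


@dataclass
class STPConfig:
    """Short-term depression/facilitation constants (Tsodyks-Markram style).

    The state (x, u) lives per *presynaptic* neuron (release-site
    dynamics are axonal) and is shared across that neuron's outgoing
    synapses.  ``scope`` selects which synapse types are modulated:
    ``"all"`` (every type, the default: STP is part of the generic
    transmitting-synapse model), ``"exc"`` (only excitatory presynaptic
    neurons, i.e. E->E and E->I) or ``"ee"`` (recurrent excitatory
    only).
    """

    U: float = 0.04
    tau_d: float = 500.0  # ms, depression recovery
    tau_f: float = 2000.0  # ms, facilitation decay
    enabled: bool = True
    scope: str = "all"  # "all" | "exc" | "ee"

    def type_flags(self) -> tuple[bool, bool, bool, bool]:
        """(EE, EI, IE, II) modulation flags implied by scope/enabled."""
        if not self.enabled:
            return False, False, False, False
        if self.scope == "all":
            return True, True, True, True
        if self.scope == "exc":
            return True, True, False, False
        if self.scope == "ee":
            return True, False, False, False
        raise ValueError(f"unknown STP scope {self.scope!r}")


class STPState:
    """Per-presynaptic-neuron STP variables with event-driven relaxation.

    Between spikes the resource x relaxes toward 1 and the utilization u
    toward U; on a spike, x is depressed with the pre-update u, then u is
    facilitated, and the transmitted weight is scaled by the post-update
    product u * x.  Scalar counterpart of the in-kernel arrays, used for
    unit-level checks.
    """

    def __init__(self, config: STPConfig | None = None):
        self.config = config or STPConfig()
        self.x = 1.0
        self.u = self.config.U

    def relax(self, dt_ms: float) -> None:
        c = self.config
        self.x = 1.0 - (1.0 - self.x) * math.exp(-dt_ms / c.tau_d)
        self.u = c.U + (self.u - c.U) * math.exp(-dt_ms / c.tau_f)

    def on_spike(self, time_since_last_ms: float | None = None) -> float:
        """Relax, apply the spike updates, return the modulation factor u*x."""
        if time_since_last_ms is not None:
            self.relax(time_since_last_ms)
        c = self.config
        self.x = self.x * (1.0 - self.u)
        self.u = self.u + c.U * (1.0 - self.u)
        return self.u * self.x


def membrane_step(
    V: np.ndarray,
    V_T: np.ndarray | float,
    params: NeuronParams,
    noise_draws: np.ndarray,
    v_reset: np.ndarray | float | None = None,
):
    """One Euler-Maruyama membrane update; returns (V_new, spiked mask).

    Spiking neurons are set to their reset potential.  ``noise_draws``
    are standard-normal variates (seeded by the caller).
    """
    V = np.asarray(V, dtype=float)
    dt, tau = params.dt, params.tau
    V_new = V + dt * (params.e_l - V) / tau + params.noise_coef * np.asarray(noise_draws)
    if not np.isfinite(V_new).all():
        raise FloatingPointError("non-finite membrane potential after update")
    spiked = V_new >= V_T
    if v_reset is None:
        v_reset = params.v_reset_exc
    V_new = np.where(spiked, v_reset, V_new)
    return V_new, spiked


class SpikeBuffer:
    """Ring buffer of delayed synaptic events, delivered exactly once.

    Scalar-path mirror of the in-kernel delivery used by unit tests; the
    buffer depth must exceed the largest delay in steps.
    """

    def __init__(self, n_neurons: int, max_delay_steps: int):
        self.depth = max_delay_steps + 1
        self.buf = np.zeros((self.depth, n_neurons))
        self.current = 0

    def schedule(self, now_step: int, delay_steps: int, target: int, weight: float):
        if delay_steps < 1 or delay_steps >= self.depth:
            raise ValueError("delay outside buffer depth (events cannot be in the past)")
        self.buf[(now_step + delay_steps) % self.depth, target] += weight

    def deliver(self, now_step: int, V: np.ndarray) -> np.ndarray:
        slot = now_step % self.depth
        V = V + self.buf[slot]
        self.buf[slot] = 0.0
        return V


class SpikeRecord:
    """Append-only record of (neuron id, spike time in ms)."""

    def __init__(self, neuron_ids: np.ndarray, t_ms: np.ndarray):
        self.neuron_ids = np.asarray(neuron_ids, dtype=np.int32)
        self.t_ms = np.asarray(t_ms, dtype=float)

    def __len__(self) -> int:
        return len(self.neuron_ids)

    def for_neuron(self, neuron: int) -> np.ndarray:
        return self.t_ms[self.neuron_ids == neuron]

    def window(self, t0_ms: float, t1_ms: float) -> "SpikeRecord":
        m = (self.t_ms >= t0_ms) & (self.t_ms < t1_ms)
        return SpikeRecord(self.neuron_ids[m], self.t_ms[m])

    def rates_hz(self, n_neurons: int, duration_ms: float) -> np.ndarray:
        counts = np.bincount(self.neuron_ids, minlength=n_neurons)
        return counts / (duration_ms * 1e-3)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron_ids, "t_ms": self.t_ms})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpikeRecord":
        df = pd.read_csv(path)
        return cls(df["neuron_id"].to_numpy(), df["t_ms"].to_numpy())


class SnapshotSeries:
    """Per-second weighted E->E edge-list snapshots with fixed node count."""

    def __init__(self, n_exc: int):
        self.n_exc = n_exc
        self.times_s: list[float] = []
        self._edges: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    def append(self, t_s: float, W: np.ndarray, adj: np.ndarray) -> None:
        if self.times_s and t_s <= self.times_s[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        i, j = np.nonzero(adj)
        self.times_s.append(float(t_s))
        self._edges.append(
            (i.astype(np.int16), j.astype(np.int16), W[i, j].astype(np.float32))
        )

    def __len__(self) -> int:
        return len(self.times_s)

    def edges(self, idx: int):
        return self._edges[idx]

    def n_edges(self, idx: int) -> int:
        return len(self._edges[idx][0])

    def adjacency(self, idx: int) -> np.ndarray:
        a = np.zeros((self.n_exc, self.n_exc), dtype=bool)
        i, j, _ = self._edges[idx]
        a[i, j] = True
        return a

    def weight_matrix(self, idx: int) -> np.ndarray:
        w = np.zeros((self.n_exc, self.n_exc))
        i, j, wv = self._edges[idx]
        w[i, j] = wv
        return w

    def index_at(self, t_s: float) -> int:
        return int(np.searchsorted(self.times_s, t_s))

    def window(self, t0_s: float, t1_s: float) -> list[int]:
        t = np.asarray(self.times_s)
        return list(np.nonzero((t >= t0_s) & (t <= t1_s))[0])

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for t, (i, j, w) in zip(self.times_s, self._edges):
            frames.append(
                pd.DataFrame(
                    {"t_s": t, "source": i.astype(int), "target": j.astype(int),
                     "weight_mV": w.astype(float)}
                )
            )
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["t_s", "source", "target", "weight_mV"]
        )


@dataclass
class SimulationResult:
    """Raw outputs of one trial plus handles on the final network state."""

    spikes: SpikeRecord
    snapshots: SnapshotSeries
    lifetime_log: np.ndarray  # structured: source, target, t_create_s, t_death_s
    per_second: pd.DataFrame  # scalar log: cf, bi fraction, rates, mean V_T
    duration_s: float
    network: "Network"

    def lifetimes_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.lifetime_log)


_LIFETIME_DTYPE = [
    ("source", "i4"), ("target", "i4"), ("t_create_s", "f8"), ("t_death_s", "f8")
]


class Network:
    """Complete spatially embedded plastic spiking network.

    Composes the spatial layout, static wiring and all plasticity
    configurations; :meth:`run` advances it and returns a
    :class:`SimulationResult`.  All randomness flows from the single
    Generator created from the ``seed`` passed to :meth:`run`.
    """

    def __init__(
        self,
        layout: SpatialLayout,
        static_wiring: StaticWiring,
        profile: ConnectionProfile | None = None,
        neuron: NeuronParams | None = None,
        stp: STPConfig | None = None,
        stdp: pl.STDPConfig | None = None,
        sn: pl.SNConfig | None = None,
        ip: pl.IPConfig | None = None,
        structural: pl.StructuralConfig | None = None,
        target_rates_hz: np.ndarray | None = None,
    ):
        self.layout = layout
        self.static = static_wiring
        self.profile = profile or ConnectionProfile()
        self.neuron = neuron or NeuronParams()
        self.stp = stp or STPConfig()
        self.stdp = stdp or pl.STDPConfig()
        self.sn = sn or pl.SNConfig()
        self.ip = ip or pl.IPConfig()
        self.structural = structural or pl.StructuralConfig()

        ne, ni = layout.n_exc, layout.n_inh
        self.n_exc, self.n_inh = ne, ni
        n = ne + ni
        p = self.neuron
        self.V = np.full(n, p.e_l)
        self.V_T = np.full(n, p.v_t_init)
        self.v_reset = np.concatenate(
            [np.full(ne, p.v_reset_exc), np.full(ni, p.v_reset_inh)]
        )
        # dynamic E->E state
        self.W = np.zeros((ne, ne))
        self.adj = np.zeros((ne, ne), dtype=bool)
        self.creation = np.full((ne, ne), np.nan)
        # creation step per synapse: STDP only pairs with partner spikes
        # fired after the synapse existed (no inherited history)
        self.creation_step = np.zeros((ne, ne), dtype=np.int64)
        self.last_spike = np.full(n, -1, dtype=np.int64)
        self.stp_x = np.ones(n)
        self.stp_u = np.full(n, self.stp.U)
        self.prob_matrix = pair_probability_matrix(
            layout.exc_positions, layout.exc_positions, self.profile, exclude_self=True
        )
        spec = static_wiring.spec
        self.w_total = pl.build_w_total(
            {t: f for t, f in spec.fractions.items() if f > 0},
            {"EE": self.sn.ee_mean_strength, "EI": spec.strengths["EI"],
             "IE": spec.strengths["IE"], "II": spec.strengths["II"]},
            ne, ni,
        )
        # static CSR tables (targets in global indices)
        self._ei = self._csr(static_wiring.edges["EI"], ne, offset=ne)
        self._ie = self._csr(static_wiring.edges["IE"], ni, offset=0)
        self._ii = self._csr(static_wiring.edges["II"], ni, offset=ne)
        self._delays = {t: spec.delay_steps(t, p.dt) for t in spec.delays_ms}
        self._strengths = spec.strengths
        # per-neuron IP targets (supports the log-normal variant)
        if target_rates_hz is None:
            target_rates_hz = np.full(n, self.ip.target_rate_hz)
        self.h_ip = np.asarray(target_rates_hz, dtype=float) * p.dt * 1e-3
        self.ip_mask = np.ones(n, dtype=bool)
        if not self.ip.include_inhibitory:
            self.ip_mask[ne:] = False
        self.step = 0  # global step counter

    @staticmethod
    def _csr(edges, n_pre, offset):
        pre, post = edges
        order = np.lexsort((post, pre))
        pre, post = np.asarray(pre)[order], np.asarray(post)[order]
        ptr = np.zeros(n_pre + 1, dtype=np.int64)
        np.add.at(ptr[1:], pre, 1)
        np.cumsum(ptr, out=ptr)
        return ptr, (post + offset).astype(np.int64)

    # ------------------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        """Write the full dynamic state as a columnar ``.npz`` container.

        Columns: membrane potentials ``V``, thresholds ``V_T``, the dense
        E->E weight/adjacency/creation matrices, last-spike steps, STP
        state (x, u) and the global step counter.  Static wiring and
        configuration are not stored; restore into a network built from
        the same config.
        """
        np.savez_compressed(
            path, V=self.V, V_T=self.V_T, W=self.W, adj=self.adj,
            creation=self.creation, creation_step=self.creation_step,
            last_spike=self.last_spike, stp_x=self.stp_x, stp_u=self.stp_u,
            step=np.int64(self.step),
        )

    def load_checkpoint(self, path) -> None:
        """Restore state written by :meth:`save_checkpoint`, in place."""
        data = np.load(path)
        for name in ("V", "V_T", "W", "adj", "creation", "creation_step",
                     "last_spike", "stp_x", "stp_u"):
            current = getattr(self, name)
            if data[name].shape != current.shape:
                raise ValueError(f"checkpoint field {name} has shape "
                                 f"{data[name].shape}, expected {current.shape}")
            setattr(self, name, data[name].copy())
        self.step = int(data["step"])

    # ------------------------------------------------------------------
    def run(
        self,
        duration_s: float,
        seed=None,
        backend: str = "numba",
        record_capacity: int = 2_000_000,
        progress: bool = False,
    ) -> SimulationResult:
        """Advance the network ``duration_s`` simulated seconds.

        Per-second schedule after each 1 s chunk of steps:
        normalization -> structural growth -> pruning -> snapshot.
        Deterministic given the seed; ``backend='python'`` runs the pure
        reference stepper (tiny networks only).
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        p = self.neuron
        steps_per_s = int(round(1000.0 / p.dt))
        n_full = int(duration_s)
        rem_steps = int(round((duration_s - n_full) * steps_per_s))

        snapshots = SnapshotSeries(self.n_exc)
        snapshots.append(self.step * p.dt / 1000.0 - 1e-9 if self.step else 0.0,
                         self.W, self.adj)
        lifetime_chunks: list[np.ndarray] = []
        rec_ids: list[np.ndarray] = []
        rec_steps: list[np.ndarray] = []
        log_rows = []
        rec_id = np.empty(record_capacity, dtype=np.int32)
        rec_step = np.empty(record_capacity, dtype=np.int64)
        spike_counts = np.zeros(self.n_exc + self.n_inh, dtype=np.int64)
        max_delay = max(self._delays.values())
        buf = np.zeros((max_delay + 1, self.n_exc + self.n_inh))
        prev_counts = spike_counts.copy()
        self._overflow_warned = False

        chunks = [steps_per_s] * n_full + ([rem_steps] if rem_steps else [])
        for ci, n_steps in enumerate(chunks):
            noise = rng.standard_normal((n_steps, self.n_exc + self.n_inh))
            n_rec, overflow = self._advance(backend, n_steps, noise, buf,
                                            rec_id, rec_step, spike_counts)
            if overflow and not self._overflow_warned:
                import warnings

                warnings.warn("spike record capacity exceeded; record truncated "
                              "(rates remain exact)")
                self._overflow_warned = True
            rec_ids.append(rec_id[:n_rec].copy())
            rec_steps.append(rec_step[:n_rec].copy())
            if not np.isfinite(self.V).all():
                bad = np.nonzero(~np.isfinite(self.V))[0]
                raise RuntimeError(
                    f"non-finite membrane potential at t = "
                    f"{self.step * p.dt / 1000.0:.3f} s (neurons {bad[:5]}...)"
                )
            is_full_second = n_steps == steps_per_s
            if is_full_second:
                t_s = round(self.step * p.dt / 1000.0)
                if self.sn.enabled and "EE" in self.w_total:
                    pl.normalize_incoming(self.W, self.w_total["EE"], self.sn.eta_sn)
                if self.structural.growth_enabled:
                    gi, gj = pl.structural_growth(self.W, self.adj, self.creation,
                                                  self.prob_matrix, t_s,
                                                  self.structural, rng)
                    self.creation_step[gi, gj] = self.step
                if self.structural.pruning_enabled:
                    log = pl.structural_pruning(self.W, self.adj, self.creation,
                                                t_s, self.structural)
                    if len(log):
                        lifetime_chunks.append(log)
                snapshots.append(t_s, self.W, self.adj)
                sec_counts = spike_counts - prev_counts
                prev_counts = spike_counts.copy()
                a_and = self.adj & self.adj.T
                npairs = self.n_exc * (self.n_exc - 1)
                log_rows.append(
                    {
                        "t_s": t_s,
                        "connection_fraction": self.adj.sum() / npairs,
                        "bidirectional_fraction": a_and.sum() / npairs,
                        "mean_rate_exc_hz": sec_counts[: self.n_exc].mean(),
                        "mean_rate_inh_hz": sec_counts[self.n_exc:].mean()
                        if self.n_inh else np.nan,
                        "mean_v_t_exc_mv": self.V_T[: self.n_exc].mean(),
                    }
                )
            if progress and is_full_second and t_s % 50 == 0:
                print(f"  t = {t_s:.0f} s, cf = {log_rows[-1]['connection_fraction']:.4f}")

        ids = np.concatenate(rec_ids) if rec_ids else np.empty(0, dtype=np.int32)
        steps = np.concatenate(rec_steps) if rec_steps else np.empty(0, dtype=np.int64)
        lifetimes = (
            np.concatenate(lifetime_chunks)
            if lifetime_chunks
            else np.empty(0, dtype=_LIFETIME_DTYPE)
        )
        return SimulationResult(
            spikes=SpikeRecord(ids, steps * p.dt),
            snapshots=snapshots,
            lifetime_log=lifetimes,
            per_second=pd.DataFrame(log_rows),
            duration_s=float(duration_s),
            network=self,
        )

    # ------------------------------------------------------------------
    def _advance(self, backend, n_steps, noise, buf, rec_id, rec_step, spike_counts):
        p = self.neuron
        mod_ee, mod_ei, mod_ie, mod_ii = self.stp.type_flags()
        args = (
            self.step, n_steps, p.dt, p.e_l, p.tau, p.noise_coef, noise,
            self.V, self.V_T, self.v_reset, self.n_exc,
            self.W, self.adj, self.creation_step, self.last_spike,
            mod_ee, mod_ei, mod_ie, mod_ii, self.stp_x, self.stp_u,
            self.stp.U, self.stp.tau_d, self.stp.tau_f,
            self.stdp.enabled, self.stdp.a_plus, self.stdp.a_minus,
            self.stdp.tau_plus, self.stdp.tau_minus, self.stdp.w_max,
            self.ip.enabled, self.ip_mask, self.ip.eta_ip, self.h_ip,
            self._ei[0], self._ei[1], self._strengths["EI"],
            self._ie[0], self._ie[1], self._strengths["IE"],
            self._ii[0], self._ii[1], self._strengths["II"],
            self._delays["EE"], self._delays["EI"],
            self._delays["IE"], self._delays["II"],
            buf, rec_id, rec_step, spike_counts,
        )
        if backend == "numba":
            from ._kernel import step_chunk

            out = step_chunk(*args)
        elif backend == "python":
            out = _step_chunk_python(*args)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        self.step += n_steps
        return out


def _step_chunk_python(
    step0, n_steps, dt, e_l, tau_m, noise_coef, noise, V, V_T, v_reset, n_exc,
    W, adj, creation_step, last_spike,
    mod_ee, mod_ei, mod_ie, mod_ii, stp_x, stp_u, stp_U, tau_d, tau_f,
    stdp_on, a_plus, a_minus, tau_plus, tau_minus, w_max,
    ip_on, ip_mask, eta_ip, h_ip,
    ei_ptr, ei_tgt, w_ei, ie_ptr, ie_tgt, w_ie, ii_ptr, ii_tgt, w_ii,
    d_ee, d_ei, d_ie, d_ii, buf, rec_id, rec_step, spike_counts,
):
    """Pure-Python/numpy reference for the compiled kernel (same contract)."""
    stdp_cfg = pl.STDPConfig(a_plus, a_minus, tau_plus, tau_minus, w_max,
                             enabled=stdp_on)
    D = buf.shape[0]
    cap = rec_id.shape[0]
    n_rec = 0
    overflow = False
    for s in range(n_steps):
        g = step0 + s
        V += dt * (e_l - V) / tau_m + noise_coef * noise[s]
        spiked = V >= V_T
        V[spiked] = v_reset[spiked]
        spikers = np.nonzero(spiked)[0]
        if stdp_on:
            for i in spikers:
                if i < n_exc:
                    pl.stdp_on_spike(W, adj, last_spike[:n_exc], int(i), g,
                                     stdp_cfg, dt, creation_step)
        for i in spikers:
            is_exc = i < n_exc
            update_stp = (mod_ee or mod_ei) if is_exc else (mod_ie or mod_ii)
            factor = 1.0
            if update_stp:
                x, u = stp_x[i], stp_u[i]
                if last_spike[i] >= 0:
                    dtms = (g - last_spike[i]) * dt
                    x = 1.0 - (1.0 - x) * math.exp(-dtms / tau_d)
                    u = stp_U + (u - stp_U) * math.exp(-dtms / tau_f)
                x = x * (1.0 - u)
                u = u + stp_U * (1.0 - u)
                stp_x[i], stp_u[i] = x, u
                factor = u * x
            if is_exc:
                slot = (g + d_ee) % D
                targets = np.nonzero(adj[i])[0]
                buf[slot, targets] += (factor if mod_ee else 1.0) * W[i, targets]
                slot = (g + d_ei) % D
                f_ei = factor * w_ei if mod_ei else w_ei
                for e in range(ei_ptr[i], ei_ptr[i + 1]):
                    buf[slot, ei_tgt[e]] += f_ei
            else:
                j = i - n_exc
                slot = (g + d_ie) % D
                f_ie = factor * w_ie if mod_ie else w_ie
                for e in range(ie_ptr[j], ie_ptr[j + 1]):
                    buf[slot, ie_tgt[e]] += f_ie
                slot = (g + d_ii) % D
                f_ii = factor * w_ii if mod_ii else w_ii
                for e in range(ii_ptr[j], ii_ptr[j + 1]):
                    buf[slot, ii_tgt[e]] += f_ii
        for i in spikers:
            last_spike[i] = g
            spike_counts[i] += 1
            if n_rec < cap:
                rec_id[n_rec] = i
                rec_step[n_rec] = g
                n_rec += 1
            else:
                overflow = True
        slot = g % D
        V += buf[slot]
        buf[slot] = 0.0
        if ip_on:
            V_T[ip_mask] += eta_ip * (spiked[ip_mask].astype(float) - h_ip[ip_mask])
    return n_rec, overflow
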