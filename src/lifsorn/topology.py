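"""Spatial layout, distance-dependent wiring and null-model control graphs.

Neurons live on a flat 2D sheet (a cortical-slice abstraction, default
1000 x 1000 um) and the probability that an ordered pair of neurons is
wired decays with their Euclidean distance following a Gaussian profile.
Only *relative* probabilities matter: wiring draws a fixed number of
edges without replacement, with per-pair sampling weights proportional
to the profile, so connection fractions are exactly reproducible.

The module also provides the two random-graph null models used by the
analysis layer: a plain Erdos-Renyi digraph matched in nodes and edges,
and a "modified" Erdos-Renyi control matched separately in the number of
unidirectional edges and reciprocal (bidirectional) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SpatialLayout",
    "ConnectionProfile",
    "WiringSpec",
    "StaticWiring",
    "place_neurons",
    "pair_probability",
    "pair_probability_matrix",
    "wire_static_populations",
    "weighted_sample_without_replacement",
    "generate_er_control",
    "generate_modified_er_control",
]

#: Synapse types keyed by (presynaptic population, postsynaptic population).
SYNAPSE_TYPES = ("EE", "EI", "IE", "II")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SpatialLayout:
    """Positions of all neurons on the sheet; excitatory first, then inhibitory."""

    positions: np.ndarray  # (n_exc + n_inh, 2), um
    sheet_width: float = 1000.0
    sheet_height: float = 1000.0
    n_exc: int = 400
    n_inh: int = 80

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.n_exc + self.n_inh, 2):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"n_exc + n_inh = {self.n_exc + self.n_inh}"
            )
        if (self.positions < 0).any() or (
            self.positions > [self.sheet_width, self.sheet_height]
        ).any():
            raise ValueError("positions outside the sheet")

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def exc_positions(self) -> np.ndarray:
        return self.positions[: self.n_exc]

    @property
    def inh_positions(self) -> np.ndarray:
        return self.positions[self.n_exc :]

    def to_dataframe(self) -> pd.DataFrame:
        pop = ["exc"] * self.n_exc + ["inh"] * self.n_inh
        return pd.DataFrame(
            {
                "neuron_id": np.arange(self.n_total),
                "population": pop,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sheet_width=1000.0, sheet_height=1000.0) -> "SpatialLayout":
        df = pd.read_csv(path)
        n_exc = int((df["population"] == "exc").sum())
        n_inh = int((df["population"] == "inh").sum())
        pos = df.sort_values("neuron_id")[["x_um", "y_um"]].to_numpy()
        return cls(pos, sheet_width, sheet_height, n_exc, n_inh)


@dataclass
class ConnectionProfile:
    """Gaussian distance-dependent relative connection probability.

    ``half_width`` is 200 um by default.  Under the default ``sigma``
    interpretation the profile is ``exp(-d^2 / (2 half_width^2))``; the
    alternative ``hwhm`` interpretation reads the half-width as the
    half-width at half maximum, i.e. ``sigma = half_width / sqrt(2 ln 2)``.
    """

    half_width: float = 200.0
    interpretation: str = "sigma"  # "sigma" | "hwhm"

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.interpretation not in ("sigma", "hwhm"):
            raise ValueError("interpretation must be 'sigma' or 'hwhm'")

    @property
    def sigma(self) -> float:
        if self.interpretation == "sigma":
            return self.half_width
        return self.half_width / np.sqrt(2.0 * np.log(2.0))

    def __call__(self, distance_um):
        return pair_probability(distance_um, self)


#: Uniform profile sentinel: every pair equally likely (used by the
#: "no topology" model variant).
@dataclass
class UniformProfile:
    def __call__(self, distance_um):
        d = np.asarray(distance_um, dtype=float)
        if (d < 0).any():
            raise ValueError("distance must be non-negative")
        return np.ones_like(d)

    @property
    def sigma(self) -> float:  # pragma: no cover - cosmetic
        return np.inf


def pair_probability(distance_um, profile: ConnectionProfile):
    """Relative connection probability at the given distance(s), in (0, 1]."""
    d = np.asarray(distance_um, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be non-negative")
    s = profile.sigma
    out = np.exp(-(d**2) / (2.0 * s**2))
    if np.ndim(distance_um) == 0:
        return float(out)
    return out


def pair_probability_matrix(
    pre_positions: np.ndarray,
    post_positions: np.ndarray,
    profile,
    exclude_self: bool = False,
) -> np.ndarray:
    """Matrix of relative probabilities for all ordered (pre, post) pairs.

    With ``exclude_self=True`` (same population on both sides) the
    diagonal is zeroed, removing self-pairs from any subsequent sampling.
    """
    diff = pre_positions[:, None, :] - post_positions[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    p = np.asarray(profile(d), dtype=float)
    if exclude_self:
        if p.shape[0] != p.shape[1]:
            raise ValueError("exclude_self requires a square pair matrix")
        np.fill_diagonal(p, 0.0)
    return p


@dataclass
class WiringSpec:
    """Per-type connection fraction, insertion strength (mV) and delay (ms)."""

    fractions: dict = field(
        default_factory=lambda: {"EE": 0.1, "EI": 0.1, "IE": 0.1, "II": 0.5}
    )
    strengths: dict = field(
        default_factory=lambda: {"EE": 0.0001, "EI": 1.5, "IE": -1.5, "II": -1.5}
    )
    delays_ms: dict = field(
        default_factory=lambda: {"EE": 1.5, "EI": 0.5, "IE": 1.0, "II": 1.0}
    )

    def __post_init__(self):
        for t in SYNAPSE_TYPES:
            if not 0.0 <= self.fractions[t] <= 1.0:
                raise ValueError(f"connection fraction for {t} outside [0, 1]")
            if self.delays_ms[t] <= 0:
                raise ValueError(f"conduction delay for {t} must be positive")

    def delay_steps(self, syn_type: str, dt_ms: float) -> int:
        steps = self.delays_ms[syn_type] / dt_ms
        rounded = int(round(steps))
        if abs(steps - rounded) > 1e-9 or rounded < 1:
            raise ValueError(
                f"delay {self.delays_ms[syn_type]} ms for {syn_type} is not a "
                f"positive multiple of dt = {dt_ms} ms"
            )
        return rounded


@dataclass
class StaticWiring:
    """Fixed-efficacy synapse tables (E->I, I->E, I->I); E->E starts empty."""

    # each entry: (pre_indices, post_indices) with population-local indices
    edges: dict
    spec: WiringSpec

    def count(self, syn_type: str) -> int:
        return len(self.edges[syn_type][0])

    def to_dataframe(self, layout: SpatialLayout) -> pd.DataFrame:
        rows = []
        for t in SYNAPSE_TYPES:
            pre, post = self.edges[t]
            pre_g = pre if t[0] == "E" else pre + layout.n_exc
            post_g = post if t[1] == "E" else post + layout.n_exc
            rows.append(
                pd.DataFrame(
                    {
                        "type": t,
                        "source": pre_g,
                        "target": post_g,
                        "weight_mV": self.spec.strengths[t],
                        "delay_ms": self.spec.delays_ms[t],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def place_neurons(
    n_exc: int = 400,
    n_inh: int = 80,
    sheet_width: float = 1000.0,
    sheet_height: float = 1000.0,
    seed=None,
) -> SpatialLayout:
    """Uniform-random neuron positions on the sheet; deterministic per seed."""
    if n_exc <= 0 or n_inh < 0:
        raise ValueError("need n_exc >= 1 and n_inh >= 0")
    if sheet_width <= 0 or sheet_height <= 0:
        raise ValueError("sheet dimensions must be positive")
    rng = _as_rng(seed)
    n = n_exc + n_inh
    pos = rng.uniform([0.0, 0.0], [sheet_width, sheet_height], size=(n, 2))
    return SpatialLayout(pos, sheet_width, sheet_height, n_exc, n_inh)


def weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of ``k`` items drawn without replacement, P(item) ∝ weight.

    Uses the Gumbel top-k trick: adding i.i.d. Gumbel noise to log-weights
    and taking the k largest keys is equivalent to sequential weighted
    sampling without replacement.  Zero-weight items are never selected.
    """
    w = np.asarray(weights, dtype=float).ravel()
    feasible = w > 0
    n_feasible = int(feasible.sum())
    if k > n_feasible:
        raise ValueError(f"requested {k} draws from {n_feasible} feasible items")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    keys = np.full(w.shape, -np.inf)
    gumbel = -np.log(-np.log(rng.uniform(size=n_feasible)))
    keys[feasible] = np.log(w[feasible]) + gumbel
    idx = np.argpartition(-keys, k - 1)[:k]
    return idx


def _sample_pairs(prob: np.ndarray, k: int, rng) -> tuple[np.ndarray, np.ndarray]:
    flat = weighted_sample_without_replacement(prob, k, rng)
    return np.unravel_index(flat, prob.shape)


def wire_static_populations(
    layout: SpatialLayout,
    profile,
    spec: WiringSpec | None = None,
    seed=None,
) -> StaticWiring:
    """Draw the fixed E->I, I->E and I->I synapses; E->E is left empty.

    Each type receives exactly ``round(CF * N_pre * N_post)`` edges,
    sampled without replacement with probability proportional to the
    distance profile (self-pairs excluded for I->I).
    """
    spec = spec or WiringSpec()
    rng = _as_rng(seed)
    pe, pi = layout.exc_positions, layout.inh_positions
    pops = {"E": pe, "I": pi}
    edges = {"EE": (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))}
    for t in ("EI", "IE", "II"):
        pre, post = pops[t[0]], pops[t[1]]
        n_pre, n_post = len(pre), len(post)
        k = int(round(spec.fractions[t] * n_pre * n_post))
        prob = pair_probability_matrix(pre, post, profile, exclude_self=(t[0] == t[1]))
        edges[t] = _sample_pairs(prob, k, rng)
    return StaticWiring(edges=edges, spec=spec)


def generate_er_control(n_nodes: int, n_edges: int, seed=None) -> nx.DiGraph:
    """Erdos-Renyi G(n, m) digraph: ``n_edges`` distinct directed edges, no self-loops."""
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ValueError(f"cannot place {n_edges} edges on {max_edges} ordered pairs")
    rng = _as_rng(seed)
    flat = rng.choice(max_edges, size=n_edges, replace=False)
    # map [0, n(n-1)) to off-diagonal (i, j)
    i = flat // (n_nodes - 1)
    r = flat % (n_nodes - 1)
    j = np.where(r >= i, r + 1, r)
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(zip(i.tolist(), j.tolist()))
    return g


def generate_modified_er_control(
    n_nodes: int, n_uni_edges: int, n_bi_pairs: int, seed=None
) -> nx.DiGraph:
    """Control digraph with exact unidirectional / bidirectional edge counts.

    ``n_bi_pairs`` unordered pairs receive reciprocal edges and
    ``n_uni_edges`` further pairs (disjoint from the reciprocal ones)
    receive a single edge with uniformly random orientation; pair
    placements are uniform.  This is the bidirectionality-corrected null
    for the motif census.
    """
    n_pairs = n_nodes * (n_nodes - 1) // 2
    if n_uni_edges + n_bi_pairs > n_pairs:
        raise ValueError(
            f"{n_uni_edges} + {n_bi_pairs} connected pairs exceed {n_pairs} available"
        )
    rng = _as_rng(seed)
    chosen = rng.choice(n_pairs, size=n_uni_edges + n_bi_pairs, replace=False)
    iu, ju = np.triu_indices(n_nodes, k=1)
    a, b = iu[chosen], ju[chosen]
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for idx in range(n_bi_pairs):
        g.add_edge(int(a[idx]), int(b[idx]))
        g.add_edge(int(b[idx]), int(a[idx]))
    flips = rng.integers(0, 2, size=n_uni_edges)
    for idx in range(n_uni_edges):
        s, t = a[n_bi_pairs + idx], b[n_bi_pairs + idx]
        if flips[idx]:
            s, t = t, s
        g.add_edge(int(s), int(t))
    return g


def graph_to_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def edges_to_csv(graph: nx.DiGraph, path) -> None:
    df = nx.to_pandas_edgelist(graph)
    df.to_csv(path, index=False)
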