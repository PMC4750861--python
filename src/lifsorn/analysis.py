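"""Statistics of the emergent wiring: bidirectionality, motifs, weights,
synaptic lifetimes, spiking regularity and pairwise correlations.

Conventions used throughout:

* The connection fraction is directed edges over ordered pairs
  ``n (n - 1)``; the bidirectional fraction uses the same ordered-pair
  denominator (``2 x reciprocal pairs / n (n - 1)``), so its chance
  level in a density-matched Erdos-Renyi graph is exactly the squared
  connection fraction.
* Triads are classified into the 16 directed isomorphism classes.  The
  class order is fixed by :data:`MOTIF_ORDER` (explicit diagrams in the
  docstring of :func:`triad_census`); the "closed-loop" family is the
  set of classes whose three pairs are all connected.
* Synaptic lifetime distributions are fitted exactly as a slope of a
  least-squares line on the log-log histogram below the right-censoring
  drop-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .topology import generate_modified_er_control

__all__ = [
    "connection_fraction",
    "bidirectional_stats",
    "MOTIF_ORDER",
    "CLOSED_LOOP_CLASSES",
    "triad_census",
    "count_uni_bi",
    "analytic_motif_expectation",
    "motif_overrepresentation",
    "weight_log_histogram",
    "weight_change_dynamics",
    "extract_lifetimes",
    "fit_powerlaw_slope",
    "isi_statistics",
    "spearman_table",
]


# ----------------------------------------------------------------------
# connectivity fractions
# ----------------------------------------------------------------------

def connection_fraction(adj: np.ndarray, n_exc: int | None = None) -> float:
    """Directed edges / ordered pairs for a boolean adjacency matrix."""
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0] if n_exc is None else n_exc
    if n < 2:
        raise ValueError("need at least two nodes")
    return float(a.sum()) / (n * (n - 1))


def bidirectional_stats(adj: np.ndarray, n_exc: int | None = None):
    """(bidirectional fraction, chance level, factor over chance).

    The chance level is the squared connection fraction, i.e. the
    expected bidirectional fraction of an Erdos-Renyi digraph with the
    same number of nodes and edges.
    """
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0] if n_exc is None else n_exc
    npairs = n * (n - 1)
    cf = a.sum() / npairs
    bi = (a & a.T).sum() / npairs  # = 2 * reciprocal pairs / ordered pairs
    chance = cf**2
    factor = bi / chance if chance > 0 else np.nan
    return float(bi), float(chance), float(factor)


# ----------------------------------------------------------------------
# triadic motifs
# ----------------------------------------------------------------------

#: The 16 triad isomorphism classes in the order used for the motif
#: census bars, keyed by the standard triad-census code
#: (mutual-asymmetric-null counts plus orientation letter).  Reading the
#: diagrams with nodes a, b, c:
#:
#:  1 003   a   b   c        (null triad)
#:  2 102   a<->b   c        (one reciprocal pair, isolated node)
#:  3 012   a->b    c        (one single edge, isolated node)
#:  4 021C  a->b->c          (chain)
#:  5 021D  a<-b->c          (divergence)
#:  6 021U  a->b<-c          (convergence)
#:  7 111D  a<->b<-c
#:  8 111U  a<->b->c
#:  9 201   a<->b<->c
#: 10 030T  a->b->c, a->c    (feed-forward triangle)
#: 11 030C  a->b->c->a       (cycle)
#: 12 120D  a<-b->c, a<->c
#: 13 120U  a->b<-c, a<->c
#: 14 120C  a->b->c, a<->c
#: 15 210   a->b<->c, a<->c
#: 16 300   complete (all reciprocal)
#:
#: Classes 10-16 have all three pairs connected; these form the
#: "closed-loop" family whose joint overrepresentation is the motif
#: signature of the self-organized network.
MOTIF_ORDER = [
    "003", "102", "012", "021C", "021D", "021U", "111D", "111U",
    "201", "030T", "030C", "120D", "120U", "120C", "210", "300",
]

#: 0-based indices of the fully connected ("closed loop") triad classes.
CLOSED_LOOP_CLASSES = list(range(9, 16))


def triad_census(graph: nx.DiGraph) -> np.ndarray:
    """Counts of the 16 triad classes, in :data:`MOTIF_ORDER` order.

    Every unordered node triple falls in exactly one class, so the
    counts sum to C(N, 3).  Self-loops are rejected.
    """
    if any(u == v for u, v in nx.selfloop_edges(graph)):
        raise ValueError("triad census requires a simple digraph without self-loops")
    census = nx.triadic_census(graph)
    return np.array([census[name] for name in MOTIF_ORDER], dtype=np.int64)


def count_uni_bi(adj_or_graph) -> tuple[int, int]:
    """(# unidirectional directed edges, # reciprocal unordered pairs)."""
    if isinstance(adj_or_graph, nx.DiGraph):
        a = nx.to_numpy_array(adj_or_graph, dtype=bool)
    else:
        a = np.asarray(adj_or_graph, dtype=bool)
    both = a & a.T
    n_bi = int(both.sum()) // 2
    n_uni = int(a.sum()) - 2 * n_bi
    return n_uni, n_bi


def _pattern_class_index(bits: tuple) -> int:
    """Class index (0-based, MOTIF_ORDER) of one labelled 3-node pattern.

    ``bits`` are the six directed edges in the fixed order
    (ab, ba, ac, ca, bc, cb).
    """
    g = nx.DiGraph()
    g.add_nodes_from([0, 1, 2])
    order = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
    for bit, e in zip(bits, order):
        if bit:
            g.add_edge(*e)
    return int(np.nonzero(triad_census(g))[0][0])


def analytic_motif_expectation(n_nodes: int, n_uni: int, n_bi: int) -> np.ndarray:
    """Exact expected triad-class counts under the modified-ER null.

    The null assigns the requested numbers of unidirectional and
    reciprocal pairs to uniformly chosen distinct unordered pairs
    (orientations of unidirectional edges independent and fair).  For a
    fixed triple, the chance that its three pairs carry ``k`` null,
    ``l`` unidirectional and ``m`` reciprocal states is multivariate
    hypergeometric; summing the labelled-pattern probabilities per
    isomorphism class and multiplying by C(N, 3) gives the exact
    expectation that the Monte-Carlo control mean converges to.
    """
    m_pairs = n_nodes * (n_nodes - 1) // 2
    n_null = m_pairs - n_uni - n_bi
    if n_null < 0:
        raise ValueError("edge counts exceed available pairs")

    def falling(n, k):
        out = 1.0
        for t in range(k):
            out *= n - t
        return out

    class_prob = np.zeros(16)
    for ab in (0, 1):
        for ba in (0, 1):
            for ac in (0, 1):
                for ca in (0, 1):
                    for bc in (0, 1):
                        for cb in (0, 1):
                            states = [(ab, ba), (ac, ca), (bc, cb)]
                            k1 = sum(1 for s in states if sum(s) == 1)
                            k2 = sum(1 for s in states if sum(s) == 2)
                            k0 = 3 - k1 - k2
                            prob = (
                                falling(n_null, k0)
                                * falling(n_uni, k1)
                                * falling(n_bi, k2)
                                / falling(m_pairs, 3)
                                * 0.5**k1
                            )
                            if prob > 0:
                                idx = _pattern_class_index(
                                    (ab, ba, ac, ca, bc, cb)
                                )
                                class_prob[idx] += prob
    n_triples = n_nodes * (n_nodes - 1) * (n_nodes - 2) / 6.0
    return n_triples * class_prob


@dataclass
class MotifReport:
    """Observed counts vs the bidirectionality-matched control."""

    observed: np.ndarray  # (16,)
    expected: np.ndarray  # (16,) mean over controls (or analytic)
    spread: np.ndarray  # (16,) control standard deviation (0 for analytic)
    ratio: np.ndarray  # observed / expected, nan where expected ~ 0
    low_expectation: np.ndarray  # boolean flags for near-zero expectations

    def closed_loop_ratio(self) -> float:
        """Pooled observed/expected over the fully connected triad family."""
        idx = CLOSED_LOOP_CLASSES
        return float(self.observed[idx].sum() / self.expected[idx].sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": np.arange(1, 17),
                "class": MOTIF_ORDER,
                "observed": self.observed,
                "expected": self.expected,
                "spread": self.spread,
                "ratio": self.ratio,
                "low_expectation": self.low_expectation,
            }
        )


def motif_overrepresentation(
    graph_or_adj,
    n_control_samples: int = 20,
    seed=None,
    method: str = "montecarlo",
    low_expectation_threshold: float = 1.0,
) -> MotifReport:
    """Per-class motif counts relative to the modified-ER control.

    The control matches the observed number of unidirectional edges and
    reciprocal pairs (placed independently), which corrects the census
    for the overrepresentation of bidirectional connections.  With
    ``method='analytic'`` the closed-form expectation replaces the
    Monte-Carlo control mean.
    """
    if isinstance(graph_or_adj, nx.DiGraph):
        graph = graph_or_adj
        n = graph.number_of_nodes()
    else:
        a = np.asarray(graph_or_adj, dtype=bool)
        graph = nx.from_numpy_array(a, create_using=nx.DiGraph)
        n = a.shape[0]
    observed = triad_census(graph)
    n_uni, n_bi = count_uni_bi(graph)
    if method == "analytic":
        expected = analytic_motif_expectation(n, n_uni, n_bi)
        spread = np.zeros(16)
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        samples = np.empty((n_control_samples, 16))
        for k in range(n_control_samples):
            ctrl = generate_modified_er_control(n, n_uni, n_bi, rng)
            samples[k] = triad_census(ctrl)
        expected = samples.mean(axis=0)
        spread = samples.std(axis=0, ddof=1) if n_control_samples > 1 else np.zeros(16)
    else:
        raise ValueError(f"unknown method {method!r}")
    low = expected < low_expectation_threshold
    ratio = np.divide(observed, expected, out=np.full(16, np.nan), where=expected > 0)
    return MotifReport(observed, expected, spread, ratio, low)


# ----------------------------------------------------------------------
# weight statistics
# ----------------------------------------------------------------------

def weight_log_histogram(weights: np.ndarray, bins: int = 40):
    """Normalized histogram of log10 weights plus shape summaries.

    Zero or negative weights are excluded (a zero weight marks a synapse
    pending elimination, not a strength).  Returns (density, bin edges,
    skewness, excess kurtosis) of the log10-transformed weights.
    """
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("no positive weights to histogram")
    logw = np.log10(w)
    density, edges = np.histogram(logw, bins=bins, density=True)
    return density, edges, float(stats.skew(logw)), float(stats.kurtosis(logw))


def weight_change_dynamics(W0: np.ndarray, W1: np.ndarray, n_bins: int = 8):
    """Paired weight changes for synapses present in both snapshots.

    Returns a tidy frame with initial weight, absolute and relative
    change, and a binned summary of the median |relative change| per
    initial-weight bin (log-spaced).
    """
    present = (np.asarray(W0) > 0) & (np.asarray(W1) > 0)
    w0 = np.asarray(W0)[present]
    w1 = np.asarray(W1)[present]
    df = pd.DataFrame({"w0": w0, "dw": w1 - w0, "rel_dw": (w1 - w0) / w0})
    edges = np.logspace(np.log10(w0.min()), np.log10(w0.max()), n_bins + 1)
    df["w0_bin"] = pd.cut(df["w0"], edges, include_lowest=True)
    summary = df.groupby("w0_bin", observed=True).agg(
        n=("w0", "size"),
        mean_dw=("dw", "mean"),
        median_abs_rel=("rel_dw", lambda x: np.median(np.abs(x))),
    )
    return df, summary


# ----------------------------------------------------------------------
# synaptic lifetimes
# ----------------------------------------------------------------------

def extract_lifetimes(
    lifetime_log: np.ndarray,
    phase: str,
    duration_s: float,
    growth_end_s: float = 150.0,
    stable_start_s: float = 350.0,
) -> np.ndarray:
    """Lifetimes (s) of pruned synapses in the requested phase window.

    Growth phase: synapses whose death time is below ``growth_end_s``.
    Stable phase: synapses created after ``stable_start_s``.  Synapses
    still alive at the end of the run never enter the log, so the sample
    is automatically free of right-censored entries.
    """
    log = np.asarray(lifetime_log)
    if phase == "growth":
        mask = log["t_death_s"] < growth_end_s
    elif phase == "stable":
        mask = log["t_create_s"] > stable_start_s
    elif phase == "all":
        mask = np.ones(len(log), dtype=bool)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    lt = log["t_death_s"][mask] - log["t_create_s"][mask]
    return lt[lt > 0]


def fit_powerlaw_slope(
    lifetimes: np.ndarray,
    observation_window_s: float,
    n_bins: int = 12,
    dropoff_fraction: float = 0.1,
    min_samples: int = 50,
    min_count: int = 5,
):
    """Power-law slope of the lifetime distribution via log-log regression.

    Lifetimes are histogrammed in log-spaced bins; a least-squares line
    is fitted to log10(density) vs log10(lifetime) over the bins whose
    centres lie below the drop-off cut (``dropoff_fraction`` of the
    observation window, excluding the region distorted by the finite
    run length).  Bins with fewer than ``min_count`` entries are
    excluded: dropping empty bins while keeping one-count bins biases
    the tail density upward and the slope shallow.  Returns the positive
    slope magnitude and the regression result.
    """
    lt = np.asarray(lifetimes, dtype=float)
    if lt.size < min_samples:
        raise ValueError(f"need at least {min_samples} lifetimes, got {lt.size}")
    lo, hi = lt.min(), lt.max()
    if hi <= lo:
        raise ValueError("degenerate lifetime sample")
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    counts, _ = np.histogram(lt, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / widths
    cut = dropoff_fraction * observation_window_s
    keep = (counts >= min_count) & (centers <= cut)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 histogram points before the drop-off cut")
    fit = stats.linregress(np.log10(centers[keep]), np.log10(density[keep]))
    return -float(fit.slope), fit


def sample_powerlaw_lifetimes(
    exponent: float, n: int, xmin: float = 1.0, seed=None
) -> np.ndarray:
    """Inverse-CDF samples from a density ∝ L^-exponent on [xmin, inf)."""
    if exponent <= 1.0:
        raise ValueError("power-law exponent must exceed 1 for a proper density")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    return xmin * (1.0 - u) ** (-1.0 / (exponent - 1.0))


# ----------------------------------------------------------------------
# spiking statistics
# ----------------------------------------------------------------------

def isi_statistics(
    spike_record,
    n_neurons: int,
    window_ms: tuple[float, float] | None = None,
    deficit_ms: float = 20.0,
    min_spikes_cv: int = 10,
):
    """Pooled ISI distribution, exponential tail fit and per-neuron CVs.

    The exponential rate is the maximum-likelihood fit to the ISI tail
    beyond ``deficit_ms`` (the refractory-deficit region at the low
    end): for a shifted exponential, rate = 1 / mean(ISI - deficit).
    CV = sd/mean of each neuron's ISIs (neurons with at least
    ``min_spikes_cv`` spikes).
    """
    rec = spike_record
    if window_ms is not None:
        rec = rec.window(*window_ms)
    pooled = []
    cvs = np.full(n_neurons, np.nan)
    for n in range(n_neurons):
        t = rec.for_neuron(n)
        if len(t) >= 2:
            isi = np.diff(np.sort(t))
            pooled.append(isi)
            if len(t) >= min_spikes_cv and isi.mean() > 0:
                cvs[n] = isi.std(ddof=1) / isi.mean()
    if not pooled:
        raise ValueError("no neuron fired twice in the window")
    pooled = np.concatenate(pooled)
    tail = pooled[pooled > deficit_ms]
    rate_hz = 1000.0 / (tail - deficit_ms).mean() if tail.size else np.nan
    return {
        "isis_ms": pooled,
        "tail_rate_hz": float(rate_hz),
        "cv": cvs,
        "median_cv": float(np.nanmedian(cvs)),
    }


# ----------------------------------------------------------------------
# distance / weight / correlation table
# ----------------------------------------------------------------------

def spearman_table(
    spike_record,
    weight_matrix: np.ndarray,
    layout,
    bin_ms: float = 50.0,
    window_ms: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Spearman rank correlations among distance, weight and spike correlation.

    For every connected E->E ordered pair, the pairwise spike
    correlation is the Pearson correlation of binned spike counts
    (50 ms bins over a 50 s window by default); the table reports
    Spearman's rho and p-value among {intersomatic distance, synaptic
    weight, spike correlation} across those pairs.
    """
    rec = spike_record if window_ms is None else spike_record.window(*window_ms)
    t0 = rec.t_ms.min() if len(rec) else 0.0
    t1 = rec.t_ms.max() + bin_ms if len(rec) else bin_ms
    n_exc = weight_matrix.shape[0]
    n_bins = max(int(np.ceil((t1 - t0) / bin_ms)), 1)
    counts = np.zeros((n_exc, n_bins))
    exc_mask = rec.neuron_ids < n_exc
    b = ((rec.t_ms[exc_mask] - t0) / bin_ms).astype(int).clip(0, n_bins - 1)
    np.add.at(counts, (rec.neuron_ids[exc_mask], b), 1)
    # Pearson correlation of binned counts for all pairs at once
    c = counts - counts.mean(axis=1, keepdims=True)
    sd = c.std(axis=1)
    sd[sd == 0] = np.nan
    corr = (c @ c.T) / (n_bins * np.outer(sd, sd))
    i, j = np.nonzero(weight_matrix > 0)
    d = np.sqrt(((layout.exc_positions[i] - layout.exc_positions[j]) ** 2).sum(1))
    vals = {
        "distance": d,
        "weight": weight_matrix[i, j],
        "spike_correlation": corr[i, j],
    }
    ok = np.isfinite(vals["spike_correlation"])
    names = list(vals)
    rows = []
    for a in names:
        for bname in names:
            rho, p = stats.spearmanr(vals[a][ok], vals[bname][ok])
            rows.append({"var_a": a, "var_b": bname, "rho": rho, "p_value": p})
    return pd.DataFrame(rows).pivot(index="var_a", columns="var_b", values=["rho", "p_value"])
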