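# lifsorn

A self-organizing recurrent spiking network (LIF-SORN) of a neocortical
layer-5 slice, together with the analysis suite that quantifies the
non-random wiring it develops.

Local cortical circuits are far from random graphs: reciprocal
(bidirectional) connections and certain triangular motifs are
overrepresented, synaptic efficacies follow a heavy-tailed,
log-normal-like distribution, synaptic lifetimes follow a power law, and
strong synapses fluctuate relatively less than weak ones.  This package
simulates a spatially embedded network of noisy leaky integrate-and-fire
neurons whose recurrent excitatory wiring *grows from nothing* under
five interacting plasticity mechanisms, and shows that these non-random
features arise jointly from self-organization under a simple
distance-dependent topological constraint.

## Model

400 excitatory and 80 inhibitory LIF neurons are scattered uniformly on
a 1000 × 1000 µm sheet.  Every membrane potential follows

    dV/dt = −(V − E_l)/τ + noise,      E_l = −60 mV, τ = 20 ms,

integrated at dt = 0.1 ms with an Ornstein–Uhlenbeck noise term of
stationary standard deviation σ = 5 mV.  A neuron crossing its threshold
V_T spikes and resets (excitatory to −70 mV, below rest, providing
effective refractoriness; inhibitory to −60 mV).  Synapses add their
weight to the target's membrane potential after a type-specific
conduction delay; transmission is modulated by short-term plasticity
(fast depression, slower facilitation; factor u·x with U = 0.04,
τ_d = 500 ms, τ_f = 2000 ms).

All synapses are placed with a Gaussian distance-dependent probability
profile (half-width 200 µm).  E→I, I→E and I→I connections are fixed
(fractions 0.1 / 0.1 / 0.5, weights ±1.5 mV).  The recurrent E→E
population starts **empty** and is shaped by:

* **STDP** — nearest-neighbour exponential pair rule,
  Δw = A₊ e^(−Δt/τ₊) for pre-before-post and −A₋ e^(−|Δt|/τ₋) for
  post-before-pre (A₊ = 15 mV, τ₊ = 15 ms, A₋ = 7.5 mV, τ₋ = 30 ms);
* **Synaptic normalization (SN)** — once per second each neuron's
  incoming E→E weights are rescaled multiplicatively to the target sum
  W_total = CF · w̄ · N_pre = 0.1 · 1.5 mV · 400 = 60 mV;
* **Intrinsic plasticity (IP)** — every step,
  V_T ← V_T + η_IP (N_spikes − h_IP) with η_IP = 0.1 mV and
  h_IP = 3 Hz · 0.1 ms = 3·10⁻⁴, enforcing a 3 Hz target rate;
* **Structural plasticity** — once per second, round(N(μ, μ)) new
  synapses (negative draws → 0) are inserted at 10⁻⁴ mV on
  distance-profile-weighted unconnected pairs, and every synapse whose
  weight fell below 10⁻⁶ mV is pruned.  The growth mean μ is the
  model's one hand-tuned constant, calibrated so that growth balances
  pruning at connection fraction 0.1 (μ = 3100/s here).

The emergent wiring is analyzed with: connection-fraction and
bidirectionality time series (chance level = squared connection
fraction of a density-matched Erdős–Rényi graph), a 16-class triadic
motif census against a reciprocity-matched "modified Erdős–Rényi"
control, log-weight histograms, weight-change dynamics, synaptic
lifetime power-law fits, ISI/CV statistics, and a Spearman table of
distance / weight / spike-correlation.  A three-state Markov model
{unconnected, singly, doubly connected} with closed-form stationary
distribution u = 1/(1+α(1+β)), s = αu, d = αβu (α = p_US/p_SU,
β = p_SD/p_DS) predicts the bidirectional overrepresentation
A = d/p² analytically from transition rates estimated on snapshots.

## Worked example

```python
from lifsorn import ExperimentConfig, build_network
from lifsorn import analysis as an, markov as mk

net = build_network(ExperimentConfig(), seed=101)
res = net.run(500.0, seed=102)          # ~1 minute of wall time

tail = res.per_second.query("t_s > 450")
print("connection fraction ", round(tail.connection_fraction.mean(), 4))
print("bidirectional frac. ", round(tail.bidirectional_fraction.mean(), 4))

lt = an.extract_lifetimes(res.lifetime_log, "stable", 500.0)
slope, _ = an.fit_powerlaw_slope(lt, observation_window_s=150.0)
print("lifetime slope      ", round(slope, 2))

est = mk.estimate_transitions(res.snapshots, (400.0, 500.0))
print("alpha, beta         ", round(est.alpha, 3), round(est.beta, 3))
print("predicted A         ", round(mk.overrepresentation_A(est.alpha, est.beta), 2))
```

prints

```
connection fraction  0.092
bidirectional frac.  0.0202
lifetime slope       1.68
alpha, beta          0.148 0.108
predicted A          2.3
```

i.e. the network holds the selected connection fraction of ≈ 0.1, its
reciprocal pairs sit roughly twice above the Erdős–Rényi chance level,
pruned-synapse lifetimes follow a power law with slope ≈ 5/3, and the
pair Markov model reproduces the measured overrepresentation from
per-second transition rates alone.

A command-line interface wraps the same machinery:

```bash
lifsorn run --seed 0 --trials 1 --duration 500 --out runs/default
lifsorn analyze runs/default
lifsorn report runs/default          # Markov pair-model report
lifsorn ablate no-pruning            # mechanism-removal checks
```

## Layout

| module | contents |
| --- | --- |
| `lifsorn.topology` | sheet layout, Gaussian profile, static wiring, ER and modified-ER nulls |
| `lifsorn.dynamics` | LIF + noise stepping, STP, delayed delivery, the `Network` run loop |
| `lifsorn.plasticity` | STDP, synaptic normalization, intrinsic plasticity, growth/pruning |
| `lifsorn.analysis` | fractions, motif census + controls, weights, lifetimes, ISIs, Spearman table |
| `lifsorn.markov` | three-state pair model: estimation, stationary solution, overrepresentation |
| `lifsorn.experiments` | configs (YAML), trial runner, ablation presets, fixture generators |

See `docs/methods.md` for the modelling choices, numerical conventions
and known limitations.
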