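# Methods

This note records the model as implemented, the conventions behind every
numerical choice, and what the package's tests do and do not establish.

## Network and dynamics

Neurons are leaky integrate-and-fire units with intrinsic membrane
noise.  The membrane equation dV/dt = −(V−E_l)/τ + noise is integrated
with the Euler–Maruyama scheme at dt = 0.1 ms; the noise increment is
σ√(2·dt/τ)·N(0,1), which realizes an Ornstein–Uhlenbeck process *on the
membrane potential itself* with stationary standard deviation σ = 5 mV.
The temporal spectrum of the intended noise is underdetermined (only its
5 mV amplitude is fixed); we place the OU process on V because it gives
the membrane exactly the stated stationary amplitude with the membrane's
own correlation time, and it needs no extra, unconstrained time
constant.  "Variance of the noise is 5 mV" is read as a standard
deviation — the unit is mV, and the parameter table lists σ.

Thresholds start at −50 mV (2σ above rest) and are immediately taken
over by intrinsic plasticity; the starting value only sets the length of
the initial convergence transient (a few seconds).  Refractoriness is
implemented solely through the reset values: the excitatory reset 10 mV
below rest yields an effective refractory period of a few tens of
milliseconds (visible as the low-end deficit of the ISI distribution),
while the inhibitory reset at rest makes that population
faster-refracting.  There is no hard clamp window.

Spike delivery adds the synaptic weight to the target's membrane
potential after the type-specific conduction delay (E→E 1.5 ms, E→I
0.5 ms, I→E and I→I 1.0 ms), implemented as a ring buffer over delay
steps.  Deliveries due in a step are applied after that step's spike
detection, so an input can first trigger a spike on the following step.

Short-term plasticity keeps one (x, u) state per *presynaptic* neuron
(release-site dynamics are axonal, shared across that neuron's outgoing
synapses).  Between spikes the state relaxes continuously (closed-form
exponential, evaluated lazily at spike times); on a spike, x is
depressed with the pre-update u, u is then facilitated, and the
transmitted weight is scaled by the post-update product u·x.  STP is
part of the generic transmitting-synapse model and by default modulates
all four synapse types (`scope="all"`); restricting it to excitatory
axons (`"exc"`) or to the recurrent excitatory population (`"ee"`) is a
configuration choice.  The scope mainly rescales the effective strength
of the fixed pathways; the reported wiring statistics were found to be
robust across the three scopes.

### Per-step and per-second schedule

Within a step: membrane/noise update → threshold/reset → STDP for every
excitatory spike → STP update and delivery scheduling → spike
registration → delivery of due events → IP threshold update.
Simultaneous pre/post spikes pair with the partner's *previous* spike
(spike memory is updated only after all of a step's spikes are
processed), and same-step spikers are processed in ascending neuron id,
which makes runs bit-reproducible.

Once per simulated second: synaptic normalization → structural growth →
pruning → connectivity snapshot.  Normalization therefore acts on the
pre-growth weight mass and pruning sees post-normalization weights; a
synapse inserted at second k is first exposed to STDP during second
k+1, so recorded lifetimes are at least 1 s (the snapshot cadence is
also the lifetime resolution).

The inner loop is a numba kernel; a pure-Python/numpy reference stepper
implements the identical contract and the test suite checks both paths
produce identical spike records and weights on a small network.  All
randomness flows through one `numpy` Generator per run (noise is
pre-drawn per one-second chunk, growth draws follow in sequence), so a
seed fixes the full trajectory.

## Plasticity rules

**STDP.**  Nearest-neighbour exponential pair rule, event-driven: when a
neuron spikes, each of its incoming synapses is potentiated against the
source's most recent spike (Δw = A₊e^(−Δt/τ₊)) and each outgoing
synapse is depressed against the target's most recent spike
(Δw = −A₋e^(−Δt/τ₋)); A₊ = 15 mV, τ₊ = 15 ms, A₋ = 7.5 mV, τ₋ = 30 ms
(the window integrals A₊τ₊ and A₋τ₋ balance exactly).  Weights clip at
zero; a clipped synapse still exists until the next pruning pass and can
be rescued by potentiation in between.  New synapses inherit no spike
history: partners' spikes from before the synapse's creation are
ignored.  An optional per-synapse ceiling `w_max` saturates
potentiation; it is unbounded by default because with normalization
active the incoming-sum constraint dominates, and it is set to the
normalization target in the no-SN ablation, where it becomes the
binding "synaptic maximum" at which weights pile up.

**Synaptic normalization.**  Multiplicative, once per second with rate
η_SN = 1: every neuron's incoming E→E weights are scaled by a common
factor so their sum lands exactly on W_total.  W_total is the product
connection-fraction × mean synapse strength × incoming population size;
for E→E this is 0.1 · 1.5 mV · 400 = 60 mV, taking the 1.5 mV strength
of the fixed pathways as the E→E mean strength (the value is exposed as
`SNConfig.ee_mean_strength`).  E→I, I→E and I→I weights are fixed, so
normalizing them is a no-op and is omitted.  Neurons with zero incoming
sum are skipped.

**Intrinsic plasticity.**  At every step V_T ← V_T + η_IP(N_spikes −
h_IP) with η_IP = 0.1 mV and h_IP = 3 Hz × 0.1 ms = 3·10⁻⁴; at this
cadence N_spikes is the 0/1 spike indicator and the counter reset is
implicit.  IP applies to both populations (thresholds are shared model
parameters); a flag restricts it to excitatory neurons.  A variant draws
per-neuron target rates from a log-normal distribution (mean 3.0 Hz,
sd 1.0 Hz).

**Structural plasticity.**  Growth: once per second, k = max(0,
round(N(μ, μ))) new synapses are placed on currently unconnected ordered
E→E pairs, sampled without replacement with probability proportional to
the Gaussian distance profile (Gumbel top-k), at 10⁻⁴ mV.  Negative
draws insert nothing (≈ 16% of draws, since the sd equals the mean);
draws exceeding the available pairs insert all remaining pairs with a
warning.  Pruning: once per second, after growth, every synapse below
10⁻⁶ mV is removed and its (creation, death) pair appended to the
lifetime log.

The growth mean μ is the model's single hand-tuned constant; its
defining criterion is that growth balances pruning at the target
connection fraction 0.1.  `experiments.calibrate_growth_rate` implements
that calibration (probe runs, proportional rescaling, sd kept equal to
the mean); for this implementation it yields μ ≈ 3100 synapses/s for
the 400+80 network, which is the shipped default.  The balance point is
sensitive to how often weak synapses are driven below threshold —
i.e. to spike-pairing statistics that differ between implementations —
so μ should be re-calibrated, not copied, whenever the dynamics,
network size (the 2000-neuron scale-up) or the IP-target variant change.
With substantially weaker depression (e.g. A₋ halved) no balance exists
at this μ and the graph grows past the target; the lifetime statistics
remain well-defined.

## Topology and null models

Positions are uniform on the sheet (open boundaries, Euclidean distance;
the sheet is a slice, not a torus).  The Gaussian profile's "half-width"
of 200 µm is read as σ; a half-width-at-half-maximum interpretation
(σ = 200/√(2 ln 2) µm) is selectable.  Static wiring draws *exact*
rounded edge counts per type without replacement, with sampling weights
proportional to the profile, so connection fractions are reproducible
rather than Bernoulli-fluctuating.

Two null models support the analysis: an Erdős–Rényi digraph matched in
nodes and edges (chance level for reciprocity: squared density,
because the squaring operation is convex, any *inhomogeneous* profile
lifts the reciprocal fraction above it — verified as a property test),
and the modified control matched separately in unidirectional-edge and
reciprocal-pair counts with independent placement, which corrects the
motif census for the reciprocity excess.  The per-class expectation
under this control is also available in closed form (multivariate
hypergeometric over pair states), and the Monte-Carlo control means are
tested against it.

## Analysis conventions

* Connection fraction: directed edges / N(N−1) ordered pairs.
  Bidirectional fraction: 2 × reciprocal pairs / N(N−1), so its chance
  level is exactly the squared connection fraction.
* Triad census: the 16 directed isomorphism classes, ordered as
  documented in `analysis.MOTIF_ORDER` (null triad first, single
  reciprocal pair second, fully reciprocal triangle last); counts always
  sum to C(N,3).  The "closed-loop" family is the seven classes whose
  three pairs are all connected; because single-trial per-class ratios
  are noisy, the family-level check pools observed and expected counts.
  Ratios can alternatively be averaged per trial or pooled across
  trials; both reducers are provided by composing the census over runs.
* Lifetime power law: log-spaced histogram of pruned-synapse lifetimes;
  least-squares line on log₁₀(density) vs log₁₀(lifetime) over bins
  below the drop-off cut, defaulting to 10% of the observation window
  (the right-censoring artifact region).  Bins with fewer than 5 entries
  are excluded (keeping 1-count bins while dropping empty ones biases
  the tail shallow).  Synapses alive at run end never enter the log, so
  the sample is uncensored by construction.  Phase windows: growth =
  death before 150 s; stable = creation after 350 s (500 s schedule) or
  after 250 s for shortened ≥300 s runs.  The estimator recovers known
  exponents from inverse-CDF synthetic samples within ±0.1 at n = 10⁴.
* ISI statistics: the exponential tail rate is the maximum-likelihood
  fit of a shifted exponential beyond the 20 ms refractory-deficit
  region; CV is per-neuron sd/mean of ISIs.
* Spearman table: pairwise spike correlation is the Pearson correlation
  of 50 ms binned counts over a 50 s window (the pairwise estimator is
  otherwise unconstrained); Spearman's ρ and p are then computed among
  distance, weight and spike correlation over connected E→E pairs.
* Markov pair model: pair states are sampled at the 1 s snapshot
  cadence (the schedule of structural events), transitions estimated by
  maximum likelihood p_XY = #(X→Y)/#(intervals starting in X) over the
  final 100 s.  Direct U↔D jumps violate the model's single-event
  assumption; they are excluded from numerator and denominator, tallied,
  and warned about above 1% of transitions.  Pairs never connected
  still occupy U and inform p_US.

## Scope of the tests

The suite validates unit-level exactness against hand-derived values,
the stepping kernel against an independent reference implementation,
the census against a brute-force classifier, the Markov solution against
power iteration, and estimator calibration against synthetic data with
known parameters.  End-to-end tests run the full model (500 s default
schedule; shortened, scaled-down windows for variants) and check the
emergent statistics — stable connection fraction, reciprocity above
chance, 3 Hz homeostasis, power-law lifetimes and their shift with the
depression/potentiation balance, closed-loop motif elevation, and the
Markov model's prediction of the measured overrepresentation.

Synthetic fixtures emulate spike trains (Poisson/periodic), power-law
lifetimes and hand-built snapshot series; they do not emulate real
recordings, so passing tests demonstrate internal consistency and the
model's claimed self-organization, not agreement with any particular
experimental dataset.

## Known limitations

* The stable phase has faster synaptic turnover than the growth-rate
  calibration criterion alone can fix: with all printed constants and
  μ calibrated to connection fraction 0.1, the reciprocal fraction and
  its factor over chance settle near the value implied by the
  distance-profile insertion bias (factor ≈ 2.1–2.4), somewhat above
  the 1.8 regime reported for slower-churning realizations of the same
  mechanism set.
* Lifetime-slope estimates on 1 s-resolution data depend visibly on the
  binning convention; the shipped convention is fixed and documented
  above, and shifts in the expected direction (steeper with stronger
  depression), but the absolute slope under doubled depression falls
  short of 5/2 (~1.9 under this estimator).
* Connection-fraction trajectories fluctuate by ±0.02 within a run and
  across seeds; single-trial statistics inherit that spread.
* No conductance-based synapses, spike-rate adaptation, structured
  external input, multiple synapses per ordered pair, or 3D geometry;
  firing-rate distributions are unimodal by construction (IP), unless
  the log-normal-target variant is used.
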