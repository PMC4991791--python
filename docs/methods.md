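# Methods

This document specifies the model, the network-construction
definitions, the statistics, the synthetic-data generators, and the
numerical choices implemented in `recruitnet`, together with known
limitations.

## Network model

### Populations and connectivity

The model is a recurrent network of 1000 excitatory and 200 inhibitory
neurons plus a pool of 50 external Poisson input units. Every ordered
pair of neurons is connected independently with a probability that
depends on the classes of the two cells. Probabilities are
parameterized as *target ← source*:

| connection        | probability |
|-------------------|-------------|
| E ← E             | 0.20        |
| E ← I             | 0.35        |
| I ← E             | 0.25        |
| I ← I             | 0.30        |
| E ← input unit    | 0.10        |

Synaptic weights are drawn from a lognormal distribution with location
−0.64 and scale 0.51 (mean 0.60, variance 0.11 in units of the leak
conductance), capturing the heavy right tail of cortical synaptic
efficacies: most synapses are weak, a few are strong. Inhibitory-onto-
excitatory weights carry an extra ×1.5 factor. A global `weight_scale`
multiplier supports the double-strength contrast arm (×2 on every
weight, same topology). Self-connections are excluded. Input-pool
projections are redrawn at the start of every epoch; recurrent
connectivity is fixed for the lifetime of a network instance.

### Membrane dynamics

Each neuron is a conductance-based leaky integrate-and-fire unit.
With conductances expressed as multiples of the leak conductance:

    tau_m dV/dt = (E_leak − V) + g_e (E_e − V) + g_i (E_i − V)
                  + g_t (E_t − V)

| parameter | value | parameter | value |
|-----------|-------|-----------|-------|
| tau_m     | 20 ms | E_leak    | −65 mV |
| tau_e     | 10 ms | E_e = E_t | 0 mV  |
| tau_i     | 5 ms  | E_i       | −90 mV |
| V_thresh  | −48 mV| V_reset   | −70 mV |
| refractory| 1 ms  | g_t       | 0.20 (= g_leak) |

Synaptic conductances decay exponentially and are incremented by the
presynaptic weight one integration step after each presynaptic spike.
The tonic conductance `g_t` places the isolated single-neuron
equilibrium at (E_leak + g_t·E_t)/(1 + g_t) = −32.5 mV, above
threshold: every neuron fires tonically in isolation, and the sparse
network regime is therefore *inhibition-stabilized*. This has a
consequence worth stating plainly: the sparse asynchronous state
coexists with a saturated runaway attractor, and a synchronized cold
start (all cells at the same potential) ignites the runaway state.
Trials therefore start desynchronized near the sparse operating point —
excitatory potentials uniform on [E_leak − 5, E_leak + 10] mV,
inhibitory potentials uniform on [−60 mV, V_thresh] (inhibitory cells
sit near threshold in the stationary state) — with synaptic
conductances at zero.

Small networks are harder to stabilize: at the full-scale 5:1 E:I ratio
a few-hundred-neuron network falls into the runaway state in every
trial, because each cell samples far fewer independent inhibitory
inputs. Test fixtures therefore use a relatively larger inhibitory
population; the scientific configuration is always full scale.

### Trial protocol

A standard trial is 50 ms of Poisson input-pool drive (15 Hz per unit)
followed by a 100 ms recording window with no external input. An epoch
is 100 trials sharing one set of input projections; a session is 5
epochs. A long free-evolution protocol (50 ms input, 950 ms recorded,
100 trials) is used for interspike-interval statistics, where 100 ms
windows would truncate the intervals of ~1 Hz neurons.

### Numerical integration

Integration uses a step of 0.1 ms: conductance decay is applied exactly
(multiplication by `exp(−dt/tau)`), the voltage update is forward
Euler. Spike times are assigned to the end of the step in which
threshold was crossed. Upward voltage overshoot is truncated by the
threshold/reset mechanism and is therefore harmless; the downward side
has no clamp, so the integrator tracks per-step voltage extrema and
raises an error if any potential dips more than 5 mV below E_i at any
step, or if any end-of-trial potential lies outside [E_i − 1 mV,
E_e + 1 mV] or is non-finite. At the default step size and
conductances, no such excursion occurs.

## From spiking to networks

### Tri-state activity and the functional network

Each 1 ms bin of each neuron is labeled firing (spiked in that bin),
active (spiked within the preceding lag interval T, default 25 ms), or
inactive. Activity never crosses trial boundaries. The functional
network has edge weight

    E_ij = P(neuron j fires | neuron i active)

estimated as the fraction of i-active bins in which j fired, pooled
over all trials of a session. Weights are conditional probabilities in
[0, 1]; the diagonal is zero.

### Recruitment and active networks

The *recruitment network* is the functional network masked by the
synaptic graph: an edge survives only where a synapse i→j exists. It
estimates where activity actually propagated through monosynaptic
connections. The *active subnetwork* is the synaptic graph restricted
to neurons that fired at least once (rows and columns of silent
neurons zeroed; node count kept so densities are comparable).

## Graph statistics

### Clustering, paths, and small-world scores

Weighted local clustering uses the geometric-mean (cube-root) form on
the symmetrized weight matrix normalized by its maximum, which is
invariant to global weight rescaling. Binary clustering is the usual
triangle/triple ratio.

Characteristic path length is the mean *hop count* over all reachable
ordered pairs (unreachable pairs are dropped and their fraction
reported). Hop counts — rather than inverse-weight Dijkstra costs —
are the implemented convention for small-world scores: on graphs of
this density (≥ 5%) almost every pair is within two hops, so the hop
metric is stable across null draws, while inverse-weight costs would
make the "path" term depend strongly on the weight distribution and
dominate the quotient. Weighted Dijkstra paths remain available as an
option.

Small-world scores compare the observed graph against density-matched
Erdős–Rényi nulls that preserve the exact weight multiset (observed
weights shuffled onto a uniformly random edge set of the same size):

    clustering ratio  = C_obs / mean(C_null)
    path ratio        = L_obs / mean(L_null)
    small-world ratio = clustering ratio / path ratio

By construction an ER graph scores ≈ 1 on all three (verified in the
tests as a self-calibration).

### Directed triangle census

Each node's directed triangles are split into four classes by edge
orientation: **fan-in** (two in-edges whose sources are connected),
**fan-out** (two out-edges whose targets are connected), **middleman**
(an in-edge and an out-edge whose endpoints are connected), and
**cycle**. Counts are computed with matrix products on the (optionally
weight-scaled) adjacency and normalized by the number of potential
triangles of each class given the node's degrees. The matrix
implementation is validated against an independent brute-force
enumeration, exhaustively over *all* simple digraphs up to 4 nodes
(4096 graphs) and on random 7- and 20-node graphs; exhaustive
enumeration to 7 nodes (2^42 graphs) is computationally impossible, so
random sampling covers the larger orders. Totals obey the identities:
every non-cyclic directed triangle contributes exactly one fan-in, one
fan-out, and one middleman count, and cycle totals are divisible by 3.

Motif comparisons across recruitment networks are conducted on binary
topologies. Recruitment edge weights are conditional firing
probabilities, which grow with the postsynaptic neuron's rate; a
weighted census therefore entangles motif structure with the rate
distribution. Concretely, a node's weighted fan-in coefficient is
large only if that node itself fires often (all three triangle edges
terminate on or near it), whereas its weighted fan-out coefficient
borrows the rates of its targets — in our simulations this rate
gradient is strong enough to invert the motif ordering relative to
the binary census. Scoring the recruited edge pattern alone isolates
the topological question: which triangle arrangements does
propagating activity preferentially traverse.

### Clustering propensity

`1 − ΔC` locates an observed clustering value on the segment between a
density-matched ER null (score 0) and a density-matched ring lattice
(score 1): `ΔC = (C_latt − C_obs) / (C_latt − C_rand)`, clipped to
[0, 1]. For weighted graphs the top 20% of edges by weight are kept
before scoring.

## Triplet timing

*Pure* motif instances are triplets with exactly the defining edge set
and no other edges among the three neurons: fan-in = {a→t, b→t, a→b};
simple convergence = {a→t, b→t}. A *coincident epoch* is a
postsynaptic spike whose centered 50 ms window [−25, +25) contains at
least one spike from each presynaptic neuron, within one trial. Epoch
rates are normalized per triplet per trial. Presynaptic timing uses
the spike of each presynaptic neuron nearest the postsynaptic spike;
the interval `t_b − t_a` is signed with `a` the presynaptic neuron that
projects onto `b`, so an asymmetric interval histogram indicates that
firing order aligns with the direction of the a→b synapse.

## Calcium-imaging arm

### Event detection

Per cell, the signal-to-noise ratio is the 99th percentile over the
mean of the raw fluorescence trace; cells at or below the cutoff
(default 1.55) are dropped. Retained traces are z-scored; contiguous
runs above 2 σ are extended backward to the most recent crossing of the
trace median and marked as event epochs. Event epochs are invariant to
affine rescaling of a retained trace; the SNR screen itself is
gain-invariant but depends on the baseline offset, as any
percentile-over-mean ratio must.

### Functional-map inference

Directed weights are inferred from single-frame-lagged co-events by an
iterative explaining-away update: each event of a target cell is
treated as generated by exactly one cell active in the preceding frame,
credit is split among candidate parents in proportion to current
weights, and each weight is re-estimated as credited events per parent
opportunity. Iterating to convergence suppresses edges whose
co-activation is explained by a stronger competing parent. The final
map averages five runs from random positive initializations scaled by
the raw co-activation counts (structurally impossible edges start and
stay at zero). The procedure is validated by planted-structure
recovery — precision of supra-threshold edges against a planted graph
exceeds five times the planted density — and by exact hand cases
(a deterministic driver pair is recovered with weight 1 in the correct
direction and 0 in the reverse).

Thresholded maps (edges above a weight percentile) are characterized by
the directed census under bootstrap false-positive redaction: a fixed
fraction (default 30%) of kept edges is removed uniformly at random and
the census recomputed, yielding confidence intervals robust to
spurious-edge contamination.

## Synthetic generators

### Rate-matched Poisson surrogate

For every (neuron, trial, 100 ms bin), surrogate spike counts are drawn
Poisson with mean equal to the observed count, times uniform within the
bin. Per-neuron, per-trial rate profiles are preserved in expectation;
all cross-neuron dependence is destroyed. The surrogate is the negative
control for the inference arm: clustering inferred from surrogate
events collapses relative to model events.

### Calcium generator

Fluorescence is generated as baseline 1.0 plus, per planted event
onset, a peak-normalized difference-of-exponentials transient (50 ms
rise, 600 ms decay) scaled by a per-cell lognormal amplitude
(location 0, scale 0.75), plus Gaussian noise (σ = 0.06). Onsets are
sparse Bernoulli processes (0.10 events/s) modulated by shared
population bursts (0.20 bursts/s, ×8 rate lift) and by a planted
directed ER graph (density 0.03): an edge i→j lifts j's onset
probability by 0.35 one frame after an i onset. Cells receive uniform
positions in a 300 µm field; an optional distance kernel thins planted
edges with an exponential length scale.

Generator realism is tuned to the detection pipeline it feeds, not to
any analysis outcome: the amplitude spread is chosen so that the
default SNR screen retains ≈ 43% of cells (dim cells genuinely
indistinguishable from noise), matching the strictness that a
conservative experimental screen exhibits. Ground truth (onset raster
and planted graph) is returned alongside the recording so detection and
inference can be scored.

## Limitations

- **Interspike-interval irregularity.** Under the long free-evolution
  protocol the model's pooled-per-neuron CV² of interspike intervals is
  ≈ 3, not ≈ 0.8: the inhibition-stabilized tonic-drive regime produces
  occasional long gaps interleaved with short bursts, and pooling
  across trials mixes slow rate differences into the interval variance.
  Alternative estimators (per-trial local CV2, median across neurons)
  were examined and recorded; none was adopted post hoc to force
  agreement. The statistic is reported as computed.
- **Participation.** ≈ 85–88% of excitatory neurons fire within one
  epoch in this implementation, higher than the ≈ 64% the published
  regime exhibits. The silent minority matters: silent nodes deflate
  null clustering and inflate null path lengths for the active and
  recruitment graphs, so downstream normalized ratios (recruitment
  small-world and path ratios, active-subnetwork clustering) shift
  with participation. Differences in these ratios track this single
  regime discrepancy, not the graph machinery, which self-calibrates
  to 1.0 on ER graphs.
- **Path-length convention.** Published small-world values for these
  network families are consistent with binary hop-count paths (the
  functional path ratio is 1.0 with near-zero variance, which only a
  discrete hop metric produces at these densities); the implementation
  follows that convention by default. Inverse-weight Dijkstra paths
  are available but yield a different decomposition of the small-world
  quotient.
- **Exhaustive census validation stops at 4 nodes.** All 2^12 simple
  digraphs on 4 nodes are enumerated; 7 nodes would require 2^42
  graphs. Random graphs at orders 7 and 20 cover the gap.
- **The explaining-away inference is a heuristic.** It has no
  uniqueness guarantee; multi-initialization averaging and
  planted-recovery validation bound its behavior empirically, not
  analytically.
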