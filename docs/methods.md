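# Methods

This note documents the model, the defaults, the numerical choices, and
the known limitations of `evoplast`.

## Plastic neuron model

Networks are synchronous and recurrent: all activations at step t+1 are
computed from activations at step t. Neuron i computes

    o_i(t+1) = phi( sum_{j in S_i} s_ij w_ij o_j(t) + b_i ),
    phi(x) = 1 / (1 + exp(-lambda x)),

where S_i are its inputs from *standard* neurons. Inputs from *modulatory*
neurons are excluded from the drive and instead summed into the
modulatory signal m_i = sum_{j in M_i} s_ij w_ij o_j(t). After a step,
every plastic weight is updated by the neuromodulated Hebbian rule

    w_ij <- clamp( w_ij + eta * phi_m(m_i) * o_i(t+1) * o_j(t+1),
                   w_min, w_max ),

with phi_m = tanh. A connection is **plastic** iff its source is standard
and its target receives at least one modulatory connection; with
phi_m(0) = 0 every other weight is exactly frozen, and randomizing "the
modulated weights" at the start of a lifetime can never destroy evolved
fixed wiring. Connections leaving modulatory neurons are gates, never
plastic themselves.

Conventions worth stating precisely:

- **Input clamping.** Input neurons relay their clamped values without a
  sigmoid, and a new input vector is visible from the first step after it
  is set (a feed-forward path of depth d needs exactly d steps).
- **Update timing.** Plasticity may be applied after every simulation
  step, in both the stimulus and the reward phase of an episode. The
  modulatory sums entering the update are the ones recorded by the step
  that produced the current activations.
- **Weights.** Magnitude in [w_min, w_max] = [0, 2] plus a separate sign
  in {-1, +1}; plasticity modifies the magnitude only. There are no
  negative magnitudes; inhibition is the sign.

Defaults: eta = 0.1, lambda = 5, w_min = 0, w_max = 2, biases of evolved
genotypes bounded to [-2, 2]. These are package defaults chosen on the
scale of the unit weight range; all are configurable through
`PlasticityParams` and the encoding constructors. Hand-built fixtures may
use biases outside the genotype bounds (they are not genotypes).

## The operant-conditioning task

Stimuli and actions are indexed 0..3. The network sees 10 input lines:
4 one-hot stimulus lines, a positive- and a negative-reward line, and 4
one-hot feedback lines carrying a copy of the softmax-chosen action. (A
9-line variant with one signed reward line exists for the strict 9-input
substrate; the two-line layout is the default everywhere so that all three
encodings are comparable.)

One **lifetime** on one association set: plastic magnitudes are redrawn
uniformly from [0, 2], activations zeroed, then 90 episodes run. Each
episode presents the 4 associations in fixed stimulus order; per
association: (a) clamp the stimulus-only input and simulate 5 steps with
learning, (b) softmax-select an action from the 4 output activations
(tau = 0.1), (c) clamp stimulus + reward + feedback — the stimulus stays
on during the reward phase — and simulate 5 further steps with learning.
On the last episode each association scores 1 if the sampled action is
correct, and the 4 pre-softmax outputs are appended to the behavior
descriptor (length 16 per set).

Two granularities are computed: the association-level average (used as the
evolutionary fitness, since it gives a finer gradient) and the set-level
"fully learned" flags. The **GLA score** is the set-level success rate over
all 256 sets, averaged over `n_repeats` = 5 seeded lifetimes per set by
default to tame softmax sampling noise; the association-level average is
reported alongside.

Calibration anchors (recomputed by `scripts/acceptance.py` and the test
suite): an oracle agent scores fitness = GLA = 1; a network with all-zero
weights and biases has equal outputs, so its association-level fitness sits
at chance 0.25 and its set-level GLA at (1/4)^4 ~ 0.0039.

## Encodings

**Direct.** Nodes carry (bias, kind); edges carry (magnitude, sign).
Mutation applies, in fixed order and each with its own probability:
add-connection, delete-connection, move one endpoint, add-node by
splitting a connection (both halves keep the split edge's genes),
delete-hidden-node, then per-element value mutation. Real genes use Deb's
polynomial mutation (eta_m = 15); boolean genes flip; categorical genes
redraw. Defaults: p_add/del/move-connection = 0.1, p_add/del-neuron =
0.05, p_weight = p_param = 0.1 per element — values in the usual range
for this operator set, configurable via `MutationRates`. Generation-0
genotypes are feed-forward input-to-output bipartite graphs with random
weights and no hidden nodes, hence no modulatory neurons and no plastic
weights. Self-loops on hidden/output nodes are allowed (the networks are
recurrent anyway). Crossover is not used.

**Map-based.** The genotype is the same kind of graph, but every label is
a real gene in [0, 1]: nodes decode to (is_map, inhibitory, modulatory,
bias), edges to (weight, inhibitory, connection type). Booleans threshold
at 0.5; the weight maps affinely onto [0, w_max]; the bias onto [-2, 2].
Development expands each map node into `map_size` = 4 identical neurons
(matching the 4 stimuli/actions; a map-sized group is also what the
regularity analysis groups by). One-to-one edges connect k-th neuron to
k-th neuron; one-to-all edges form the full bipartite fan with one shared
weight. A one-to-one edge touching a singleton degenerates to one-to-all;
one-to-one between maps of unequal sizes is a development error surfaced
as minimal fitness (it cannot occur at uniform map size, but the guard
stays). A connection develops inhibitory if either its edge flag or its
source node's flag says so (an inhibitory map makes its outgoing
connections inhibitory). The I/O roster is fixed: stimulus map, two reward
singletons, feedback map, output map. Hidden maps may be simultaneously
inhibitory and modulatory; the flags are independent.

Regularity guarantee: a hidden map whose incident edges are all one-to-all
("free") develops into `map_size` interchangeable neurons, so the
automorphism count of the developed network is a multiple of map_size! —
the property `MapEncoding.has_free_hidden_map` detects (it additionally
requires the map to survive pruning, since pruned neurons do not count).

**HNN (minimal HyperNEAT).** Two CPPNs — feed-forward graphs of {sine,
sigmoid, Gaussian, linear} function nodes evolved with the direct-encoding
operators, cycles rejected at development — are queried over a fixed 3D
substrate (inputs at z = -1, hidden at z = 0, outputs at z = +1, x evenly
and exactly symmetrically spaced within semantic groups). The
connection-centred CPPN (6 coordinates + constant bias input 1.0) returns
a link-expression output, thresholded at 0.5 to create the connection, and
a signed weight whose magnitude is |out| clipped to 1 and scaled to
[0, w_max]. The node-centred CPPN returns the bias (clipped to [-1, 1],
scaled by 2) and the kind output: a hidden neuron is modulatory iff the
kind output is below 0.4. Connectivity is queried for input->hidden,
input->output, hidden->hidden (self and recurrent included) and
hidden->output pairs. The substrate defaults to 10 inputs so that HNN
networks are drop-in comparable with the other encodings; a strict 9-input
variant (single signed reward line) is available.

## Regularity measurement

The network is pruned to neurons lying on some directed input-to-output
path (fixtures without I/O neurons are measured as-is), then transformed:
neurons become vertices colored "m" (modulatory) or "n" (anything else);
each connection becomes a two-edge path through an auxiliary vertex
colored by its signed weight's bin — large/small x negative/positive,
boundary |w| >= w_max/2, with 0 binned as small positive. Biases are
ignored. Input and output neurons carry only the m/n colors, so same-role
I/O neurons may be permuted; a stricter role-colored mode exists but is
off by default. Plastic weights are set to the midpoint (w_min + w_max)/2
before binning so the measure is deterministic and independent of learning
history; a "snapshot" mode bins the current magnitudes instead.

Counting is exact at any scale: BLISS (via python-igraph) returns the
generators of the color-preserving automorphism group and sympy's
permutation-group machinery (Schreier–Sims) returns the group order, so
astronomically large symmetry groups are counted without enumeration. Two
independent oracles cross-check it in the tests: exhaustive enumeration of
color-class-respecting permutations (<= 10 vertices, optionally with edge
labels checked directly instead of bin vertices) and igraph's VF2 counter.

## Evolutionary algorithm

NSGA-II, maximizing (fitness, behavioral novelty). Novelty is the mean
Euclidean distance from an individual's behavior descriptor to its k = 15
nearest neighbors in the current pool plus an archive; if fewer than k
others exist the mean runs over what is available. One uniformly chosen
offspring descriptor is appended to the unbounded archive per generation —
the simplest policy consistent with ranking against "archive plus current
population". Variation is mutation-only; parents are chosen by binary
tournament on (rank, crowding distance), ties broken by crowding and then
at random; survivors are the best `population_size` of the combined
parent+offspring pool, so the best fitness never decreases. Each
individual is evaluated exactly once, with an RNG derived from (run seed,
generation, index): runs are exactly reproducible, and a re-run of a
series regenerates identical CSVs. Runs stop at perfect fitness on the
evolutionary training set or at the generation cap; the reported champion
is the best-fitness individual, novelty discarded. Development failures
(CPPN cycles, malformed map expansions) receive fitness 0 and a zero
descriptor rather than crashing the run.

## Scale presets and performance

The published-scale setup (population 400, up to 4000 generations,
training-set sizes 1–7, many replicates) is cluster work. The package
ships two presets: `full` (400 x 4000, sizes 1–7, 20 replicates per cell)
and `desk` (100 x 500, sizes 1–3, 5 replicates), and the test suite and
acceptance script run still smaller problem sizes (populations 16–100,
15–150 generations) chosen so the whole suite completes in minutes on one
core. The qualitative regularity comparison between encodings at these
tiny scales is logged as advisory rather than asserted: single-replicate
medians of a heavy-tailed count are not a stable statistic.

The per-lifetime simulation (3600 network updates) is JIT-compiled with
numba; a pure-numpy path over the public network operations is kept as the
reference implementation, and the two are asserted equal on identical
random streams in the tests. All stochastic procedures consume pre-drawn
uniforms so the two paths see the same randomness.

## The hand-wired learner

`fixtures.hand_learner()` validates the whole pipeline without evolution:
a plastic stimulus-to-relay fan (the association memory), relays driving
the outputs through fixed strong connections, and per-action modulatory
gates that implement "feedback j AND reward" (positive gate strengthens,
negative gate weakens relay j's active stimulus weight). With the default
task parameters it fully learns roughly half of all 256 association sets
and answers ~85% of associations correctly — more than two orders of
magnitude above the set-level chance of 0.0039.

It is deliberately not perfect. In a synchronous network the first step
after a new stimulus is clamped still carries the previous association's
gate activations, so one synchronous step's worth of each reward's
plastic update leaks onto the next stimulus's weights; together with
softmax sampling at test time this caps its set-level score around 0.5.
The leak is a property of the model semantics ("weight changes can occur
at any time"), not of the implementation; evolved solutions face it too
and must be robust to it.

## What the synthetic conditions do and do not show

All inputs are generated: association sets are enumerable, training sets
are random draws, initial genotypes are random. Passing tests show that
the model, encodings, regularity measure and optimizer behave exactly as
specified under these conditions; they do not show that the published
full-scale distributions (GLA medians per encoding and training-set size,
fractions of regular champions) are reproduced, which would require
hundreds of multi-hour runs. The series runner exists precisely so that a
user with the compute budget can launch that grid with `--preset full`.

## Known limitations

- Continuous-time, spiking dynamics, weight decay and heterosynaptic
  rules are out of scope.
- The novelty archive policy and k are package choices (see above);
  results at tiny scale are insensitive to them, but full-scale dynamics
  may not be.
- The automorphism count of a *pruned* network is the regularity measure;
  counting before pruning would let disconnected duplicated structure
  inflate the score.
- `gla_score` is a stochastic estimate; with the default 5 repeats its
  per-network standard error is about 0.01–0.02 for mid-range scores.
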