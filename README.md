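# evoplast

Evolving plastic artificial neural networks under developmental encodings,
and measuring how a network's structural **regularity** relates to its
**general learning abilities**.

## The problem

A plastic neural network can change its synaptic weights during its
"lifetime", which lets a single evolved architecture learn many different
tasks. The catch is generalization: a network evolved to learn a handful of
reward contingencies often fails on contingencies it never saw during
evolution. Developmental (generative) genotype-to-network mappings are
biased towards *regular* architectures — repeated modules, symmetries —
and that bias plausibly produces networks that apply the same learning
rule to whole groups of inputs rather than overfitting the evolved cases.

`evoplast` is a complete experimental system for studying this question in
a simulated operant-conditioning ("Skinner box") task:

- an agent sees one of 4 stimuli (lights) and must pick one of 4 actions
  (levers); an **association set** assigns the correct action to every
  stimulus, and there are 4^4 = 256 possible sets (the *global training
  set* G);
- during one lifetime on one set the agent gets 90 learning episodes with
  immediate positive/negative reward and a copy of its own chosen action
  fed back to its inputs;
- evolution only ever sees a small random subset E of G (1–7 sets); the
  **General Learning Abilities (GLA) score** of a champion is the fraction
  of all 256 sets it can still learn.

## The model

**Plastic neurons.** Neurons are *standard* or *modulatory*. With
o_j the presynaptic outputs, the activation of neuron i is

    o_i = phi( sum_{j in standard inputs} s_ij * w_ij * o_j + b_i ),
    phi(x) = 1 / (1 + exp(-lambda * x)),

while modulatory inputs accumulate separately into m_i = sum_{j in
modulatory inputs} s_ij * w_ij * o_j. Every *plastic* weight (standard
source, modulated target) follows a neuromodulated Hebbian rule

    w_ij  <-  clamp( w_ij + eta * tanh(m_i) * o_i * o_j , w_min, w_max ),

so weight change happens only where modulatory neurons gate it. Weights
are magnitudes in [0, 2] with a separate excitatory/inhibitory sign.
Actions are drawn from a softmax over the 4 output activations,
p_k = exp(o_k / tau) / sum_l exp(o_l / tau).

**Three encodings** map genotypes to networks:

- `direct` — the evolved graph *is* the network (7 mutation operators,
  no crossover);
- `map` — a labeled graph of *neural maps* (groups of identical neurons)
  with one-to-one / one-to-all connection schemes, expanded at development
  time: strongly biased towards regular networks;
- `hnn` — a minimal HyperNEAT: two CPPNs queried over a fixed 3D substrate
  decide connectivity (via a thresholded link-expression output), weights,
  biases and neuron kinds.

**Evolution** is NSGA-II over two objectives — task fitness and
behavioral novelty (mean distance to the k nearest behavior descriptors in
population + archive) — with mutation-only variation and mu+lambda
survivor selection.

**Regularity** is the exact number of automorphisms of the developed
network, computed on a vertex-colored digraph (neurons colored
modulatory/other, each connection replaced by a path through a vertex
colored by its weight bin; biases ignored). Counting uses BLISS group
generators (python-igraph) plus a Schreier–Sims group order (sympy), with
a brute-force enumerator as independent oracle.

## Worked example

```python
import numpy as np
from evoplast import *
from evoplast.fixtures import hand_learner

gs = enumerate_global_set(4, 4)              # the 256 association sets
net = hand_learner()                          # hand-wired plastic learner

res = evaluate_fitness(net, gs[:5], TaskConfig(), np.random.default_rng(0))
print(f"fitness on 5 sets: {res.fitness:.3f}  fully learned: {res.set_success.tolist()}")

gla = gla_score(net, gs, TaskConfig(), np.random.default_rng(0), n_repeats=3)
print(f"GLA: {gla.set_level:.3f} (association level {gla.association_level:.3f})")
print("automorphisms:", network_automorphisms(net))
```

prints

```
fitness on 5 sets: 0.900  fully learned: [True, True, True, False, False]
GLA: 0.482 (association level 0.843)
automorphisms: 576
```

i.e. the hand-wired learner answers 90% of associations correctly on the
five tested sets and fully learns three of them; across all 256 sets it
fully learns 48% (chance level is 1/256 ~ 0.004), and its four identical
action channels give it 576 structural symmetries.

An evolutionary run is one call:

```python
from evoplast import run_experiment
rec = run_experiment("map", n_train=1, seed=3, population_size=50, max_generations=100)
print(rec.champion_fitness, rec.converged, rec.generations, rec.champion_automorphisms)
# 1.0 True 11 967680
```

The map-based encoding reaches perfect fitness on its single training set
within 11 generations and its champion is extremely regular (967,680
automorphisms) — though with |E| = 1 it generalizes poorly, exactly the
regime the GLA score is designed to expose.

The same operations are available from a shell:

```bash
evoplast evolve --encoding map --n-train 2 --seed 1 --preset desk --out champions/
evoplast evaluate --network champions/map_n2_s1.json --set-size 7 --gla
evoplast regularity --network champions/map_n2_s1.json
evoplast series --preset desk --out results/
```

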