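"""Operant-conditioning ("Skinner box") task.

An agent faces ``n_stimuli`` lights and ``n_actions`` levers.  An
*association set* assigns one correct action to every stimulus; the *global
training set* is all ``n_actions ** n_stimuli`` such sets (256 for the 4x4
task).  During one lifetime on one set the network starts with randomized
plastic weights and runs 90 learning episodes; each episode presents the
four stimuli in fixed order, lets the network act through a softmax over
its four outputs, and then feeds back the chosen action together with a
positive or negative reward while the network keeps adapting.  Fitness is
the fraction of associations answered correctly on the last episode,
averaged over the evolutionary training set; the General Learning Abilities
(GLA) score is the fraction of all 256 sets that are fully learned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._kernel import (
    REWARD_SIGNED_LINE,
    REWARD_TWO_LINES,
    CompiledNetwork,
    run_lifetime,
)
from .network import PlasticNetwork


@dataclass(frozen=True)
class Association:
    """One stimulus -> action pair that yields the positive reward."""

    stimulus: int
    action: int


@dataclass(frozen=True)
class AssociationSet:
    """Exactly one correct action per stimulus (actions may repeat)."""

    actions: Tuple[int, ...]

    def __post_init__(self):
        if any(a < 0 for a in self.actions):
            raise ValueError("negative action index")

    def __len__(self) -> int:
        return len(self.actions)

    def __iter__(self):
        return (Association(s, a) for s, a in enumerate(self.actions))

    def __getitem__(self, stimulus: int) -> int:
        return self.actions[stimulus]

    def to_text(self) -> str:
        return ",".join(f"{s}→{a}" for s, a in enumerate(self.actions))

    @classmethod
    def from_text(cls, text: str) -> "AssociationSet":
        pairs = {}
        for item in text.strip().split(","):
            item = item.replace("->", "→")
            s, a = item.split("→")
            pairs[int(s)] = int(a)
        return cls(tuple(pairs[s] for s in sorted(pairs)))


def enumerate_global_set(n_inputs: int, n_outputs: int) -> List[AssociationSet]:
    """All association sets, lexicographically ordered, duplicate free."""
    if n_inputs < 1 or n_outputs < 1:
        raise ValueError("n_inputs and n_outputs must be positive")
    return [
        AssociationSet(actions)
        for actions in itertools.product(range(n_outputs), repeat=n_inputs)
    ]


def sample_training_set(
    global_set: Sequence[AssociationSet], n_train: int, rng: np.random.Generator
) -> List[AssociationSet]:
    """Draw ``n_train`` distinct sets; fixed for a whole evolutionary run."""
    if not 1 <= n_train <= len(global_set):
        raise ValueError(f"n_train must be in [1, {len(global_set)}]")
    idx = rng.choice(len(global_set), size=n_train, replace=False)
    return [global_set[int(i)] for i in idx]


def write_training_set(sets: Iterable[AssociationSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write(s.to_text() + "\n")


def read_training_set(path) -> List[AssociationSet]:
    with open(path) as fh:
        return [AssociationSet.from_text(line) for line in fh if line.strip()]


@dataclass
class TaskConfig:
    """Task constants.

    tau is the softmax temperature: small tau approaches argmax selection,
    large tau approaches uniform selection.  reward_magnitude is the value
    placed on the active reward input line.
    """

    n_stimuli: int = 4
    n_actions: int = 4
    n_episodes: int = 90
    n_steps_per_phase: int = 5
    tau: float = 0.1
    reward_magnitude: float = 1.0

    def __post_init__(self):
        for name in ("n_stimuli", "n_actions", "n_episodes", "n_steps_per_phase"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.reward_magnitude <= 0:
            raise ValueError("reward_magnitude must be positive")

    @property
    def n_input_lines(self) -> int:
        return self.n_stimuli + 2 + self.n_actions


def _softmax_probs(outputs: np.ndarray, tau: float) -> np.ndarray:
    z = (outputs - outputs.max()) / tau
    e = np.exp(z)
    return e / e.sum()


def _softmax_pick(outputs: np.ndarray, tau: float, u: float) -> int:
    p = _softmax_probs(np.asarray(outputs, dtype=float), tau)
    return int(min(np.searchsorted(np.cumsum(p), u * p.sum()), p.size - 1))


def softmax_select(
    outputs: Sequence[float], tau: float, rng: np.random.Generator
) -> int:
    """Sample action i with probability exp(o_i/tau) / sum_k exp(o_k/tau)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return _softmax_pick(np.asarray(outputs, dtype=float), tau, rng.random())


def encode_input_vector(
    stimulus: int,
    chosen_action: Optional[int] = None,
    reward: int = 0,
    n_stimuli: int = 4,
    n_actions: int = 4,
    reward_magnitude: float = 1.0,
    reward_style: int = REWARD_TWO_LINES,
) -> np.ndarray:
    """Input layout: [one-hot stimulus | reward line(s) | one-hot feedback].

    With two reward lines (default) the vector has length
    ``n_stimuli + 2 + n_actions`` (10 for the 4x4 task); with a single
    signed reward line, length 9 (used by the strict 9-input substrate).
    ``reward`` is +1, -1 or 0.
    """
    if not 0 <= stimulus < n_stimuli:
        raise ValueError("stimulus index out of range")
    if chosen_action is not None and not 0 <= chosen_action < n_actions:
        raise ValueError("action index out of range")
    if reward not in (-1, 0, 1):
        raise ValueError("reward must be +1, -1 or 0")
    n_reward = 2 if reward_style == REWARD_TWO_LINES else 1
    x = np.zeros(n_stimuli + n_reward + n_actions)
    x[stimulus] = 1.0
    if reward_style == REWARD_TWO_LINES:
        if reward > 0:
            x[n_stimuli] = reward_magnitude
        elif reward < 0:
            x[n_stimuli + 1] = reward_magnitude
    else:
        x[n_stimuli] = reward * reward_magnitude
    if chosen_action is not None:
        x[n_stimuli + n_reward + chosen_action] = 1.0
    return x


@dataclass
class FitnessResult:
    """Outcome of one evaluation on an evolutionary training set."""

    fitness: float                     # fraction of associations correct
    descriptor: np.ndarray             # 4 raw outputs x 4 assoc x |E|
    set_success: np.ndarray            # bool per set: all associations correct
    set_fitness: float = 0.0           # fraction of fully learned sets

    def __post_init__(self):
        self.set_fitness = float(np.mean(self.set_success)) if len(
            self.set_success
        ) else 0.0


def _reward_style_for(network: PlasticNetwork, config: TaskConfig) -> int:
    if network.n_inputs == config.n_input_lines:
        return REWARD_TWO_LINES
    if network.n_inputs == config.n_input_lines - 1:
        return REWARD_SIGNED_LINE
    raise ValueError(
        f"network has {network.n_inputs} inputs; expected "
        f"{config.n_input_lines} (two reward lines) or "
        f"{config.n_input_lines - 1} (signed reward line)"
    )


def _lifetime_python(
    network: PlasticNetwork,
    assoc: AssociationSet,
    config: TaskConfig,
    reward_style: int,
    reset_u: np.ndarray,
    softmax_u: np.ndarray,
):
    """Reference lifetime over the public network operations."""
    net = network.copy()
    net._reset_plastic_from(reset_u)
    n_a = len(assoc)
    success = np.zeros(n_a, dtype=np.int8)
    raw = np.zeros((n_a, config.n_actions))
    up = 0
    for ep in range(config.n_episodes):
        for s in range(n_a):
            x = encode_input_vector(
                s,
                None,
                0,
                config.n_stimuli,
                config.n_actions,
                config.reward_magnitude,
                reward_style,
            )
            outs = net.activate(x, config.n_steps_per_phase, learn=True)
            action = _softmax_pick(outs, config.tau, softmax_u[up])
            up += 1
            correct = action == assoc[s]
            x = encode_input_vector(
                s,
                action,
                1 if correct else -1,
                config.n_stimuli,
                config.n_actions,
                config.reward_magnitude,
                reward_style,
            )
            net.activate(x, config.n_steps_per_phase, learn=True)
            if ep == config.n_episodes - 1:
                success[s] = 1 if correct else 0
                raw[s] = outs
    return success, raw


def evaluate_fitness(
    network: PlasticNetwork,
    training_set: Sequence[AssociationSet],
    config: TaskConfig,
    rng: np.random.Generator,
    backend: str = "fast",
) -> FitnessResult:
    """Episodic fitness over an evolutionary training set.

    For each set: randomize the plastic weights, run ``n_episodes``
    episodes, score the last one.  Fitness is the association-level average
    in [0, 1]; the per-set all-correct flags and the behavior descriptor
    (the pre-softmax outputs of the last episode, 16 values per set) are
    returned alongside.
    """
    if len(training_set) == 0:
        raise ValueError("training set must not be empty")
    if network.n_outputs != config.n_actions:
        raise ValueError(
            f"network has {network.n_outputs} outputs, task needs {config.n_actions}"
        )
    style = _reward_style_for(network, config)
    cnet = CompiledNetwork.from_network(network) if backend == "fast" else None
    n_plastic = int(network.plastic_mask().sum())
    success_all = []
    raws = []
    for assoc in training_set:
        reset_u = rng.random(n_plastic)
        softmax_u = rng.random(config.n_episodes * len(assoc))
        if backend == "fast":
            success, raw = run_lifetime(
                cnet,
                np.asarray(assoc.actions),
                config.n_episodes,
                config.n_steps_per_phase,
                config.tau,
                config.reward_magnitude,
                style,
                reset_u,
                softmax_u,
            )
        elif backend == "reference":
            success, raw = _lifetime_python(
                network, assoc, config, style, reset_u, softmax_u
            )
        else:
            raise ValueError(f"unknown backend {backend!r}")
        success_all.append(np.asarray(success))
        raws.append(np.asarray(raw).ravel())
    success_all = np.array(success_all)
    return FitnessResult(
        fitness=float(success_all.mean()),
        descriptor=np.concatenate(raws),
        set_success=success_all.all(axis=1),
    )


@dataclass
class GlaResult:
    """GLA score: per-set success rate over the global training set."""

    set_level: float
    association_level: float
    n_sets: int
    n_repeats: int


def gla_score(
    agent,
    global_set: Sequence[AssociationSet],
    config: TaskConfig,
    rng: np.random.Generator,
    n_repeats: int = 5,
) -> GlaResult:
    """Fraction of association sets fully learned, averaged over
    ``n_repeats`` seeded lifetimes per set.

    ``agent`` is a :class:`PlasticNetwork` or any object with the agent
    protocol (``begin_set``/``act``/``observe``).
    """
    set_scores = []
    assoc_scores = []
    for _ in range(n_repeats):
        if isinstance(agent, PlasticNetwork):
            res = evaluate_fitness(agent, global_set, config, rng)
        else:
            res = evaluate_agent(agent, global_set, config, rng)
        set_scores.append(res.set_fitness)
        assoc_scores.append(res.fitness)
    return GlaResult(
        set_level=float(np.mean(set_scores)),
        association_level=float(np.mean(assoc_scores)),
        n_sets=len(global_set),
        n_repeats=n_repeats,
    )


class OracleAgent:
    """Upper-bound agent: answers every association correctly.

    Used to calibrate the task (fitness and GLA must both reach 1.0).
    """

    def begin_set(self, assoc: AssociationSet, rng: np.random.Generator) -> None:
        self._assoc = assoc

    def act(self, stimulus: int, rng: np.random.Generator):
        a = self._assoc[stimulus]
        outs = np.zeros(4)
        outs[a] = 1.0
        return a, outs

    def observe(self, stimulus, action, reward) -> None:
        pass


class UniformAgent:
    """Chance-level agent: picks uniformly among the four actions."""

    def begin_set(self, assoc, rng) -> None:
        pass

    def act(self, stimulus: int, rng: np.random.Generator):
        a = int(rng.integers(0, 4))
        return a, np.full(4, 0.25)

    def observe(self, stimulus, action, reward) -> None:
        pass


def evaluate_agent(
    agent,
    training_set: Sequence[AssociationSet],
    config: TaskConfig,
    rng: np.random.Generator,
) -> FitnessResult:
    """Run the episodic procedure with an abstract agent (no network)."""
    if len(training_set) == 0:
        raise ValueError("training set must not be empty")
    success_all = []
    raws = []
    for assoc in training_set:
        agent.begin_set(assoc, rng)
        n_a = len(assoc)
        success = np.zeros(n_a, dtype=np.int8)
        raw = np.zeros((n_a, config.n_actions))
        for ep in range(config.n_episodes):
            for s in range(n_a):
                action, outs = agent.act(s, rng)
                correct = action == assoc[s]
                agent.observe(s, action, 1 if correct else -1)
                if ep == config.n_episodes - 1:
                    success[s] = 1 if correct else 0
                    raw[s] = outs
        success_all.append(success)
        raws.append(raw.ravel())
    success_all = np.array(success_all)
    return FitnessResult(
        fitness=float(success_all.mean()),
        descriptor=np.concatenate(raws),
        set_success=success_all.all(axis=1),
    )
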