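"""Ant-colony-system architecture search over an incrementally grown graph.

The search maintains a rooted graph whose nodes are concrete layer choices
(a kind plus one parameter permutation).  Starting from an input-only
root, ants walk to a depth that increases by one each round: at a frontier
node all legal layer choices are added once as children with the initial
pheromone tau0, and each ant picks a child by the ant-colony-system (ACS)
pseudo-random proportional rule — with probability ``q0`` the
maximum-pheromone child, otherwise pheromone-proportional sampling — doing
a local pheromone update (decay toward tau0) on every edge it crosses.
When all ants of a round have been evaluated, the round's best ant
reinforces its path with the global update (decay toward its fitness).

Each ant path is repaired into a valid trainable architecture (flatten +
dense tail) before evaluation, so exactly ``n_ants * depth`` candidate
models are trained over a full search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .arch import (
    Architecture,
    ConstraintSet,
    LayerSpec,
    SearchSpaceSpec,
    repair_architecture,
)

__all__ = [
    "GraphNode",
    "Ant",
    "ACOConfig",
    "ACOHistory",
    "acs_select",
    "local_pheromone_update",
    "global_pheromone_update",
    "run_aco_search",
]

logger = logging.getLogger(__name__)


@dataclass
class GraphNode:
    """A layer choice with pheromone-weighted edges to successor choices."""

    layer_choice: LayerSpec | None  # None for the input root
    children: list["GraphNode"] = field(default_factory=list)
    pheromones: list[float] = field(default_factory=list)  # one per child
    expanded: bool = False

    def expand(self, choices: list[LayerSpec], tau0: float) -> None:
        """Add every choice once as a child with initial pheromone tau0."""
        if self.expanded:
            return
        existing = {c.layer_choice for c in self.children}
        for choice in choices:
            if choice not in existing:
                self.children.append(GraphNode(choice))
                self.pheromones.append(tau0)
        self.expanded = True


@dataclass
class Ant:
    """A walked path through the graph and its evaluated fitness."""

    path: list[GraphNode] = field(default_factory=list)
    edge_refs: list[tuple[GraphNode, int]] = field(default_factory=list)
    fitness: float | None = None

    def architecture(
        self, input_shape, rules: ConstraintSet, dense_default: LayerSpec | None = None
    ) -> Architecture:
        layers = tuple(n.layer_choice for n in self.path)
        raw = Architecture(layers, tuple(input_shape)) if layers else None
        if raw is None:
            raise ValueError("empty ant path")
        return repair_architecture(raw, rules, dense_default=dense_default)


@dataclass(frozen=True)
class ACOConfig:
    n_ants: int = 16
    depth: int = 32
    epochs_per_eval: int = 10
    image_size: int = 64
    q0: float = 0.5  # ACS greediness
    rho: float = 0.1  # evaporation
    tau0: float = 1.0  # initial pheromone
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 1 or self.depth < 1:
            raise ValueError("n_ants and depth must be positive")
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must lie in [0, 1]")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")


@dataclass
class ACOHistory:
    """Per-(depth, ant) fitness records plus the best-so-far trace."""

    records: list[dict] = field(default_factory=list)  # depth, ant, fitness
    best_fitness: list[float] = field(default_factory=list)  # running best


def acs_select(node: GraphNode, q0: float, rng: np.random.Generator) -> int:
    """ACS pseudo-random proportional rule; returns the chosen child index.

    With probability ``q0`` the maximum-pheromone child is taken (ties to
    the lowest index); otherwise a child is sampled with probability
    proportional to pheromone.
    """
    if not node.children:
        raise IndexError("node has no children (expansion exhausted)")
    tau = np.asarray(node.pheromones, dtype=float)
    if rng.random() < q0:
        return int(np.argmax(tau))  # argmax ties -> lowest index
    return int(rng.choice(len(tau), p=tau / tau.sum()))


def local_pheromone_update(tau: float, rho: float, tau0: float) -> float:
    """Per-step decay toward the initial pheromone: (1-rho)*tau + rho*tau0."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1]")
    return (1.0 - rho) * tau + rho * tau0


def global_pheromone_update(best_ant: Ant, rho: float) -> None:
    """Reinforce the best ant's path: tau' = (1-rho)*tau + rho*fitness.

    Only edges on the best path change; everything else is untouched.
    """
    if best_ant.fitness is None:
        raise RuntimeError("global update requires an evaluated ant")
    f = best_ant.fitness
    for parent, child_idx in best_ant.edge_refs:
        tau = parent.pheromones[child_idx]
        parent.pheromones[child_idx] = (1.0 - rho) * tau + rho * f


def run_aco_search(
    evaluator: Callable[[Architecture], float],
    config: ACOConfig,
    space: SearchSpaceSpec,
    rules: ConstraintSet = ConstraintSet(),
    input_shape: tuple[int, int, int] | None = None,
) -> tuple[Architecture, ACOHistory]:
    """Depth-bounded ACS search; returns the best architecture and history.

    Exactly ``config.n_ants * config.depth`` evaluator calls are made.
    An evaluator failure assigns fitness 0 to that candidate and the search
    continues.  Deterministic given the seed and a deterministic evaluator.
    """
    rng = np.random.default_rng(config.rng_seed)
    shape = input_shape or (config.image_size, config.image_size, 3)
    from .arch import LayerKind

    dense_default = (
        space.choices(LayerKind.DE)[0] if LayerKind.DE in space.layer_vocab else None
    )
    root = GraphNode(None)
    choices = space.all_choices()
    history = ACOHistory()
    best_arch: Architecture | None = None
    best_fit = -1.0

    for depth in range(1, config.depth + 1):
        round_best: Ant | None = None
        for ant_idx in range(config.n_ants):
            ant = Ant()
            node = root
            for _ in range(depth):
                if not node.expanded:
                    node.expand(choices, config.tau0)
                if not node.children:
                    break  # expansion exhausted: terminate this walk
                child_idx = acs_select(node, config.q0, rng)
                node.pheromones[child_idx] = local_pheromone_update(
                    node.pheromones[child_idx], config.rho, config.tau0
                )
                ant.edge_refs.append((node, child_idx))
                node = node.children[child_idx]
                ant.path.append(node)
            arch = ant.architecture(shape, rules, dense_default)
            try:
                ant.fitness = float(evaluator(arch))
            except Exception as exc:  # candidate failure is not fatal
                logger.warning("candidate failed (%s); fitness set to 0", exc)
                ant.fitness = 0.0
            history.records.append(
                {"depth": depth, "ant": ant_idx, "fitness": ant.fitness}
            )
            if ant.fitness > best_fit:
                best_fit, best_arch = ant.fitness, arch
            history.best_fitness.append(best_fit)
            if round_best is None or ant.fitness > round_best.fitness:
                round_best = ant
        global_pheromone_update(round_best, config.rho)

    assert best_arch is not None
    return best_arch, history
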