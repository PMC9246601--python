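"""Particle-swarm architecture search with discrete block-copy velocities.

Particles are architectures.  A velocity is a per-slot plan over layer
positions: keep the particle's own layer, copy the slot from the
particle's personal best (pbest), or copy it from the swarm's global best
(gbest).  At each differing slot the source is gbest with probability
``Cg`` and pbest otherwise, so good blocks of the global best propagate
through the swarm; slots the particle already shares with both sources are
kept.  When a source is longer than the particle, trailing slots may be
appended from it (gbest with probability Cg), letting architectures grow
toward the best performers, truncated at the B_u length bound.  After
every move a repair pass restores the three structural rules.

The classical continuous update (position += velocity with inertia w and
cognitive/social terms c1*r_t1, c1*r_t2) is kept in :class:`PSOConfig` as
documented, unused fields recording the correspondence; the discrete
block-copy scheme parameterized by Cg is what runs.

A full search performs ``runs x iterations x swarm_size`` candidate
evaluations; each run is independent and the best gbest across runs wins,
ties broken by smaller trainable-parameter count, then earlier discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping

import numpy as np

from .arch import (
    Architecture,
    ConstraintSet,
    LayerKind,
    LayerSpec,
    SearchSpaceSpec,
    random_architecture,
    repair_architecture,
)
from .evaluation import count_parameters

__all__ = [
    "SlotOp",
    "Velocity",
    "Particle",
    "Swarm",
    "PSOConfig",
    "PSOHistory",
    "init_swarm",
    "compute_velocity",
    "apply_velocity",
    "run_pso_search",
]

logger = logging.getLogger(__name__)


class SlotOp(Enum):
    KEEP = "keep"
    COPY_PBEST = "copy_from_pbest"
    COPY_GBEST = "copy_from_gbest"


@dataclass(frozen=True)
class Velocity:
    """Per-slot operation plan; length = alignment length of the move."""

    ops: tuple[SlotOp, ...]


@dataclass
class Particle:
    arch: Architecture
    pbest_arch: Architecture
    pbest_fitness: float = -1.0
    current_fitness: float = -1.0

    def record(self, fitness: float) -> None:
        self.current_fitness = fitness
        if fitness > self.pbest_fitness:
            self.pbest_fitness = fitness
            self.pbest_arch = self.arch


@dataclass
class Swarm:
    particles: list[Particle]
    gbest_arch: Architecture | None = None
    gbest_fitness: float = -1.0
    gbest_params: int = 0

    def update_gbest(self, particle: Particle, input_shape) -> None:
        """Adopt the particle as gbest if strictly fitter, or equally fit
        but smaller (fewer trainable parameters)."""
        f = particle.current_fitness
        if self.gbest_arch is None or f > self.gbest_fitness:
            self.gbest_arch = particle.arch
            self.gbest_fitness = f
            self.gbest_params = count_parameters(particle.arch, input_shape)
        elif f == self.gbest_fitness:
            p = count_parameters(particle.arch, input_shape)
            if p < self.gbest_params:
                self.gbest_arch, self.gbest_params = particle.arch, p


@dataclass(frozen=True)
class PSOConfig:
    runs: int = 5
    iterations: int = 12
    swarm_size: int = 20
    Cg: float = 0.5
    epochs_particle: int = 1
    epochs_gbest: int = 100
    layer_probs: Mapping[str, float] | None = None
    rng_seed: int = 0
    # classical continuous-update symbols, documented but not executed
    w: float | None = None
    c1: float | None = None
    r_t1: float | None = None
    r_t2: float | None = None

    def __post_init__(self) -> None:
        if self.runs < 1 or self.iterations < 1 or self.swarm_size < 1:
            raise ValueError("runs, iterations and swarm_size must be positive")
        if not 0.0 <= self.Cg <= 1.0:
            raise ValueError("Cg must lie in [0, 1]")


@dataclass
class PSOHistory:
    """Per-(run, iteration, particle) fitness plus per-run gbest traces."""

    records: list[dict] = field(default_factory=list)
    gbest_per_run: list[list[float]] = field(default_factory=list)
    final_gbest_fitness: float = -1.0


def init_swarm(
    config: PSOConfig,
    space: SearchSpaceSpec,
    rules: ConstraintSet = ConstraintSet(),
    rng: np.random.Generator | int | None = None,
    input_shape: tuple[int, int, int] = (64, 64, 3),
) -> Swarm:
    """Random constraint-satisfying swarm; pbest = initial self."""
    rng = np.random.default_rng(rng if rng is not None else config.rng_seed)
    particles = []
    for _ in range(config.swarm_size):
        arch = random_architecture(
            space, rules, config.layer_probs, rng, input_shape=input_shape
        )
        particles.append(Particle(arch=arch, pbest_arch=arch))
    return Swarm(particles)


def compute_velocity(
    particle: Particle,
    gbest: Architecture,
    Cg: float,
    rng: np.random.Generator,
) -> Velocity:
    """Draw the per-slot block-copy plan against pbest and gbest.

    Alignment runs over ``max(len(particle), len(chosen sources))`` slots;
    for each slot the source is gbest with probability Cg else pbest, and
    the op is a copy only where the particle's slot differs from (or does
    not reach) that source.
    """
    own = particle.arch.layers
    pb = particle.pbest_arch.layers
    gb = gbest.layers
    n = max(len(own), len(pb), len(gb))
    ops = []
    for i in range(n):
        use_gbest = rng.random() < Cg
        src = gb if use_gbest else pb
        if i >= len(src):
            ops.append(SlotOp.KEEP)  # source has nothing to offer here
        elif i < len(own) and own[i] == src[i]:
            ops.append(SlotOp.KEEP)
        else:
            ops.append(SlotOp.COPY_GBEST if use_gbest else SlotOp.COPY_PBEST)
    return Velocity(tuple(ops))


def apply_velocity(
    particle: Particle,
    velocity: Velocity,
    gbest: Architecture,
    rules: ConstraintSet = ConstraintSet(),
    B_u: int = 20,
) -> Architecture:
    """Rewrite slots per the plan, truncate at B_u, repair, and return."""
    own = particle.arch.layers
    pb = particle.pbest_arch.layers
    gb = gbest.layers
    out: list[LayerSpec] = []
    for i, op in enumerate(velocity.ops):
        if op is SlotOp.KEEP:
            if i < len(own):
                out.append(own[i])
        elif op is SlotOp.COPY_PBEST:
            if i < len(pb):
                out.append(pb[i])
            elif i < len(own):
                out.append(own[i])
        else:
            if i < len(gb):
                out.append(gb[i])
            elif i < len(own):
                out.append(own[i])
    out = out[:B_u]
    if not out:
        out = list(gb[:B_u])
    # slot mixing can merge flattens from both sources; keep the first
    seen_f = False
    deduped: list[LayerSpec] = []
    for l in out:
        if l.kind is LayerKind.F:
            if seen_f:
                continue
            seen_f = True
        deduped.append(l)
    out = deduped
    return repair_architecture(
        Architecture(tuple(out), particle.arch.input_shape), rules
    )


def run_pso_search(
    evaluator: Callable[[Architecture], float],
    config: PSOConfig,
    space: SearchSpaceSpec,
    rules: ConstraintSet = ConstraintSet(),
    input_shape: tuple[int, int, int] | None = None,
) -> tuple[Architecture, PSOHistory]:
    """r independent runs of i iterations over p particles.

    Exactly ``r*i*p`` evaluator calls; within each run the gbest fitness
    trace is non-decreasing.  Returns the best gbest across runs (ties to
    the smaller model, then the earlier run) and the full history.
    Deterministic given seed and a deterministic evaluator.
    """
    shape = input_shape or (64, 64, 3)
    history = PSOHistory()
    overall_arch: Architecture | None = None
    overall_fit, overall_params = -1.0, 0

    for run in range(config.runs):
        rng = np.random.default_rng((config.rng_seed, run))
        swarm = init_swarm(config, space, rules, rng, input_shape=shape)
        gbest_trace: list[float] = []
        for it in range(config.iterations):
            if it > 0:
                # move every particle before re-evaluating the swarm
                for particle in swarm.particles:
                    vel = compute_velocity(particle, swarm.gbest_arch, config.Cg, rng)
                    particle.arch = apply_velocity(
                        particle, vel, swarm.gbest_arch, rules, space.B_u
                    )
            for p_idx, particle in enumerate(swarm.particles):
                try:
                    fitness = float(evaluator(particle.arch))
                except Exception as exc:
                    logger.warning("candidate failed (%s); fitness set to 0", exc)
                    fitness = 0.0
                particle.record(fitness)
                swarm.update_gbest(particle, shape)
                history.records.append(
                    {
                        "run": run,
                        "iteration": it,
                        "particle": p_idx,
                        "fitness": fitness,
                        "gbest_fitness": swarm.gbest_fitness,
                    }
                )
            gbest_trace.append(swarm.gbest_fitness)
        history.gbest_per_run.append(gbest_trace)
        params = count_parameters(swarm.gbest_arch, shape)
        better = swarm.gbest_fitness > overall_fit or (
            swarm.gbest_fitness == overall_fit and params < overall_params
        )
        if overall_arch is None or better:
            overall_arch = swarm.gbest_arch
            overall_fit = swarm.gbest_fitness
            overall_params = params

    history.final_gbest_fitness = overall_fit
    assert overall_arch is not None
    return overall_arch, history
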