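"""Architecture representation, constraints, and search-space calculus.

A candidate model is an ordered sequence of typed, parameterized layers
drawn from a seven-symbol vocabulary:

======  =================================================
C2D     2-D convolution (``filter_count``, ``kernel_size``)
BN      batch normalization
DO      dropout (``rate``)
MP      max pooling (``pool_size``)
AP      average pooling (``pool_size``)
DE      dense / fully connected (``unit_count``)
F       flatten
======  =================================================

Architectures are written in a pipe-delimited notation, e.g.
``"C2D | BN | MP | F | DE"``.  Three structural rules keep candidates
trainable as image classifiers: at least one dense layer, a flatten before
the first dense layer, and no convolution after the flatten.

The module also provides the exact (arbitrary-precision) cardinality
calculus for bounded-length layer sequences and for per-layer parameter
permutation counts, plus the search-budget arithmetic for the two swarm
searches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LayerKind",
    "LayerSpec",
    "Architecture",
    "ConstraintSet",
    "SearchSpaceSpec",
    "SearchBudget",
    "Violation",
    "ArchitectureParseError",
    "parse_architecture",
    "format_architecture",
    "validate_architecture",
    "repair_architecture",
    "count_search_space",
    "count_parameterized_space",
    "count_models_aco",
    "count_models_pso",
    "random_architecture",
    "aco_default_space",
    "pso_default_space",
    "desk_space",
]


class LayerKind(str, Enum):
    """The seven layer abbreviations making up the search vocabulary."""

    C2D = "C2D"
    BN = "BN"
    DO = "DO"
    MP = "MP"
    AP = "AP"
    DE = "DE"
    F = "F"


# which parameter names each kind defines
_PARAM_NAMES: dict[LayerKind, tuple[str, ...]] = {
    LayerKind.C2D: ("filter_count", "kernel_size"),
    LayerKind.BN: (),
    LayerKind.DO: ("rate",),
    LayerKind.MP: ("pool_size",),
    LayerKind.AP: ("pool_size",),
    LayerKind.DE: ("unit_count",),
    LayerKind.F: (),
}

#: Conventional default parameters used when the notation omits them.
DEFAULT_PARAMS: dict[LayerKind, dict[str, float | int]] = {
    LayerKind.C2D: {"filter_count": 32, "kernel_size": 3},
    LayerKind.BN: {},
    LayerKind.DO: {"rate": 0.5},
    LayerKind.MP: {"pool_size": 2},
    LayerKind.AP: {"pool_size": 2},
    LayerKind.DE: {"unit_count": 64},
    LayerKind.F: {},
}


class ArchitectureParseError(ValueError):
    """Raised for a token that is not a known layer abbreviation."""


@dataclass(frozen=True)
class LayerSpec:
    """One typed, parameterized layer."""

    kind: LayerKind
    params: tuple[tuple[str, float | int], ...] = ()

    def __post_init__(self) -> None:
        expected = _PARAM_NAMES[self.kind]
        got = tuple(name for name, _ in self.params)
        if got != expected:
            raise ValueError(
                f"{self.kind.value} expects params {expected}, got {got}"
            )
        p = dict(self.params)
        for name in ("filter_count", "kernel_size", "pool_size", "unit_count"):
            if name in p and (int(p[name]) != p[name] or p[name] < 1):
                raise ValueError(f"{self.kind.value}.{name} must be an integer >= 1")
        if "rate" in p and not (0.0 < p["rate"] < 1.0):
            raise ValueError("DO.rate must lie strictly in (0, 1)")

    @classmethod
    def make(cls, kind: LayerKind | str, **params: float | int) -> "LayerSpec":
        if not isinstance(kind, LayerKind):
            kind = LayerKind(str(kind).upper())
        merged = dict(DEFAULT_PARAMS[kind])
        merged.update(params)
        return cls(kind, tuple((k, merged[k]) for k in _PARAM_NAMES[kind]))

    def get(self, name: str) -> float | int:
        return dict(self.params)[name]

    def to_dict(self) -> dict:
        return {"kind": self.kind.value, **dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "LayerSpec":
        d = dict(d)
        kind = d.pop("kind")
        return cls.make(kind, **d)


@dataclass(frozen=True)
class Architecture:
    """An ordered layer sequence plus the input image shape (H, W, C)."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (64, 64, 3)

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("an architecture needs at least one layer")
        n_flat = sum(1 for l in self.layers if l.kind is LayerKind.F)
        if n_flat > 1:
            raise ValueError("at most one flatten (F) layer is allowed")

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def kinds(self) -> tuple[LayerKind, ...]:
        return tuple(l.kind for l in self.layers)

    def notation(self) -> str:
        return format_architecture(self)

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_shape": list(self.input_shape),
                "notation": self.notation(),
                "layers": [l.to_dict() for l in self.layers],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Architecture":
        d = json.loads(text)
        return cls(
            tuple(LayerSpec.from_dict(l) for l in d["layers"]),
            tuple(d["input_shape"]),
        )


@dataclass(frozen=True)
class ConstraintSet:
    """The three structural rules a trainable candidate must satisfy."""

    min_dense: int = 1
    flatten_before_dense: bool = True
    no_conv_after_flatten: bool = True


@dataclass(frozen=True)
class Violation:
    rule: str
    index: int  # offending layer index, -1 for whole-architecture rules

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule}@{self.index}"


@dataclass
class SearchSpaceSpec:
    """Layer vocabulary with per-kind parameter grids and length bounds.

    ``perm_counts`` (the per-layer permutation counts P_i) are derived from
    the grid lengths; ``t_l`` is the vocabulary cardinality.
    """

    layer_vocab: tuple[LayerKind, ...]
    param_grids: dict[LayerKind, list[dict]]
    B_l: int = 3
    B_u: int = 20

    def __post_init__(self) -> None:
        self.layer_vocab = tuple(LayerKind(k) for k in self.layer_vocab)
        if not (1 <= self.B_l <= self.B_u):
            raise ValueError("need 1 <= B_l <= B_u")
        for k in self.layer_vocab:
            grid = self.param_grids.get(k)
            if not grid:
                raise ValueError(f"no parameter grid for {k.value}")

    @property
    def t_l(self) -> int:
        return len(self.layer_vocab)

    @property
    def perm_counts(self) -> tuple[int, ...]:
        return tuple(len(self.param_grids[k]) for k in self.layer_vocab)

    def choices(self, kind: LayerKind) -> list[LayerSpec]:
        return [LayerSpec.make(kind, **p) for p in self.param_grids[kind]]

    def all_choices(self) -> list[LayerSpec]:
        out: list[LayerSpec] = []
        for k in self.layer_vocab:
            out.extend(self.choices(k))
        return out

    def sample_params(self, kind: LayerKind, rng: np.random.Generator) -> dict:
        grid = self.param_grids[kind]
        return dict(grid[int(rng.integers(len(grid)))])


@dataclass(frozen=True)
class SearchBudget:
    """Model-training budgets for the two searches."""

    ants: int = 16
    depth: int = 32
    runs: int = 5
    iterations: int = 12
    swarm_size: int = 20

    def __post_init__(self) -> None:
        for name in ("ants", "depth", "runs", "iterations", "swarm_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def aco_models(self) -> int:
        return count_models_aco(self.ants, self.depth)

    @property
    def pso_models(self) -> int:
        return count_models_pso(self.runs, self.iterations, self.swarm_size)


# ---------------------------------------------------------------------------
# notation


def parse_architecture(
    text: str,
    defaults: Mapping[LayerKind, Mapping[str, float | int]] | None = None,
    input_shape: tuple[int, int, int] = (64, 64, 3),
) -> Architecture:
    """Parse pipe-delimited notation like ``"C2D | BN | MP | F | DE"``.

    Tokens are case-insensitive; unspecified layer parameters are filled
    from ``defaults`` (falling back to :data:`DEFAULT_PARAMS`).
    """
    layers = []
    for pos, token in enumerate(text.split("|"), start=1):
        token = token.strip()
        try:
            kind = LayerKind(token.upper())
        except ValueError:
            raise ArchitectureParseError(
                f"unknown layer token {token!r} at position {pos}"
            ) from None
        params = dict(DEFAULT_PARAMS[kind])
        if defaults and kind in defaults:
            params.update(defaults[kind])
        layers.append(LayerSpec.make(kind, **params))
    return Architecture(tuple(layers), tuple(input_shape))


def format_architecture(arch: Architecture) -> str:
    """Inverse of :func:`parse_architecture` (canonical ``" | "`` separator)."""
    return " | ".join(l.kind.value for l in arch.layers)


# ---------------------------------------------------------------------------
# constraints


def validate_architecture(
    arch: Architecture, rules: ConstraintSet = ConstraintSet()
) -> list[Violation]:
    """Return the list of structural-rule violations (empty = valid)."""
    out: list[Violation] = []
    kinds = arch.kinds
    n_dense = kinds.count(LayerKind.DE)
    if n_dense < rules.min_dense:
        out.append(Violation("min_dense", -1))
    f_idx = kinds.index(LayerKind.F) if LayerKind.F in kinds else None
    if rules.flatten_before_dense and n_dense >= 1:
        first_de = kinds.index(LayerKind.DE)
        if f_idx is None or f_idx > first_de:
            out.append(Violation("flatten_before_dense", first_de))
    elif rules.flatten_before_dense and n_dense == 0 and f_idx is None:
        # no dense at all: flag the missing flatten alongside min_dense
        out.append(Violation("flatten_before_dense", -1))
    if rules.no_conv_after_flatten and f_idx is not None:
        for i in range(f_idx + 1, len(kinds)):
            if kinds[i] is LayerKind.C2D:
                out.append(Violation("no_conv_after_flatten", i))
    return out


_SPATIAL = (LayerKind.C2D, LayerKind.MP, LayerKind.AP)


def repair_architecture(
    arch: Architecture,
    rules: ConstraintSet = ConstraintSet(),
    dense_default: LayerSpec | None = None,
) -> Architecture:
    """Deterministically edit an architecture until it satisfies the rules.

    Appends a dense layer if none exists, re-inserts a single flatten just
    before the first dense layer, and drops spatial layers (conv/pooling)
    that would follow the flatten.  Idempotent: architectures that already
    satisfy the rules (and have no spatial layer after the flatten) are
    returned unchanged.
    """
    if not validate_architecture(arch, rules):
        kinds = arch.kinds
        if LayerKind.F in kinds:
            f_idx = kinds.index(LayerKind.F)
            if all(k not in _SPATIAL for k in kinds[f_idx + 1 :]):
                return arch
    layers = [l for l in arch.layers if l.kind is not LayerKind.F]
    if not any(l.kind is LayerKind.DE for l in layers):
        layers.append(dense_default or LayerSpec.make(LayerKind.DE))
    first_de = next(i for i, l in enumerate(layers) if l.kind is LayerKind.DE)
    head, tail = layers[:first_de], layers[first_de:]
    tail = [l for l in tail if l.kind not in _SPATIAL]
    repaired = tuple(head) + (LayerSpec.make(LayerKind.F),) + tuple(tail)
    out = Architecture(repaired, arch.input_shape)
    assert not validate_architecture(out, rules)
    return out


# ---------------------------------------------------------------------------
# cardinality calculus (exact integers throughout)


def count_search_space(t_l: int, B_l: int, B_u: int) -> int:
    """Number of layer-kind sequences of length B_l..B_u over t_l symbols.

    Exactly ``sum(t_l**b for b in range(B_l, B_u + 1))`` in
    arbitrary-precision integer arithmetic.
    """
    t_l, B_l, B_u = int(t_l), int(B_l), int(B_u)
    if t_l < 1:
        raise ValueError("vocabulary size t_l must be >= 1")
    if not (1 <= B_l <= B_u):
        raise ValueError("need 1 <= B_l <= B_u")
    return sum(t_l**b for b in range(B_l, B_u + 1))


def count_parameterized_space(
    P: Sequence[int], n: Sequence[int], mode: str = "as_printed"
) -> int:
    """Parameter-permutation count for a fixed layer-kind multiset.

    ``P`` holds per-kind permutation counts, ``n`` the per-kind layer
    multiplicities.  ``mode="as_printed"`` returns the literal sum of powers
    ``sum(P_i ** n_i)``; ``mode="combinatorial"`` returns the product of
    powers ``prod(P_i ** n_i)`` — the number of distinct parameterizations
    of the fixed sequence.
    """
    if len(P) != len(n):
        raise ValueError("P and n must have equal length")
    P = [int(p) for p in P]
    n = [int(m) for m in n]
    if mode == "as_printed":
        return sum(p**m for p, m in zip(P, n))
    if mode == "combinatorial":
        out = 1
        for p, m in zip(P, n):
            out *= p**m
        return out
    raise ValueError(f"unknown mode {mode!r}")


def count_models_aco(ants: int, depth: int) -> int:
    """Models trained by the ant search: ants x depth."""
    if ants < 1 or depth < 1:
        raise ValueError("ants and depth must be positive")
    return int(ants) * int(depth)


def count_models_pso(r: int, i: int, p: int) -> int:
    """Models trained by the particle search: runs x iterations x swarm."""
    if r < 1 or i < 1 or p < 1:
        raise ValueError("runs, iterations and swarm size must be positive")
    return int(r) * int(i) * int(p)


# ---------------------------------------------------------------------------
# default search spaces


def aco_default_space(B_l: int = 3, B_u: int = 20) -> SearchSpaceSpec:
    """Vocabulary [C2D, MP, BN, DE] with permutation counts (9, 2, 1, 4).

    Conv: filters {32,64,128} x kernels {1,3,5}; max-pool: {2,3};
    batch-norm parameterless; dense units {64,128,256,512}.
    """
    grids = {
        LayerKind.C2D: [
            {"filter_count": f, "kernel_size": k}
            for f in (32, 64, 128)
            for k in (1, 3, 5)
        ],
        LayerKind.MP: [{"pool_size": p} for p in (2, 3)],
        LayerKind.BN: [{}],
        LayerKind.DE: [{"unit_count": u} for u in (64, 128, 256, 512)],
    }
    return SearchSpaceSpec(
        (LayerKind.C2D, LayerKind.MP, LayerKind.BN, LayerKind.DE), grids, B_l, B_u
    )


def pso_default_space(B_l: int = 3, B_u: int = 20) -> SearchSpaceSpec:
    """Vocabulary [C2D, MP, AP, DE] with the full initialization ranges.

    Conv outputs 3..256 with square kernels 3/5/7, dense units 1..300,
    pooling size 2.
    """
    grids = {
        LayerKind.C2D: [
            {"filter_count": f, "kernel_size": k}
            for f in range(3, 257)
            for k in (3, 5, 7)
        ],
        LayerKind.MP: [{"pool_size": 2}],
        LayerKind.AP: [{"pool_size": 2}],
        LayerKind.DE: [{"unit_count": u} for u in range(1, 301)],
    }
    return SearchSpaceSpec(
        (LayerKind.C2D, LayerKind.MP, LayerKind.AP, LayerKind.DE), grids, B_l, B_u
    )


def desk_space(B_l: int = 3, B_u: int = 10) -> SearchSpaceSpec:
    """Small grids sized for single-CPU experiments on toy images."""
    grids = {
        LayerKind.C2D: [
            {"filter_count": f, "kernel_size": k} for f in (8, 16, 32) for k in (3, 5)
        ],
        LayerKind.MP: [{"pool_size": 2}],
        LayerKind.AP: [{"pool_size": 2}],
        LayerKind.DE: [{"unit_count": u} for u in (16, 32, 64)],
    }
    return SearchSpaceSpec(
        (LayerKind.C2D, LayerKind.MP, LayerKind.AP, LayerKind.DE), grids, B_l, B_u
    )


# ---------------------------------------------------------------------------
# random generation


#: Table-style trunk sampling probabilities: conv / pooling / fully connected.
DEFAULT_LAYER_PROBS: dict[str, float] = {"conv": 0.7, "pool": 0.15, "dense": 0.15}


def random_architecture(
    space: SearchSpaceSpec,
    rules: ConstraintSet = ConstraintSet(),
    layer_probs: Mapping[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
    input_shape: tuple[int, int, int] = (64, 64, 3),
    bn_prob: float = 0.5,
    do_prob: float = 0.3,
    do_rate: float = 0.5,
) -> Architecture:
    """Draw a random constraint-satisfying architecture.

    A trunk of length uniform in [B_l, B_u] is sampled i.i.d. over
    conv / pooling / dense kinds with ``layer_probs``, then stably
    partitioned so dense layers come last (preserving the sampled kind
    multiset).  Batch-norm is attached after conv/dense blocks with
    probability ``bn_prob`` and dropout with ``do_prob`` (rate
    ``do_rate``), capped so the pre-repair length stays within B_u.
    A final repair pass inserts the flatten and guarantees validity.
    """
    if space.B_u < 2:
        raise ValueError("B_u < 2 cannot host a flatten + dense tail")
    rng = np.random.default_rng(rng)
    probs = dict(layer_probs or DEFAULT_LAYER_PROBS)
    names = ("conv", "pool", "dense")
    pvec = np.array([probs[n] for n in names], dtype=float)
    if abs(pvec.sum() - 1.0) > 1e-9:
        raise ValueError("layer_probs must sum to 1 over conv/pool/dense")

    has_ap = LayerKind.AP in space.layer_vocab
    length = int(rng.integers(space.B_l, space.B_u + 1))
    trunk: list[LayerSpec] = []
    for _ in range(length):
        role = names[int(rng.choice(3, p=pvec))]
        if role == "conv":
            kind = LayerKind.C2D
        elif role == "dense":
            kind = LayerKind.DE
        else:  # fair coin between max and average pooling when both exist
            kind = (
                LayerKind.AP
                if has_ap and rng.random() < 0.5
                else LayerKind.MP
            )
        trunk.append(LayerSpec.make(kind, **space.sample_params(kind, rng)))

    # stable partition: spatial trunk first, dense tail last
    trunk = [l for l in trunk if l.kind is not LayerKind.DE] + [
        l for l in trunk if l.kind is LayerKind.DE
    ]

    budget = space.B_u - len(trunk)  # decoration slots left under B_u
    decorated: list[LayerSpec] = []
    for layer in trunk:
        decorated.append(layer)
        if layer.kind in (LayerKind.C2D, LayerKind.DE):
            if rng.random() < bn_prob and budget > 0:
                decorated.append(LayerSpec.make(LayerKind.BN))
                budget -= 1
            if rng.random() < do_prob and budget > 0:
                decorated.append(LayerSpec.make(LayerKind.DO, rate=do_rate))
                budget -= 1

    dense_default = space.choices(LayerKind.DE)[0] if LayerKind.DE in space.layer_vocab else None
    arch = repair_architecture(
        Architecture(tuple(decorated), tuple(input_shape)),
        rules,
        dense_default=dense_default,
    )
    return arch
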