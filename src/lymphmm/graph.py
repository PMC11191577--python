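"""Lymphatic-spread graph and hidden-state enumeration.

The anatomy is abstracted as a directed acyclic graph whose nodes are lymph
node levels (LNLs). Two kinds of arcs carry parameters:

* a *tumor arc* into every level ``v`` with base probability ``b_v`` — the
  per-timestep probability of direct seeding from the primary tumor, and
* *level arcs* ``r -> s`` with transition probability ``t_rs`` — the
  per-timestep probability that an already involved level ``r`` seeds its
  downstream neighbour ``s``.

A patient's true (possibly occult) involvement pattern is a binary hidden
state over the levels; with ``V`` levels there are ``2**V`` states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "LymphGraph",
    "HiddenState",
    "build_default_graph",
    "enumerate_states",
    "is_progression",
    "state_bits",
]


class GraphValidationError(ValueError):
    """Raised when a lymphatic graph violates its structural invariants."""


@dataclass(frozen=True)
class HiddenState:
    """True involvement pattern over the graph's levels.

    ``bits[i]`` is 0 (healthy) or 1 (involved) for the i-th level in graph
    order; ``index`` encodes the pattern as an integer with the first level
    as the least-significant bit.
    """

    bits: tuple[int, ...]
    index: int

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("state bits must be 0 or 1")
        expected = sum(b << i for i, b in enumerate(self.bits))
        if expected != self.index:
            raise ValueError(
                f"index {self.index} does not encode bits {self.bits}"
            )

    @classmethod
    def from_index(cls, index: int, n_levels: int) -> "HiddenState":
        if not 0 <= index < 2**n_levels:
            raise ValueError(f"index {index} out of range for {n_levels} levels")
        bits = tuple((index >> i) & 1 for i in range(n_levels))
        return cls(bits=bits, index=index)

    @classmethod
    def from_bits(cls, bits) -> "HiddenState":
        bits = tuple(int(b) for b in bits)
        return cls(bits=bits, index=sum(b << i for i, b in enumerate(bits)))

    def label(self, levels: tuple[str, ...] | None = None) -> str:
        """Pattern string in level order, e.g. ``'0101'``."""
        return "".join(str(b) for b in self.bits)


@dataclass(frozen=True)
class LymphGraph:
    """Directed acyclic graph of lymphatic drainage.

    Parameters
    ----------
    levels
        Ordered LNL labels; the order fixes the bit layout of hidden states
        (first level = least-significant bit).
    tumor_arcs
        One ``(level, parameter_name)`` pair per level, the base-probability
        arc from the primary tumor.
    level_arcs
        ``(source, target, parameter_name)`` triples for inter-level drainage.
    """

    levels: tuple[str, ...]
    tumor_arcs: tuple[tuple[str, str], ...]
    level_arcs: tuple[tuple[str, str, str], ...]

    def __init__(self, levels, tumor_arcs=None, level_arcs=()):  # noqa: D107
        levels = tuple(str(v) for v in levels)
        if tumor_arcs is None:
            tumor_arcs = tuple((v, f"b{i + 1}") for i, v in enumerate(levels))
        else:
            tumor_arcs = tuple((str(v), str(name)) for v, name in tumor_arcs)
        level_arcs = tuple(
            (str(r), str(s), str(name)) for r, s, name in level_arcs
        )
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "tumor_arcs", tumor_arcs)
        object.__setattr__(self, "level_arcs", level_arcs)
        self._validate()

    def _validate(self) -> None:
        if not self.levels:
            raise GraphValidationError("graph needs at least one level")
        if len(set(self.levels)) != len(self.levels):
            raise GraphValidationError("duplicate level labels")
        tumor_levels = [v for v, _ in self.tumor_arcs]
        if sorted(tumor_levels) != sorted(self.levels):
            raise GraphValidationError(
                "every level needs exactly one tumor arc"
            )
        names = [n for _, n in self.tumor_arcs] + [n for *_, n in self.level_arcs]
        if len(set(names)) != len(names):
            raise GraphValidationError("arc parameter names must be unique")
        known = set(self.levels)
        for r, s, _ in self.level_arcs:
            if r not in known or s not in known:
                raise GraphValidationError(f"arc {r}->{s} references unknown level")
            if r == s:
                raise GraphValidationError(f"self-loop on level {r}")
        dag = nx.DiGraph()
        dag.add_nodes_from(self.levels)
        dag.add_edges_from((r, s) for r, s, _ in self.level_arcs)
        if not nx.is_directed_acyclic_graph(dag):
            raise GraphValidationError("level arcs must form a DAG")

    # -- derived structure ------------------------------------------------

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_states(self) -> int:
        return 2**self.n_levels

    def level_index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise KeyError(f"unknown level {level!r}") from None

    def parents(self, level: str) -> list[tuple[str, str]]:
        """``(parent_level, parameter_name)`` pairs of arcs into ``level``."""
        return [(r, name) for r, s, name in self.level_arcs if s == level]

    def base_parameter(self, level: str) -> str:
        for v, name in self.tumor_arcs:
            if v == level:
                return name
        raise KeyError(level)

    def topological_levels(self) -> list[str]:
        """Levels sorted so every arc goes from earlier to later."""
        dag = nx.DiGraph()
        dag.add_nodes_from(self.levels)
        dag.add_edges_from((r, s) for r, s, _ in self.level_arcs)
        # stable among ties: prefer declared level order
        order = {v: i for i, v in enumerate(self.levels)}
        return list(nx.lexicographical_topological_sort(dag, key=order.get))

    @property
    def parameter_names(self) -> list[str]:
        """Spread-parameter names: base probabilities then level arcs."""
        ordered = [self.base_parameter(v) for v in self.levels]
        return ordered + [name for *_, name in self.level_arcs]


def build_default_graph() -> LymphGraph:
    """The four-level cervical drainage chain I -> II -> III -> IV.

    Base probabilities ``b1..b4`` seed each level directly from the primary
    tumor; transition probabilities ``t12, t23, t34`` carry spread down the
    chain of efferent lymphatics.
    """
    levels = ("I", "II", "III", "IV")
    tumor_arcs = tuple((v, f"b{i + 1}") for i, v in enumerate(levels))
    level_arcs = (("I", "II", "t12"), ("II", "III", "t23"), ("III", "IV", "t34"))
    return LymphGraph(levels=levels, tumor_arcs=tumor_arcs, level_arcs=level_arcs)


def enumerate_states(graph: LymphGraph) -> list[HiddenState]:
    """All ``2**V`` hidden states in increasing index order.

    State 0 is all-healthy, state ``2**V - 1`` all-involved.
    """
    return [HiddenState.from_index(i, graph.n_levels) for i in range(graph.n_states)]


def state_bits(graph: LymphGraph) -> np.ndarray:
    """``(2**V, V)`` 0/1 array; row i is the bit pattern of state index i."""
    idx = np.arange(graph.n_states)
    return (idx[:, None] >> np.arange(graph.n_levels)[None, :]) & 1


def is_progression(x: HiddenState, y: HiddenState) -> bool:
    """True iff ``y`` can follow ``x`` under no-healing dynamics.

    Involvement is monotone: every level involved in ``x`` must remain
    involved in ``y`` (subset partial order on involvement sets).
    """
    if len(x.bits) != len(y.bits):
        raise ValueError("states belong to different graphs")
    return (x.index & y.index) == x.index
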