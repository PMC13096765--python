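"""Transition graphs and covariate-to-transition mappings.

A multistate model is a directed graph of numbered health states.  Every
permitted move ``i -> j`` is a *transition* with a contiguous 1-based index
``g = 1..G``; absorbing states (the death states in the breast-cancer
application) have no outgoing transitions.  Covariates enter the model
through a mapping that says which transitions each baseline covariate is
allowed to affect; mapping one design column to several transitions encodes
a coefficient shared across those transitions.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "TransitionGraph",
    "MappingTerm",
    "CovariateMapping",
    "figure1_breast5",
    "get_preset",
    "load_graph_config",
]


@dataclass(frozen=True)
class TransitionGraph:
    """Directed state/transition structure of a multistate model.

    Parameters
    ----------
    n_states
        Number of states, labelled ``1..n_states``.
    transitions
        Ordered ``(from_state, to_state)`` pairs; the position in this
        sequence defines the transition index ``g`` (1-based).
    absorbing_states
        States with no outgoing transitions.
    """

    n_states: int
    transitions: tuple[tuple[int, int], ...]
    absorbing_states: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", tuple(tuple(t) for t in self.transitions))
        object.__setattr__(self, "absorbing_states", frozenset(self.absorbing_states))
        seen: set[tuple[int, int]] = set()
        for i, j in self.transitions:
            for s in (i, j):
                if not 1 <= s <= self.n_states:
                    raise ValueError(f"state {s} outside 1..{self.n_states}")
            if i in self.absorbing_states:
                raise ValueError(f"transition {i}->{j} leaves absorbing state {i}")
            if (i, j) in seen:
                raise ValueError(f"duplicate transition {i}->{j}")
            seen.add((i, j))
        for s in self.absorbing_states:
            if not 1 <= s <= self.n_states:
                raise ValueError(f"absorbing state {s} outside 1..{self.n_states}")

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def origin(self, g: int) -> int:
        """Origin state of transition ``g`` (1-based)."""
        return self.transitions[self._check(g) - 1][0]

    def target(self, g: int) -> int:
        return self.transitions[self._check(g) - 1][1]

    def transition_id(self, i: int, j: int) -> int:
        """1-based index of transition ``i -> j``."""
        try:
            return self.transitions.index((i, j)) + 1
        except ValueError:
            raise KeyError(f"no transition {i}->{j}") from None

    def out_transitions(self, state: int) -> list[int]:
        """Transition ids leaving ``state`` (empty for absorbing states)."""
        return [g for g, (i, _) in enumerate(self.transitions, start=1) if i == state]

    def _check(self, g: int) -> int:
        if not 1 <= g <= self.n_transitions:
            raise KeyError(f"unknown transition id {g} (graph has G={self.n_transitions})")
        return g


@dataclass(frozen=True)
class MappingTerm:
    """One design column: a baseline covariate restricted to a set of transitions."""

    column: str
    covariate: str
    transitions: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", frozenset(self.transitions))


@dataclass(frozen=True)
class CovariateMapping:
    """Ordered covariate-to-transition mapping defining the expanded design.

    Each term produces one column of the transition-specific design vector
    ``Z_g``: the baseline covariate's value where ``g`` is in the term's
    transition set, zero elsewhere.
    """

    terms: tuple[MappingTerm, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        names = [t.column for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate design column names in mapping")

    @property
    def columns(self) -> list[str]:
        return [t.column for t in self.terms]

    @property
    def covariates(self) -> list[str]:
        """Distinct baseline covariates referenced, in first-use order."""
        out: list[str] = []
        for t in self.terms:
            if t.covariate not in out:
                out.append(t.covariate)
        return out

    @property
    def p(self) -> int:
        return len(self.terms)

    def validate(self, graph: TransitionGraph) -> None:
        for t in self.terms:
            bad = [g for g in t.transitions if not 1 <= g <= graph.n_transitions]
            if bad:
                raise ValueError(
                    f"mapping column {t.column!r} references unknown transition(s) {sorted(bad)}"
                )

    def design_row(self, base: Mapping[str, float], g: int) -> np.ndarray:
        """Expanded design vector ``Z_g`` for one record of transition ``g``."""
        return np.array(
            [float(base[t.covariate]) if g in t.transitions else 0.0 for t in self.terms]
        )

    @classmethod
    def shared(cls, covariates: Sequence[str], graph: TransitionGraph) -> "CovariateMapping":
        """One column per covariate, shared across all transitions."""
        allg = frozenset(range(1, graph.n_transitions + 1))
        return cls(tuple(MappingTerm(c, c, allg) for c in covariates))


def figure1_breast5() -> TransitionGraph:
    """The 5-state breast-cancer graph: surgery (1), local relapse (2),
    distant relapse (3), cancer death (4), other-cause death (5); 9
    transitions, both death states absorbing."""
    return TransitionGraph(
        n_states=5,
        transitions=(
            (1, 2), (1, 3), (1, 4), (1, 5),
            (2, 3), (2, 4), (2, 5),
            (3, 4), (3, 5),
        ),
        absorbing_states=frozenset({4, 5}),
    )


_PRESETS = {"figure1_breast5": figure1_breast5}


def get_preset(name: str) -> TransitionGraph:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown graph preset {name!r}; known: {sorted(_PRESETS)}") from None


def load_graph_config(path) -> tuple[TransitionGraph, CovariateMapping | None]:
    """Read a graph (+ optional covariate mapping) from a YAML config.

    The file either names a preset::

        preset: figure1_breast5

    or spells the graph out::

        n_states: 3
        transitions: [[1, 2], [2, 3]]
        absorbing_states: [3]

    and may add a mapping section::

        mapping:
          - {column: size, covariate: size, transitions: [1, 2]}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"graph config {path} is not a mapping")
    if "preset" in cfg:
        graph = get_preset(cfg["preset"])
    else:
        try:
            graph = TransitionGraph(
                n_states=int(cfg["n_states"]),
                transitions=tuple((int(i), int(j)) for i, j in cfg["transitions"]),
                absorbing_states=frozenset(int(s) for s in cfg.get("absorbing_states", ())),
            )
        except KeyError as exc:
            raise ValueError(f"graph config {path} missing key {exc}") from None
    mapping = None
    if "mapping" in cfg:
        terms = tuple(
            MappingTerm(
                column=str(t["column"]),
                covariate=str(t.get("covariate", t["column"])),
                transitions=frozenset(int(g) for g in t["transitions"]),
            )
            for t in cfg["mapping"]
        )
        mapping = CovariateMapping(terms)
        mapping.validate(graph)
    return graph, mapping
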