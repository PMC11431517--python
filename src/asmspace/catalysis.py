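"""Probabilistic catalyst assignment.

Each reaction of a construction independently receives a catalyst with
probability ``p_cat``.  Catalysts are drawn from the construction's full
element set E (products plus constituents, the final product included) under
one of two strategies:

``UNIFORM_NO_REUSE``
    all elements equally likely; no element may catalyse two reactions.
``WEIGHTED_REUSE``
    elements weighted by their symbol count relative to the longest element,
    drawn independently with replacement — longer elements are likelier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .core import Construction, Element

__all__ = [
    "CatalystStrategy",
    "CatalysedConstruction",
    "catalyst_probabilities",
    "assign_catalysts",
]


class CatalystStrategy(str, enum.Enum):
    """How a catalyst is picked from the element set once a reaction is catalysed."""

    UNIFORM_NO_REUSE = "uniform-no-reuse"
    WEIGHTED_REUSE = "weighted-reuse"


@dataclass(frozen=True)
class CatalysedConstruction:
    """A construction plus a partial reaction -> catalyst assignment.

    ``catalysts`` maps the index of a reaction (position in
    ``construction.reactions``) to the element catalysing it; uncatalysed
    reactions are absent.  Under the uniform-no-reuse strategy all assigned
    catalysts are distinct.
    """

    construction: Construction
    catalysts: Mapping[int, Element]
    p_cat: float
    strategy: CatalystStrategy

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cat <= 1.0:
            raise ValueError(f"p_cat must be in [0, 1], got {self.p_cat}")
        n_reactions = len(self.construction.reactions)
        elements = self.construction.elements
        for idx, cat in self.catalysts.items():
            if not 0 <= idx < n_reactions:
                raise ValueError(f"reaction index {idx} out of range")
            if cat not in elements:
                raise ValueError(f"catalyst {cat} is not an element of the construction")
        if self.strategy is CatalystStrategy.UNIFORM_NO_REUSE:
            cats = list(self.catalysts.values())
            if len(set(cats)) != len(cats):
                raise ValueError("uniform-no-reuse forbids repeated catalysts")

    @property
    def n_catalysed(self) -> int:
        return len(self.catalysts)

    def catalyst_set(self) -> frozenset[Element]:
        """K: the set of all assigned catalysts."""
        return frozenset(self.catalysts.values())


def catalyst_probabilities(elements: Iterable[Element]) -> np.ndarray:
    """Length-weighted selection probabilities over an element collection.

    The weight of element ``e`` is ``len(e) / max_len`` where ``max_len`` is
    the longest element in the collection; probabilities are the weights
    normalised to sum to one.  Order follows the iteration order of
    ``elements``.
    """
    elems = list(elements)
    if not elems:
        raise ValueError("element collection must be non-empty")
    lengths = np.array([e.length for e in elems], dtype=float)
    weights = lengths / lengths.max()
    return weights / weights.sum()


def assign_catalysts(
    construction: Construction,
    p_cat: float,
    strategy: CatalystStrategy | str,
    rng: np.random.Generator,
) -> CatalysedConstruction:
    """Draw a random catalyst assignment for every reaction of a construction.

    A fair coin with success probability ``p_cat`` is flipped independently
    for each reaction (in pre-order from the root); the catalysed reactions
    then receive elements of E according to ``strategy``.  For no-reuse the
    distinct catalysts are drawn jointly, uniformly over subsets of E —
    distributionally identical to drawing sequentially without replacement.
    The pool E always suffices: ``|E| = 2n - 1 > n - 1`` reactions.
    """
    strategy = CatalystStrategy(strategy)
    if not 0.0 <= p_cat <= 1.0:
        raise ValueError(f"p_cat must be in [0, 1], got {p_cat}")
    n_reactions = len(construction.reactions)
    coins = rng.random(n_reactions) < p_cat
    catalysed = np.flatnonzero(coins)
    assignment: dict[int, Element] = {}
    if catalysed.size:
        elements = sorted(construction.elements, key=lambda e: (e.length, e.symbols))
        if strategy is CatalystStrategy.UNIFORM_NO_REUSE:
            picks = rng.choice(len(elements), size=catalysed.size, replace=False)
        else:
            probs = catalyst_probabilities(elements)
            picks = rng.choice(len(elements), size=catalysed.size, replace=True, p=probs)
        for idx, pick in zip(catalysed, picks):
            assignment[int(idx)] = elements[int(pick)]
    return CatalysedConstruction(
        construction=construction,
        catalysts=assignment,
        p_cat=p_cat,
        strategy=strategy,
    )
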