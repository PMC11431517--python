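"""Domain types and random construction-tree generation for the toy assembly model.

The model builds a *final product* — a word of distinct, alphabetically
ordered symbols such as ``"ABCDEF"`` — by recursively joining pairs of
contiguous fragments.  A complete set of join reactions forming a full
binary tree with the final product at the root is a :class:`Construction`;
the set of all constructions of a word is its assembly space.

Reuse of already-built fragments is deliberately forbidden here (each word
has unique symbols, each fragment is built exactly once), which makes the
assembly index of a word trivially ``len(word) - 1``; the interesting
structure lives in the *depth* of a construction — the longest chain of
consecutive reactions from a basic symbol to the root — which discriminates
parallel from consecutive builds.  The exact solver that does allow reuse
lives in :mod:`asmspace.assembly_index`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "DEFAULT_ALPHABET",
    "Element",
    "Reaction",
    "Construction",
    "make_word",
    "generate_construction",
    "depth",
    "min_depth",
    "assembly_index_unique",
]

DEFAULT_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True, slots=True)
class Element:
    """A molecule/object: a sequence of distinct symbols in ascending order.

    Covers basic building blocks (single symbols), intermediate products and
    the final product alike.
    """

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("an element needs at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"element symbols must be distinct: {self.symbols!r}")
        if list(self.symbols) != sorted(self.symbols):
            raise ValueError(
                f"element symbols must be in ascending order: {self.symbols!r}"
            )

    @property
    def length(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols


@dataclass(frozen=True, slots=True)
class Reaction:
    """A join event ``left + right -> product``.

    ``layer`` is the number of reactions between this one and the root
    reaction (root = 0); it is what the depth metric reads off.
    """

    left: Element
    right: Element
    product: Element
    layer: int

    def __post_init__(self) -> None:
        if self.left.symbols + self.right.symbols != self.product.symbols:
            raise ValueError(
                f"{self.left}+{self.right} is not a contiguous split of {self.product}"
            )
        if self.layer < 0:
            raise ValueError("layer must be non-negative")

    def __str__(self) -> str:
        return f"{self.left}+{self.right}->{self.product}"


@dataclass(frozen=True)
class Construction:
    """A full binary tree of join reactions producing ``final_product``.

    For a final product of ``n`` unique symbols a valid construction has
    exactly ``n - 1`` reactions, ``n - 2`` intermediate products, and an
    element set (products plus constituents) of exactly ``2n - 1`` members.
    Reactions are stored in pre-order from the root.
    """

    final_product: Element
    reactions: tuple[Reaction, ...]
    _by_product: dict[Element, Reaction] = field(
        init=False, repr=False, compare=False, hash=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        n = self.final_product.length
        if n < 2:
            raise ValueError("a construction needs a final product of length >= 2")
        if len(self.reactions) != n - 1:
            raise ValueError(
                f"expected {n - 1} reactions for {self.final_product}, "
                f"got {len(self.reactions)}"
            )
        by_product: dict[Element, Reaction] = {}
        for r in self.reactions:
            if r.product in by_product:
                raise ValueError(f"{r.product} is produced twice")
            by_product[r.product] = r
        if self.final_product not in by_product:
            raise ValueError("no reaction produces the final product")
        # every multi-symbol reactant must itself be produced, exactly once
        for r in self.reactions:
            for side in (r.left, r.right):
                if side.length > 1 and side not in by_product:
                    raise ValueError(f"intermediate {side} is never produced")
        object.__setattr__(self, "_by_product", by_product)

    # ---- derived sets -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of unique symbols of the final product."""
        return self.final_product.length

    @property
    def products(self) -> frozenset[Element]:
        """P: the final product and every intermediate product."""
        return frozenset(r.product for r in self.reactions)

    @property
    def constituents(self) -> frozenset[Element]:
        """C: every reactant, including the single-symbol building blocks."""
        out = set()
        for r in self.reactions:
            out.add(r.left)
            out.add(r.right)
        return frozenset(out)

    @property
    def elements(self) -> frozenset[Element]:
        """E = P ∪ C; has exactly ``2n - 1`` members."""
        return self.products | self.constituents

    def reaction_producing(self, product: Element) -> Reaction:
        return self._by_product[product]

    def subtree_reactions(self, root_product: Element) -> tuple[Reaction, ...]:
        """All reactions in the subtree rooted at ``root_product``, pre-order."""
        out: list[Reaction] = []
        stack = [root_product]
        while stack:
            node = stack.pop()
            if node.length == 1:
                continue
            r = self._by_product[node]
            out.append(r)
            stack.append(r.right)
            stack.append(r.left)
        return tuple(out)

    @property
    def depth(self) -> int:
        return depth(self)

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions)


def make_word(n: int, alphabet: str = DEFAULT_ALPHABET) -> Element:
    """The canonical ``n``-symbol word: the first ``n`` letters of ``alphabet``."""
    if n < 1:
        raise ValueError("word length must be >= 1")
    if n > len(alphabet):
        raise ValueError(
            f"word length {n} exceeds the {len(alphabet)}-symbol alphabet; "
            "pass a larger custom alphabet"
        )
    return Element(alphabet[:n])


def generate_construction(
    final_product: Element, rng: np.random.Generator
) -> Construction:
    """Sample a random construction tree by recursive product decomposition.

    Each product of length ``L`` is split at a cut position drawn uniformly
    from ``{1, ..., L-1}``; both fragments are then decomposed recursively.
    Note that uniform cut positions do *not* induce a uniform distribution
    over tree shapes (consecutive chains are individually likelier than any
    single balanced shape for longer words).

    Parameters
    ----------
    final_product
        Word of >= 2 distinct, sorted symbols.
    rng
        numpy ``Generator``; the only source of randomness.
    """
    n = final_product.length
    if n < 2:
        raise ValueError("final product must have at least 2 symbols")
    # one uniform variate per reaction, consumed in pre-order
    u = rng.random(n - 1)
    counter = [0]
    reactions: list[Reaction] = []

    def split(product: Element, layer: int) -> None:
        L = product.length
        if L == 1:
            return
        cut = 1 + int(u[counter[0]] * (L - 1))  # uniform over 1..L-1
        counter[0] += 1
        left = Element(product.symbols[:cut])
        right = Element(product.symbols[cut:])
        reactions.append(Reaction(left=left, right=right, product=product, layer=layer))
        split(left, layer + 1)
        split(right, layer + 1)

    split(final_product, 0)
    return Construction(final_product=final_product, reactions=tuple(reactions))


def depth(construction: Construction) -> int:
    """Longest chain of consecutive reactions from any symbol to the root.

    Equals ``1 + max(layer)`` over the construction's reactions, with
    single-symbol reactants contributing depth 0.
    """
    return 1 + max(r.layer for r in construction.reactions)


def min_depth(n_unique: int) -> int:
    """Minimal possible construction depth of an ``n_unique``-symbol word.

    ``ceil(log2 n)`` — the depth of a maximally parallel (balanced) build,
    analogous to the height of a balanced binary search tree. Independent of
    the particular construction chosen.
    """
    if n_unique < 1:
        raise ValueError("need at least one symbol")
    return (n_unique - 1).bit_length()


def assembly_index_unique(word: Element) -> int:
    """Assembly index of a unique-symbol word under the no-reuse rule.

    Every construction of such a word uses exactly ``len(word) - 1`` join
    reactions, so the minimum over pathways is trivial; reuse could not help
    a repeat-free word anyway.
    """
    return word.length - 1
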