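"""Autocatalysis of subconstructions and the exponential amplification factor.

Every product of a construction (the final product included) roots a
*subconstruction*: the subtree building that product, with its own product
set P_j, constituent set C_j, element set E_j = P_j ∪ C_j and catalyst set
K_j (the catalysts assigned to reactions inside the subtree).  A
subconstruction is autocatalytic when it has at least one catalyst and all
its catalysts lie inside its own element set — catalytic closure at the
subtree level.  The count ``k`` of autocatalytic subconstructions feeds the
amplification factor ``(1 + k)^2`` that reweights a construction's
contribution to the depth distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalysis import CatalysedConstruction
from .core import Element

__all__ = [
    "Subconstruction",
    "AmplificationResult",
    "enumerate_subconstructions",
    "is_autocatalytic",
    "count_autocatalytic_subsets",
    "amplification_factor",
    "amplify",
]


@dataclass(frozen=True)
class Subconstruction:
    """The subtree rooted at one product, with its derived sets."""

    root_product: Element
    products: frozenset[Element]
    constituents: frozenset[Element]
    elements: frozenset[Element]
    catalysts: frozenset[Element]

    @property
    def n_leaves(self) -> int:
        return self.root_product.length


@dataclass(frozen=True)
class AmplificationResult:
    """Autocatalytic subset count and the resulting sample multiplicity."""

    k: int
    multiplicity: int


def enumerate_subconstructions(
    cc: CatalysedConstruction,
) -> tuple[Subconstruction, ...]:
    """One subconstruction per product of the construction, root included.

    A construction of an ``n``-symbol word has ``n - 1`` products and hence
    ``n - 1`` subconstructions.  Order follows the construction's pre-order
    reaction list, so the whole construction comes first.
    """
    construction = cc.construction
    catalyst_of = {idx: cat for idx, cat in cc.catalysts.items()}
    reaction_index = {r: i for i, r in enumerate(construction.reactions)}
    out: list[Subconstruction] = []
    for r in construction.reactions:
        root = r.product
        sub_reactions = construction.subtree_reactions(root)
        products = frozenset(sr.product for sr in sub_reactions)
        constituents = frozenset(
            side for sr in sub_reactions for side in (sr.left, sr.right)
        )
        catalysts = frozenset(
            catalyst_of[reaction_index[sr]]
            for sr in sub_reactions
            if reaction_index[sr] in catalyst_of
        )
        out.append(
            Subconstruction(
                root_product=root,
                products=products,
                constituents=constituents,
                elements=products | constituents,
                catalysts=catalysts,
            )
        )
    return tuple(out)


def is_autocatalytic(sub: Subconstruction, *, count_empty: bool = False) -> bool:
    """Whether all of a subconstruction's catalysts lie within its element set.

    A subconstruction with no catalysts at all is not counted as
    autocatalytic unless ``count_empty`` is set: requiring at least one
    catalyst mirrors the construction-level definition and keeps the
    uncatalysed baseline at ``k = 0``.
    """
    if not sub.catalysts:
        return count_empty
    return sub.catalysts <= sub.elements


def count_autocatalytic_subsets(
    cc: CatalysedConstruction,
    *,
    include_root: bool = True,
    count_empty: bool = False,
) -> int:
    """k: number of autocatalytic subconstructions of a catalysed construction.

    ``include_root`` controls whether the whole construction itself (always
    autocatalytic once it carries a single catalyst, since every catalyst
    comes from its own element set) contributes to ``k``; it does by
    default, so any catalysed construction has ``k >= 1``.
    """
    construction = cc.construction
    catalyst_of = cc.catalysts
    reaction_index = {r: i for i, r in enumerate(construction.reactions)}

    k = 0

    def walk(product: Element) -> tuple[set[Element], set[Element]]:
        # returns (elements, catalysts) of the subtree rooted at `product`
        nonlocal k
        if product.length == 1:
            return {product}, set()
        r = construction.reaction_producing(product)
        left_e, left_k = walk(r.left)
        right_e, right_k = walk(r.right)
        elements = left_e | right_e
        elements.add(product)
        catalysts = left_k | right_k
        idx = reaction_index[r]
        if idx in catalyst_of:
            catalysts.add(catalyst_of[idx])
        is_root = product == construction.final_product
        if not is_root or include_root:
            if (catalysts or count_empty) and catalysts <= elements:
                k += 1
        return elements, catalysts

    walk(construction.final_product)
    return k


def amplification_factor(k: int) -> int:
    """Sample multiplicity under exponential autocatalytic amplification.

    1 when there is no autocatalytic subset, ``(1 + k)^2`` otherwise (the
    two coincide at ``k = 0``).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    return 1 if k == 0 else (1 + k) ** 2


def amplify(
    cc: CatalysedConstruction,
    *,
    include_root: bool = True,
    count_empty: bool = False,
) -> AmplificationResult:
    """Count autocatalytic subsets and derive the multiplicity in one go."""
    k = count_autocatalytic_subsets(
        cc, include_root=include_root, count_empty=count_empty
    )
    return AmplificationResult(k=k, multiplicity=amplification_factor(k))
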