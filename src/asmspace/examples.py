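"""Named worked examples of the toy model, built programmatically.

These encode the standard illustrative cases: the parallel vs consecutive
builds of the six-letter word, a catalysed six-letter construction, an
eight-letter construction whose ``EFG`` subconstruction fails the
autocatalysis test, and a six-letter assignment with known per-subset
autocatalysis verdicts.  They double as test fixtures and as ready-made
inputs for the DOT/JSON exporters.
"""

from __future__ import annotations

from .catalysis import CatalysedConstruction, CatalystStrategy
from .core import Construction, Element, Reaction

__all__ = [
    "parallel_six_letter",
    "consecutive_six_letter",
    "catalysed_six_letter",
    "eight_letter_catalysed",
    "subset_verdict_example",
]


def _construction(final: str, triples: list[tuple[str, str, int]]) -> Construction:
    reactions = tuple(
        Reaction(
            left=Element(left),
            right=Element(right),
            product=Element(left + right),
            layer=layer,
        )
        for left, right, layer in triples
    )
    return Construction(final_product=Element(final), reactions=reactions)


def parallel_six_letter() -> Construction:
    """Balanced build of ABCDEF: ABC and DEF assembled in parallel; depth 3."""
    return _construction(
        "ABCDEF",
        [
            ("ABC", "DEF", 0),
            ("AB", "C", 1),
            ("A", "B", 2),
            ("DE", "F", 1),
            ("D", "E", 2),
        ],
    )


def consecutive_six_letter() -> Construction:
    """Fully consecutive build of ABCDEF, one letter appended per step; depth 5."""
    return _construction(
        "ABCDEF",
        [
            ("ABCDE", "F", 0),
            ("ABCD", "E", 1),
            ("ABC", "D", 2),
            ("AB", "C", 3),
            ("A", "B", 4),
        ],
    )


def catalysed_six_letter() -> CatalysedConstruction:
    """Catalysed ABCDEF with products {ABCDEF, ABC, BC, DEF, EF}.

    The tree is fixed by its product set (ABCDEF = ABC + DEF, ABC = A + BC,
    DEF = D + EF); the two catalyst placements here are one representative
    choice illustrating catalysts drawn from the whole element set.
    """
    construction = _construction(
        "ABCDEF",
        [
            ("ABC", "DEF", 0),
            ("A", "BC", 1),
            ("B", "C", 2),
            ("D", "EF", 1),
            ("E", "F", 2),
        ],
    )
    return CatalysedConstruction(
        construction=construction,
        catalysts={1: Element("DEF"), 4: Element("EF")},
        p_cat=0.5,
        strategy=CatalystStrategy.WEIGHTED_REUSE,
    )


def eight_letter_catalysed() -> CatalysedConstruction:
    """Catalysed ABCDEFGH whose EFG subconstruction is *not* autocatalytic.

    The EFG subtree (EFG = E + FG, FG = F + G) carries catalysts CD and EFG;
    its element set is {EFG, FG, E, F, G}, so the outside catalyst CD breaks
    catalytic closure while the self-catalyst EFG does not.
    """
    construction = _construction(
        "ABCDEFGH",
        [
            ("ABCD", "EFGH", 0),
            ("AB", "CD", 1),
            ("A", "B", 2),
            ("C", "D", 2),
            ("EFG", "H", 1),
            ("E", "FG", 2),
            ("F", "G", 3),
        ],
    )
    return CatalysedConstruction(
        construction=construction,
        # reaction 5: E+FG->EFG catalysed by CD; reaction 6: F+G->FG by EFG
        catalysts={5: Element("CD"), 6: Element("EFG")},
        p_cat=0.5,
        strategy=CatalystStrategy.WEIGHTED_REUSE,
    )


def subset_verdict_example() -> CatalysedConstruction:
    """Consecutive ABCDEF assignment with known per-subset verdicts.

    Synthetic reconstruction: the tree is the chain ABCDEF = A + BCDEF,
    BCDEF = B + CDEF, CDEF = C + DEF, DEF = D + EF, EF = E + F with
    catalysts BCDEF (on C + DEF) and DEF (on E + F).  Walking the
    subconstructions rooted at ABCDEF, BCDEF, CDEF, DEF, EF in order gives
    the verdicts (True, True, False, True, False): the CDEF subtree fails
    because BCDEF lies outside it, and the EF subtree fails because DEF
    lies outside it.
    """
    construction = _construction(
        "ABCDEF",
        [
            ("A", "BCDEF", 0),
            ("B", "CDEF", 1),
            ("C", "DEF", 2),
            ("D", "EF", 3),
            ("E", "F", 4),
        ],
    )
    return CatalysedConstruction(
        construction=construction,
        catalysts={2: Element("BCDEF"), 4: Element("DEF")},
        p_cat=0.5,
        strategy=CatalystStrategy.WEIGHTED_REUSE,
    )
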