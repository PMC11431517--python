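"""JSON and DOT serialisation of constructions and catalyst assignments."""

from __future__ import annotations

import json
from pathlib import Path

from .assembly_index import AssemblyPathway, AssemblyStep
from .catalysis import CatalysedConstruction, CatalystStrategy
from .core import Construction, Element, Reaction

__all__ = [
    "construction_to_dict",
    "construction_from_dict",
    "catalysed_to_dict",
    "catalysed_from_dict",
    "pathway_to_dict",
    "pathway_from_dict",
    "to_dot",
    "dump_json",
    "load_json",
]


def construction_to_dict(construction: Construction) -> dict:
    return {
        "final_product": construction.final_product.symbols,
        "reactions": [
            [r.left.symbols, r.right.symbols, r.product.symbols, r.layer]
            for r in construction.reactions
        ],
    }


def construction_from_dict(data: dict) -> Construction:
    reactions = tuple(
        Reaction(
            left=Element(left), right=Element(right),
            product=Element(product), layer=int(layer),
        )
        for left, right, product, layer in data["reactions"]
    )
    return Construction(
        final_product=Element(data["final_product"]), reactions=reactions
    )


def catalysed_to_dict(cc: CatalysedConstruction) -> dict:
    return {
        "construction": construction_to_dict(cc.construction),
        "catalysts": [
            [idx, cat.symbols] for idx, cat in sorted(cc.catalysts.items())
        ],
        "p_cat": cc.p_cat,
        "strategy": cc.strategy.value,
    }


def catalysed_from_dict(data: dict) -> CatalysedConstruction:
    return CatalysedConstruction(
        construction=construction_from_dict(data["construction"]),
        catalysts={int(idx): Element(sym) for idx, sym in data["catalysts"]},
        p_cat=float(data["p_cat"]),
        strategy=CatalystStrategy(data["strategy"]),
    )


def pathway_to_dict(pathway: AssemblyPathway) -> dict:
    return {
        "target": pathway.target,
        "index": pathway.index,
        "steps": [[s.left, s.right, s.product] for s in pathway.steps],
    }


def pathway_from_dict(data: dict) -> AssemblyPathway:
    return AssemblyPathway(
        target=data["target"],
        steps=tuple(AssemblyStep(left=l, right=r) for l, r, _ in data["steps"]),
    )


def to_dot(obj: Construction | CatalysedConstruction) -> str:
    """GraphViz DOT rendering: solid reactant->product edges, dashed catalysis.

    Nodes are elements; a dashed edge runs from each catalyst to the product
    of the reaction it catalyses.
    """
    if isinstance(obj, CatalysedConstruction):
        construction = obj.construction
        catalysts = obj.catalysts
    else:
        construction = obj
        catalysts = {}
    lines = ["digraph construction {", "  rankdir=BT;", '  node [shape=box];']
    for e in sorted(construction.elements, key=lambda e: (e.length, e.symbols)):
        lines.append(f'  "{e.symbols}";')
    for i, r in enumerate(construction.reactions):
        lines.append(f'  "{r.left.symbols}" -> "{r.product.symbols}";')
        lines.append(f'  "{r.right.symbols}" -> "{r.product.symbols}";')
        if i in catalysts:
            lines.append(
                f'  "{catalysts[i].symbols}" -> "{r.product.symbols}" '
                "[style=dashed];"
            )
    lines.append("}")
    return "\n".join(lines)


def dump_json(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


def load_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
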