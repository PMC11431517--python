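"""Subconstruction enumeration, autocatalysis tests, amplification factor."""

import numpy as np
import pytest

from asmspace import (
    CatalysedConstruction,
    CatalystStrategy,
    Element,
    amplification_factor,
    amplify,
    assign_catalysts,
    count_autocatalytic_subsets,
    enumerate_subconstructions,
    generate_construction,
    is_autocatalytic,
    make_word,
)
from asmspace.examples import (
    consecutive_six_letter,
    eight_letter_catalysed,
    subset_verdict_example,
)


def _uncatalysed(construction):
    return CatalysedConstruction(
        construction=construction,
        catalysts={},
        p_cat=0.0,
        strategy=CatalystStrategy.UNIFORM_NO_REUSE,
    )


class TestEnumerateSubconstructions:
    def test_one_per_product(self, rng):
        for n in (2, 5, 9, 14):
            c = generate_construction(make_word(n), rng)
            subs = enumerate_subconstructions(_uncatalysed(c))
            assert len(subs) == n - 1
            assert {s.root_product for s in subs} == set(c.products)

    def test_two_symbol_word_has_single_subconstruction(self, rng):
        c = generate_construction(Element("AB"), rng)
        subs = enumerate_subconstructions(_uncatalysed(c))
        assert len(subs) == 1
        assert subs[0].root_product == Element("AB")

    def test_element_count_follows_leaf_count(self, rng):
        c = generate_construction(make_word(10), rng)
        for s in enumerate_subconstructions(_uncatalysed(c)):
            assert len(s.elements) == 2 * s.root_product.length - 1

    def test_nested_subtree_sets(self):
        """The EFG subtree of the catalysed 8-letter example."""
        subs = {
            s.root_product.symbols: s
            for s in enumerate_subconstructions(eight_letter_catalysed())
        }
        efg = subs["EFG"]
        assert efg.products == {Element("EFG"), Element("FG")}
        assert efg.constituents == {
            Element("E"), Element("F"), Element("G"), Element("FG")
        }
        assert efg.elements == {
            Element("EFG"), Element("FG"), Element("E"), Element("F"), Element("G")
        }
        assert efg.catalysts == {Element("CD"), Element("EFG")}


class TestIsAutocatalytic:
    def test_outside_catalyst_breaks_closure(self):
        subs = {
            s.root_product.symbols: s
            for s in enumerate_subconstructions(eight_letter_catalysed())
        }
        assert not is_autocatalytic(subs["EFG"])  # CD is not among its elements

    def test_whole_construction_with_any_catalyst(self):
        cc = eight_letter_catalysed()
        subs = {
            s.root_product.symbols: s for s in enumerate_subconstructions(cc)
        }
        assert is_autocatalytic(subs["ABCDEFGH"])

    def test_uncatalysed_subtree_not_vacuously_autocatalytic(self, rng):
        c = generate_construction(make_word(6), rng)
        subs = enumerate_subconstructions(_uncatalysed(c))
        assert not any(is_autocatalytic(s) for s in subs)
        assert all(is_autocatalytic(s, count_empty=True) for s in subs)

    def test_known_per_subset_verdicts(self):
        """Consecutive 6-letter example: subsets 0,1,3 autocatalytic; 2,4 not."""
        subs = enumerate_subconstructions(subset_verdict_example())
        verdicts = [is_autocatalytic(s) for s in subs]
        roots = [s.root_product.symbols for s in subs]
        assert roots == ["ABCDEF", "BCDEF", "CDEF", "DEF", "EF"]
        assert verdicts == [True, True, False, True, False]


class TestCountAutocatalyticSubsets:
    def test_uncatalysed_construction_has_k_zero(self, rng):
        c = generate_construction(make_word(8), rng)
        assert count_autocatalytic_subsets(_uncatalysed(c)) == 0

    def test_matches_per_subconstruction_verdicts(self, rng):
        """Fast recursive count agrees with the explicit enumeration route."""
        for _ in range(100):
            c = generate_construction(make_word(9), rng)
            cc = assign_catalysts(c, 0.4, CatalystStrategy.WEIGHTED_REUSE, rng)
            expected = sum(
                is_autocatalytic(s) for s in enumerate_subconstructions(cc)
            )
            assert count_autocatalytic_subsets(cc) == expected

    def test_verdict_example_counts_three(self):
        assert count_autocatalytic_subsets(subset_verdict_example()) == 3

    def test_self_catalysed_chain_counts_every_subtree(self):
        """Each reaction catalysed by its own product: k = n - 1 (n = 4 chain)."""
        from asmspace import Construction, Reaction

        c = Construction(
            final_product=Element("ABCD"),
            reactions=(
                Reaction(Element("ABC"), Element("D"), Element("ABCD"), 0),
                Reaction(Element("AB"), Element("C"), Element("ABC"), 1),
                Reaction(Element("A"), Element("B"), Element("AB"), 2),
            ),
        )
        cc = CatalysedConstruction(
            construction=c,
            catalysts={i: r.product for i, r in enumerate(c.reactions)},
            p_cat=1.0,
            strategy=CatalystStrategy.WEIGHTED_REUSE,
        )
        assert count_autocatalytic_subsets(cc) == 3

    def test_root_exclusion_switch(self):
        cc = subset_verdict_example()
        assert count_autocatalytic_subsets(cc, include_root=False) == 2

    def test_k_bounded_by_subconstruction_count(self, rng):
        for _ in range(50):
            c = generate_construction(make_word(12), rng)
            cc = assign_catalysts(c, 0.8, CatalystStrategy.UNIFORM_NO_REUSE, rng)
            assert 0 <= count_autocatalytic_subsets(cc) <= 11

    def test_adding_inside_catalyst_never_decreases_k(self, rng):
        """Catalysing an uncatalysed subtree from within turns it autocatalytic."""
        for _ in range(50):
            c = generate_construction(make_word(8), rng)
            cc = assign_catalysts(c, 0.3, CatalystStrategy.WEIGHTED_REUSE, rng)
            k_before = count_autocatalytic_subsets(cc)
            subs = enumerate_subconstructions(cc)
            empty = [s for s in subs if not s.catalysts and s.root_product.length > 1]
            if not empty:
                continue
            target = empty[0]
            # catalyse the reaction producing the subtree root with an element
            # drawn from inside the subtree
            idx = next(
                i for i, r in enumerate(c.reactions) if r.product == target.root_product
            )
            new_cats = dict(cc.catalysts)
            new_cats[idx] = sorted(target.elements, key=lambda e: e.symbols)[0]
            perturbed = CatalysedConstruction(
                construction=c, catalysts=new_cats, p_cat=cc.p_cat,
                strategy=CatalystStrategy.WEIGHTED_REUSE,
            )
            k_after = count_autocatalytic_subsets(perturbed)
            assert k_after >= k_before
            sub_after = {
                s.root_product: s for s in enumerate_subconstructions(perturbed)
            }[target.root_product]
            assert is_autocatalytic(sub_after)


class TestAmplificationFactor:
    @pytest.mark.parametrize("k,expected", [(0, 1), (1, 4), (2, 9), (5, 36)])
    def test_values(self, k, expected):
        assert amplification_factor(k) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            amplification_factor(-1)

    def test_strictly_increasing(self):
        values = [amplification_factor(k) for k in range(10)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_amplify_bundles_count_and_multiplicity(self):
        result = amplify(subset_verdict_example())
        assert result.k == 3
        assert result.multiplicity == 16
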