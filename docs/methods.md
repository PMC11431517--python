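# Methods

## Model

A final product `X` is a word of `n` distinct symbols in ascending
alphabetical order (default alphabet: the 26 uppercase letters; longer
words require an explicit custom alphabet). A *construction* is a full
binary tree of join reactions produced by recursive product decomposition:
a product of length `L` is split at a cut position drawn uniformly from
`{1, …, L−1}`, and both fragments are decomposed recursively. Splits are
contiguous, which together with the sorted-alphabet convention makes every
element a contiguous block of the word. A construction of an `n`-symbol
word always has `n − 1` reactions, `n − 2` intermediate products, and an
element set `E` (all products plus all constituents, the single symbols
included) of exactly `2n − 1` distinct members.

**Split distribution.** Uniform-over-cuts is a modelling choice — the
simplest reading of "randomly split". It does *not* induce a uniform
distribution over tree shapes: a fully consecutive chain of `n` leaves has
probability `2/(n−1)!·…` terms different from any individual balanced
shape. All distributional statements in the tests therefore use the
induced (non-uniform) distribution, computed by exhaustive enumeration at
small `n`. Results that depend on this choice (mean depths, separations)
would shift under a different split law; the qualitative bias mechanism
would not.

**Depth.** The root reaction has layer 0; a reaction's layer is its
distance from the root. Depth = 1 + max layer = longest chain of
consecutive reactions from a symbol to the final product. Bounds:
`⌈log₂ n⌉ ≤ depth ≤ n − 1`, with the lower bound attained by balanced
builds and the upper by the consecutive chain. Under the model's no-reuse
rule the assembly index of a unique-symbol word is exactly `n − 1`
regardless of tree shape, so depth — not join count — is the quantity
that distinguishes pathways.

## Catalysis

Each reaction independently receives a catalyst with probability
`p_cat ∈ [0, 1]` (one coin per reaction, drawn in pre-order). Catalysts
come from the construction's *full* element set `E`, including the final
product and including elements of the reaction being catalysed —
self-catalysis is deliberately allowed, since catalytic closure of a
subtree containing its own root is exactly the autocatalytic motif of
interest. Two strategies:

- **uniform-no-reuse** — all elements equally likely, and no element may
  catalyse two reactions. The distinct catalysts for all catalysed
  reactions are drawn jointly (uniformly over subsets of `E`), which is
  distributionally identical to sequential draws without replacement and
  removes any dependence on processing order. The pool never runs dry:
  `|E| = 2n − 1 > n − 1` reactions.
- **weighted-reuse** — element `e` has weight `len(e) / max len over E`,
  normalised; draws are independent with replacement, weights computed
  once over `E` (no renormalisation between draws).

Under both strategies the number of catalysed reactions is
binomial(`n − 1`, `p_cat`).

## Autocatalysis and amplification

Every product (the final product included) roots a subconstruction with
its own product, constituent, element and catalyst sets; a construction of
an `n`-symbol word has `n − 1` subconstructions. A subconstruction is
**autocatalytic** iff it carries at least one catalyst and all its
catalysts lie within its own element set.

Two definitional choices the bare closure condition leaves open:

- *Vacuous subtrees*: a subtree with zero catalysts is **not** counted as
  autocatalytic. Counting it would give `k = n − 1` for every uncatalysed
  construction, destroying the `k = 0` baseline at `p_cat = 0`; requiring
  ≥ 1 catalyst extends the construction-level definition downward
  consistently. Exposed as `count_empty` for sensitivity analysis.
- *Root inclusion*: the whole construction counts toward `k` once it has
  any catalyst (it is then autocatalytic by definition, all catalysts
  coming from its own element set), so every catalysed construction has
  `k ≥ 1` and multiplicity ≥ 4. Exposed as `include_root` /
  `include_root_in_k` (default: include).

With `k` autocatalytic subconstructions a construction contributes its
depth with multiplicity 1 (`k = 0`) or `(1 + k)²` — exponential
autocatalytic amplification. Multiplicities are stored as integer weights;
the weighted mean is identical to literally duplicating entries.

## Experiment grid

Default conditions: `p_cat ∈ {0.0, 0.1, …, 1.0}`
(11 values), lengths 6–20 (15 values), both strategies, amplification
on/off — 660 cells of `n_samples = 10,000` each. Each (p_cat, length,
strategy) combination is seeded from a stable `SeedSequence` over
(global seed, round(p_cat·1000), length, strategy code), so any sub-grid
reproduces the corresponding cells of the full grid bit for bit.
Amplification adds no randomness — it is a deterministic reweighting — so
on/off cells share the same draws; at `p_cat = 0` the two distributions
are consequently *identical*, not merely statistically close, and the
baseline-subtracted separation is exactly zero there.

**Separation** of a cell = its mean depth minus that of the matched
baseline cell (uniform-no-reuse, amplification off) at the same `p_cat`
and length. `separation_test` reports the amplified-minus-unamplified
difference at one grid point with a combined (root-sum-square)
Monte-Carlo standard error of the two cells and calls it significant
beyond 3 combined SEs; because the cells share draws, this combined SE is
conservative. The standard error of an amplified (weighted) mean uses the
ratio-estimator delta method, `sd(w·(d − μ)) / (w̄·√n)`, which reduces to
the usual `sd/√n` at unit weights.

**Problem sizes in the test suite.** Distribution-level checks run at
sizes where Monte-Carlo error is well below the asserted tolerances:
20,000 samples for tree-shape total-variation (< 0.03) and for the exact
mean-depth comparison (3 SE), 10,000 draws for binomial goodness-of-fit
(α = 0.001), 50,000 single draws for weighted-selection frequencies, and
a reduced qualitative grid of lengths {6, 10, 14} × p_cat
{0.0, 0.1, 0.5, 1.0} × 2,000 samples at seed 0 for the bias readout.

## Exact assembly index (reuse allowed)

For arbitrary strings (repeats permitted) the solver finds the minimal
number of pairwise joins, where single symbols are free and any object
built once may be reused. Search design:

- *Substring restriction*: some minimal pathway builds only contiguous
  substrings of the target — the target is produced by a join tree whose
  node products are contiguous substrings, and steps unused by that tree
  can be dropped — so the search space is restricted to those without
  loss.
- *Iterative deepening* over the step count, from the lower bound
  `⌈log₂ n⌉` (lengths at most double per join) to the greedy upper bound
  `n − 1`; states (sets of built substrings) are memoised per budget so no
  state is re-explored with an equal or smaller remaining budget.
  Candidate products are tried longest-first, then lexicographically,
  making the returned pathway deterministic.
- Degenerate inputs: a single symbol yields the empty pathway (index 0);
  an empty target is a `ValueError`; targets beyond 20 symbols or searches
  exceeding the node budget raise an explicit `AssemblySearchError` —
  never a silent wrong answer. Returned pathways are re-validated by
  replay before being returned.

## What the generator does and does not emulate

The synthetic words are idealised objects: unique symbols, strictly
binary joins, no reuse inside the toy model, catalysis as a bare
probability with no kinetics, rates or efficiencies, and no food-set
semantics beyond free single symbols. Passing tests demonstrate the
internal consistency of this abstraction and the robustness of the
bias mechanism within it — they say nothing about real reaction networks,
molecular assembly measurements, or RAF detection on general catalytic
reaction systems, all of which are out of scope.

## Known limitations

- Mean-depth magnitudes depend on the uniform-cut split law (see above);
  only signs, orderings and exact zero cases are asserted.
- The weighted/unweighted null result is a non-rejection at 3 SE, not an
  equivalence proof.
- The solver's practical target length (≤ 20 symbols) reflects the
  exponential state space; longer targets need a different algorithm, not
  a bigger budget.
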