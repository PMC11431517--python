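# asmspace

Monte-Carlo toy model linking assembly theory and autocatalytic sets.

The package samples *assembly spaces* — the sets of all binary
construction trees of a word of unique symbols such as `ABCDEF` — assigns
catalysts to reactions probabilistically, tests every subconstruction for
autocatalysis (catalytic closure at the subtree level), and amplifies each
construction's contribution to the depth distribution by `(1 + k)²`, where
`k` counts its autocatalytic subconstructions. The measured readout is the
*separation*: the amplified mean construction depth minus the unamplified
baseline. It quantifies how much autocatalysis biases assembly toward long
consecutive reaction chains rather than parallel builds, as a function of
the per-reaction catalysis probability `p_cat` and the object length. A
companion exact solver computes the classical assembly index of arbitrary
strings, where reuse of already-built fragments *is* allowed.

Intended users: researchers in origin-of-life modelling, chemical reaction
networks and complexity science who want a minimal, fully reproducible
sandbox for the interplay of pathway probability, catalysis and assembly
depth.

## The model in brief

- A word `X` of `n` distinct, alphabetically ordered symbols is built by a
  full binary tree of join reactions `[left] + [right] → [product]`, each
  product split at a uniformly random contiguous cut. Every construction
  has `n − 1` reactions and an element set `E` (products ∪ constituents)
  of `2n − 1` members.
- The **depth** of a construction is the longest chain of consecutive
  reactions from a symbol to the root; `minDepth(X) = ⌈log₂ n⌉` (balanced
  build), the maximum is `n − 1` (fully consecutive chain). Under the
  no-reuse rule the assembly index of a unique-symbol word is trivially
  `n − 1`; depth is the discriminating proxy.
- Each reaction is independently catalysed with probability `p_cat`; the
  catalyst is drawn from `E` either uniformly without reuse, or
  length-weighted (`W(e) = len(e)/max len`) with reuse.
- A subconstruction (subtree rooted at any product) is **autocatalytic**
  when it has ≥ 1 catalyst and all its catalysts lie inside its own
  element set. With `k` autocatalytic subconstructions, a construction
  enters the depth distribution with multiplicity `(1 + k)²`.
- The experiment grid sweeps `p_cat ∈ {0.0, 0.1, …, 1.0}`, lengths 6–20,
  both catalyst strategies and amplification on/off — 660 distribution
  cells of 10,000 samples each by default.

## Worked example

Sample a 2,000-construction assembly space of `ABCDEF` at `p_cat = 0.1`
with amplification:

```bash
$ asmspace sample ABCDEF --p-cat 0.1 -n 2000 --seed 42
mean depth: 3.9230
```

The unamplified expectation of the depth of a random `ABCDEF` construction
is exactly 3.8 (computable by enumerating all 42 tree shapes); the
amplified mean of 3.9230 sits above it — autocatalytic weighting favours
deeper, more consecutive constructions.

The same bias across a reduced grid (lengths {6, 10, 14}, 2,000 samples,
seed 0), at length 14:

```
p_cat=0.0: separation=+0.000  z=0.0
p_cat=0.1: separation=+0.231  z=4.8
p_cat=0.5: separation=+0.115  z=2.7
p_cat=1.0: separation=+0.006  z=0.2
```

Separation is exactly zero without catalysis, strongest at a *low*
catalysis probability of 0.1, and washes out as catalysis saturates —
autocatalysis favours consecutive builds precisely when catalysis is
scarce.

The exact solver, with reuse:

```bash
$ asmspace assembly-index ABRACADABRA
Step1: A+B->AB
...
Step7: ABRACAD+ABRA->ABRACADABRA
assembly index of ABRACADABRA: 7
```

Eleven characters, but only 7 joins: the already-built `ABRA` is reused in
the final step.

Full grids run from a YAML config (`examples/grid_demo.yaml` ships a
24-cell demonstration):

```bash
asmspace grid --config examples/grid_demo.yaml --out scratch/demo --plots
```

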