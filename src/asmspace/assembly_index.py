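"""Exact assembly index of an arbitrary symbol string, with reuse allowed.

Here repeats are permitted and — crucially — an object built once can be
reused in later joins, e.g. building ``ABRACADABRA`` in 7 steps by reusing
``ABRA``.  The minimal number of pairwise joins over all such pathways is
the assembly index; this module finds it exactly by iterative-deepening
depth-first search with memoisation.

Why the search may restrict itself to contiguous substrings of the target:
the final product is produced by a binary join tree whose leaves are single
symbols, and the product of every node of that tree is the concatenation of
its leaf symbols in order — a contiguous substring of the target.  Any step
of a minimal pathway whose product is used nowhere in that tree can be
dropped without affecting the result, so some minimal pathway builds only
contiguous substrings.  Searching over those alone is therefore lossless.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AssemblyStep",
    "AssemblyPathway",
    "AssemblySearchError",
    "exact_assembly_index",
]

MAX_TARGET_LENGTH = 20


class AssemblySearchError(RuntimeError):
    """Raised when the search budget or the practical length bound is exceeded."""


@dataclass(frozen=True, slots=True)
class AssemblyStep:
    left: str
    right: str

    @property
    def product(self) -> str:
        return self.left + self.right

    def __str__(self) -> str:
        return f"{self.left}+{self.right}->{self.product}"


@dataclass(frozen=True)
class AssemblyPathway:
    """An ordered list of joins building ``target``; ``index`` = step count."""

    target: str
    steps: tuple[AssemblyStep, ...]

    @property
    def index(self) -> int:
        return len(self.steps)

    def validate(self) -> None:
        """Replay the steps; raise if any operand is neither a symbol nor built."""
        available = set(self.target)  # single symbols are free
        for step in self.steps:
            for operand in (step.left, step.right):
                if len(operand) > 1 and operand not in available:
                    raise ValueError(f"operand {operand!r} not available when used")
            available.add(step.product)
        if self.steps:
            if self.steps[-1].product != self.target:
                raise ValueError("final step does not produce the target")
        elif len(self.target) != 1:
            raise ValueError("empty pathway for a multi-symbol target")

    def __str__(self) -> str:
        return "\n".join(
            f"Step{i}: {s.left}+{s.right}->{s.product}"
            for i, s in enumerate(self.steps, start=1)
        )


def _greedy_pathway(target: str) -> tuple[AssemblyStep, ...]:
    """Left-to-right appending pathway; index = len(target) - 1 upper bound."""
    steps = []
    for i in range(1, len(target)):
        steps.append(AssemblyStep(left=target[: i], right=target[i]))
    return tuple(steps)


def exact_assembly_index(
    target: str,
    *,
    max_length: int = MAX_TARGET_LENGTH,
    node_budget: int = 20_000_000,
) -> AssemblyPathway:
    """Minimal pairwise-join pathway assembling ``target``, reuse allowed.

    Iterative deepening over the number of steps, starting from the
    information-theoretic lower bound ``ceil(log2 len(target))`` (object
    length can at most double per join) up to the greedy upper bound
    ``len(target) - 1``.  States are sets of built substrings, memoised so a
    state is never re-explored with an equal or smaller step budget.

    Raises
    ------
    ValueError
        for an empty target.
    AssemblySearchError
        if ``target`` exceeds ``max_length`` or the node budget runs out —
        never a silent wrong answer.
    """
    if not target:
        raise ValueError("target must be non-empty")
    n = len(target)
    if n > max_length:
        raise AssemblySearchError(
            f"target length {n} exceeds the practical bound {max_length}"
        )
    if n == 1:
        return AssemblyPathway(target=target, steps=())

    # distinct contiguous substrings of length >= 2, with their splits
    substrings: set[str] = set()
    for i in range(n):
        for j in range(i + 2, n + 1):
            substrings.add(target[i:j])

    def available(part: str, built: frozenset[str]) -> bool:
        return len(part) == 1 or part in built

    splits: dict[str, list[tuple[str, str]]] = {
        s: [(s[:c], s[c:]) for c in range(1, len(s))] for s in substrings
    }
    # candidate exploration order: longer products first, then lexicographic
    ordered = sorted(substrings, key=lambda s: (-len(s), s))

    lower = (n - 1).bit_length()  # ceil(log2 n)
    upper = n - 1
    nodes = 0
    memo: dict[frozenset[str], int] = {}

    def dfs(built: frozenset[str], remaining: int) -> list[str] | None:
        nonlocal nodes
        if target in built:
            return []
        if remaining == 0:
            return None
        nodes += 1
        if nodes > node_budget:
            raise AssemblySearchError(
                f"search budget of {node_budget} nodes exhausted for {target!r}"
            )
        # longest available object at most doubles per join
        max_len = max((len(s) for s in built), default=1)
        if max_len << remaining < n:
            return None
        if memo.get(built, -1) >= remaining:
            return None
        for s in ordered:
            if s in built:
                continue
            if any(
                available(x, built) and available(y, built) for x, y in splits[s]
            ):
                tail = dfs(built | {s}, remaining - 1)
                if tail is not None:
                    return [s] + tail
        memo[built] = remaining
        return None

    best: list[str] | None = None
    for budget in range(lower, upper + 1):
        memo.clear()
        best = dfs(frozenset(), budget)
        if best is not None:
            break
    if best is None:  # the greedy pathway guarantees this never happens
        best = [s.product for s in _greedy_pathway(target)]

    # rebuild explicit steps: for each product pick the first feasible split
    steps: list[AssemblyStep] = []
    built: set[str] = set()
    for product in best:
        for x, y in splits[product]:
            if (len(x) == 1 or x in built) and (len(y) == 1 or y in built):
                steps.append(AssemblyStep(left=x, right=y))
                break
        built.add(product)
    pathway = AssemblyPathway(target=target, steps=tuple(steps))
    pathway.validate()
    return pathway
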