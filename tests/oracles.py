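"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without touching the package's own
sampling/search code paths: exhaustive enumeration over tree shapes and
assembly pathways at tiny sizes.
"""

from __future__ import annotations

from functools import lru_cache

Interval = tuple[int, int]


def enumerate_shapes(n: int) -> list[tuple[frozenset[Interval], float]]:
    """All contiguous-split full binary tree shapes over ``n`` ordered leaves.

    Each shape is identified by the frozenset of its internal-node intervals
    ``(start, stop)`` (the root interval included); the probability is the
    product over internal nodes of ``1 / (L - 1)`` for node width ``L``,
    i.e. the chance of that shape under independent uniform cut positions.
    """

    def rec(start: int, stop: int) -> list[tuple[frozenset[Interval], float]]:
        width = stop - start
        if width == 1:
            return [(frozenset(), 1.0)]
        out = []
        for cut in range(start + 1, stop):
            for left, pl in rec(start, cut):
                for right, pr in rec(cut, stop):
                    shape = left | right | {(start, stop)}
                    out.append((frozenset(shape), pl * pr / (width - 1)))
        return out

    return rec(0, n)


def exact_depth_distribution(n: int) -> dict[int, float]:
    """Exact depth distribution of a random construction of an n-symbol word."""

    @lru_cache(maxsize=None)
    def dist(width: int) -> tuple[tuple[int, float], ...]:
        if width == 1:
            return ((0, 1.0),)
        acc: dict[int, float] = {}
        for cut in range(1, width):
            for dl, pl in dist(cut):
                for dr, pr in dist(width - cut):
                    d = 1 + max(dl, dr)
                    acc[d] = acc.get(d, 0.0) + pl * pr / (width - 1)
        return tuple(sorted(acc.items()))

    return dict(dist(n))


def exact_mean_depth(n: int) -> float:
    return sum(d * p for d, p in exact_depth_distribution(n).items())


def brute_force_assembly_index(target: str) -> int:
    """Minimal join count with reuse, by unrestricted iterative deepening.

    Independent of the package solver: candidate products are *any*
    concatenation of two available objects no longer than the target, not
    just contiguous substrings of it.  Practical only for short targets.
    """
    n = len(target)
    if n == 1:
        return 0
    symbols = sorted(set(target))

    def candidates(built: frozenset[str]) -> set[str]:
        avail = list(built) + symbols
        return {
            x + y
            for x in avail
            for y in avail
            if len(x) + len(y) <= n and x + y not in built
        }

    from math import ceil, log2

    memo: dict[frozenset[str], int] = {}

    def dfs(built: frozenset[str], remaining: int) -> bool:
        if target in built:
            return True
        if remaining == 0:
            return False
        max_len = max((len(s) for s in built), default=1)
        if max_len * (2 ** remaining) < n:
            return False
        if memo.get(built, -1) >= remaining:
            return False
        for product in sorted(candidates(built)):
            if dfs(built | {product}, remaining - 1):
                return True
        memo[built] = remaining
        return False

    for budget in range(ceil(log2(n)), n):
        memo.clear()
        if dfs(frozenset(), budget):
            return budget
    return n - 1
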