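"""Monte-Carlo sampling of assembly spaces across an experimental grid.

For each grid cell — a (catalysis probability, word length, catalyst
strategy, amplification on/off) combination — a sample assembly space of
``n_samples`` random catalysed constructions is drawn and summarised by its
average construction depth.  With amplification on, each construction
contributes its depth with multiplicity ``(1 + k)^2`` where ``k`` is its
autocatalytic-subset count; the *separation* of a cell is its mean depth
minus that of the matched baseline cell (uniform catalysts, no
amplification) at the same probability and length, the readout for the
autocatalysis-induced bias toward consecutive builds.

Amplification adds no randomness of its own: on/off cells at the same
(probability, length, strategy) share the same sampled constructions and
differ only in multiplicities, so at ``p_cat = 0`` they are exactly equal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autocat import amplification_factor, count_autocatalytic_subsets
from .catalysis import CatalystStrategy, assign_catalysts
from .core import DEFAULT_ALPHABET, generate_construction, make_word

__all__ = [
    "ExperimentConfig",
    "DepthDistribution",
    "GridSummary",
    "SeparationReport",
    "sample_assembly_space",
    "run_grid",
    "separation_test",
]

DEFAULT_P_CAT = tuple(round(i / 10, 1) for i in range(11))
DEFAULT_LENGTHS = tuple(range(6, 21))

_STRATEGY_CODE = {
    CatalystStrategy.UNIFORM_NO_REUSE: 0,
    CatalystStrategy.WEIGHTED_REUSE: 1,
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experimental grid specification.

    Default grid: 11 catalysis probabilities x 15 word lengths x 2
    strategies x 2 amplification settings = 660 distribution cells of
    10,000 samples each.
    """

    p_cat_values: tuple[float, ...] = DEFAULT_P_CAT
    lengths: tuple[int, ...] = DEFAULT_LENGTHS
    strategies: tuple[CatalystStrategy, ...] = (
        CatalystStrategy.UNIFORM_NO_REUSE,
        CatalystStrategy.WEIGHTED_REUSE,
    )
    amplification: tuple[bool, ...] = (False, True)
    n_samples: int = 10_000
    seed: int = 0
    include_root_in_k: bool = True
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.p_cat_values):
            raise ValueError("catalysis probabilities must lie in [0, 1]")
        if not all(l >= 2 for l in self.lengths):
            raise ValueError("word lengths must be >= 2")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        object.__setattr__(
            self,
            "strategies",
            tuple(CatalystStrategy(s) for s in self.strategies),
        )

    @property
    def n_cells(self) -> int:
        return (
            len(self.p_cat_values)
            * len(self.lengths)
            * len(self.strategies)
            * len(self.amplification)
        )

    def cells(self):
        """Iterate (p_cat, length, strategy, amplification) over the grid."""
        return itertools.product(
            self.p_cat_values, self.lengths, self.strategies, self.amplification
        )

    # ---- YAML round-trip ---------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "p_cat_values",
            "lengths",
            "strategies",
            "amplification",
            "n_samples",
            "seed",
            "include_root_in_k",
            "alphabet",
        ):
            if key in raw:
                value = raw[key]
                kwargs[key] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "p_cat_values": list(self.p_cat_values),
            "lengths": list(self.lengths),
            "strategies": [s.value for s in self.strategies],
            "amplification": list(self.amplification),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "include_root_in_k": self.include_root_in_k,
            "alphabet": self.alphabet,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def with_(self, **kwargs) -> "ExperimentConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DepthDistribution:
    """Observed construction depths with amplification multiplicities.

    Multiplicities are stored as integer weights rather than duplicated
    entries; the weighted mean is identical to literal duplication.
    """

    depths: np.ndarray
    multiplicities: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=np.int64)
        mult = np.asarray(self.multiplicities, dtype=np.int64)
        if depths.shape != mult.shape:
            raise ValueError("depths and multiplicities must have equal length")
        if np.any(mult < 1):
            raise ValueError("multiplicities must be positive integers")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "multiplicities", mult)

    @property
    def n_samples(self) -> int:
        return self.depths.size

    @property
    def total_multiplicity(self) -> int:
        return int(self.multiplicities.sum())

    @property
    def mean_depth(self) -> float:
        return float(np.average(self.depths, weights=self.multiplicities))

    @property
    def sd_depth(self) -> float:
        mu = self.mean_depth
        var = np.average((self.depths - mu) ** 2, weights=self.multiplicities)
        return float(np.sqrt(var))

    @property
    def se_mean(self) -> float:
        """Monte-Carlo standard error of the weighted mean (ratio estimator).

        Treats each (depth, multiplicity) pair as one i.i.d. draw; for unit
        multiplicities this reduces to the usual sd / sqrt(n).
        """
        n = self.n_samples
        if n < 2:
            return float("nan")
        w = self.multiplicities.astype(float)
        d = self.depths.astype(float)
        mu = self.mean_depth
        resid = w * (d - mu)
        return float(np.sqrt(resid.var(ddof=1) / n) / w.mean())


@dataclass(frozen=True)
class SeparationReport:
    """Amplified-minus-baseline mean-depth comparison at one grid point."""

    p_cat: float
    length: int
    strategy: CatalystStrategy
    difference: float
    se_combined: float
    z: float

    @property
    def significant(self) -> bool:
        """Whether the difference exceeds 3 combined standard errors."""
        return abs(self.z) > 3.0


def _cell_seed(seed: int, p_cat: float, length: int, strategy: CatalystStrategy):
    """Stable per-cell seed sequence; amplification shares the same draws."""
    return np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, int(round(p_cat * 1000)), int(length),
         _STRATEGY_CODE[CatalystStrategy(strategy)]]
    )


def _sample_depths_and_k(
    length: int,
    p_cat: float,
    strategy: CatalystStrategy,
    n_samples: int,
    rng: np.random.Generator,
    *,
    include_root: bool = True,
    alphabet: str = DEFAULT_ALPHABET,
) -> tuple[np.ndarray, np.ndarray]:
    word = make_word(length, alphabet)
    depths = np.empty(n_samples, dtype=np.int64)
    ks = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        construction = generate_construction(word, rng)
        cc = assign_catalysts(construction, p_cat, strategy, rng)
        depths[i] = construction.depth
        ks[i] = count_autocatalytic_subsets(cc, include_root=include_root)
    return depths, ks


def sample_assembly_space(
    length: int,
    p_cat: float,
    strategy: CatalystStrategy | str,
    amplification: bool,
    n_samples: int,
    rng: np.random.Generator,
    *,
    include_root: bool = True,
    alphabet: str = DEFAULT_ALPHABET,
) -> DepthDistribution:
    """Draw a sample assembly space and return its depth distribution.

    Each of the ``n_samples`` independent draws generates a random
    construction of the canonical ``length``-symbol word, assigns catalysts
    with probability ``p_cat`` under ``strategy``, and contributes its depth
    with multiplicity 1 (``amplification=False``) or ``(1 + k)^2``
    (``amplification=True``).
    """
    if length < 2:
        raise ValueError("word length must be >= 2")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    strategy = CatalystStrategy(strategy)
    depths, ks = _sample_depths_and_k(
        length, p_cat, strategy, n_samples, rng,
        include_root=include_root, alphabet=alphabet,
    )
    if amplification:
        mult = np.array([amplification_factor(int(k)) for k in ks], dtype=np.int64)
    else:
        mult = np.ones_like(depths)
    return DepthDistribution(depths=depths, multiplicities=mult)


@dataclass(frozen=True)
class GridSummary:
    """Per-cell summary table of a full grid run.

    ``table`` has one row per (p_cat, length, strategy, amplification) cell
    with columns mean_depth, sd_depth, se_mean, n_samples,
    total_multiplicity and separation (cell mean minus the
    uniform-no-reuse / amplification-off mean at the same p_cat and length;
    NaN when that baseline cell is not part of the grid).
    """

    table: pd.DataFrame
    config: ExperimentConfig = field(compare=False)

    def cell(
        self,
        p_cat: float,
        length: int,
        strategy: CatalystStrategy | str,
        amplification: bool,
    ) -> pd.Series:
        strategy = CatalystStrategy(strategy).value
        t = self.table
        match = t[
            np.isclose(t["p_cat"], p_cat)
            & (t["length"] == length)
            & (t["strategy"] == strategy)
            & (t["amplification"] == amplification)
        ]
        if match.empty:
            raise KeyError(
                f"no grid cell at p_cat={p_cat}, length={length}, "
                f"strategy={strategy}, amplification={amplification}"
            )
        return match.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def run_grid(config: ExperimentConfig, *, progress: bool = False) -> GridSummary:
    """Run every cell of the configured grid and summarise it.

    Cells are seeded independently from a stable hash of
    (seed, p_cat, length, strategy), so any sub-grid reproduces the
    corresponding cells of the full grid bit for bit; amplification on/off
    reuse the same draws by design.
    """
    rows = []
    for p_cat in config.p_cat_values:
        for length in config.lengths:
            for strategy in config.strategies:
                rng = np.random.default_rng(
                    _cell_seed(config.seed, p_cat, length, strategy)
                )
                depths, ks = _sample_depths_and_k(
                    length, p_cat, strategy, config.n_samples, rng,
                    include_root=config.include_root_in_k,
                    alphabet=config.alphabet,
                )
                for amplification in config.amplification:
                    if amplification:
                        mult = np.array(
                            [amplification_factor(int(k)) for k in ks],
                            dtype=np.int64,
                        )
                    else:
                        mult = np.ones_like(depths)
                    dist = DepthDistribution(depths=depths, multiplicities=mult)
                    rows.append(
                        {
                            "p_cat": p_cat,
                            "length": length,
                            "strategy": strategy.value,
                            "amplification": amplification,
                            "n_samples": dist.n_samples,
                            "mean_depth": dist.mean_depth,
                            "sd_depth": dist.sd_depth,
                            "se_mean": dist.se_mean,
                            "total_multiplicity": dist.total_multiplicity,
                        }
                    )
                if progress:
                    print(
                        f"cell p_cat={p_cat} length={length} "
                        f"strategy={strategy.value} done"
                    )
    table = pd.DataFrame(rows)

    # baseline-subtracted separation per (p_cat, length)
    base_strategy = CatalystStrategy.UNIFORM_NO_REUSE.value
    baseline = table[
        (table["strategy"] == base_strategy) & (~table["amplification"])
    ].set_index(["p_cat", "length"])["mean_depth"]
    separations = []
    for _, row in table.iterrows():
        key = (row["p_cat"], row["length"])
        separations.append(
            row["mean_depth"] - baseline[key] if key in baseline.index else np.nan
        )
    table["separation"] = separations
    return GridSummary(table=table, config=config)


def separation_test(
    summary: GridSummary,
    p_cat: float,
    length: int,
    strategy: CatalystStrategy | str = CatalystStrategy.UNIFORM_NO_REUSE,
) -> SeparationReport:
    """Compare amplified vs unamplified mean depth at one grid point.

    Reports the mean-depth difference, the combined (root-sum-square)
    Monte-Carlo standard error of the two cells, and the z-like ratio; the
    difference is called significant beyond 3 combined standard errors.
    At ``p_cat = 0`` the difference is exactly zero because the two cells
    share their draws and every multiplicity is one.
    """
    strategy = CatalystStrategy(strategy)
    on = summary.cell(p_cat, length, strategy, True)
    off = summary.cell(p_cat, length, strategy, False)
    difference = float(on["mean_depth"] - off["mean_depth"])
    se = float(np.hypot(on["se_mean"], off["se_mean"]))
    z = difference / se if se > 0 else (0.0 if difference == 0 else np.inf)
    return SeparationReport(
        p_cat=p_cat,
        length=length,
        strategy=strategy,
        difference=difference,
        se_combined=se,
        z=float(z),
    )
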