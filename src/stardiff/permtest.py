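"""Label-permutation robustness tests of a two-class partition.

The test statistic for a candidate partition is the number of fragments
called differentially expressed (BH FDR below ``alpha``) by the full
two-class pipeline — normalization, dispersion estimation and the exact
test are all recomputed inside every permutation.

Two schemes are provided: a *sorted* test that exhaustively enumerates the
near-observed reassignments (single moves, reciprocal single swaps,
reciprocal double swaps), and an *unsorted* test that draws random
equal-size repartitions of the libraries.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np

from . import de
from .io import CountMatrix, LibraryMeta


@dataclasses.dataclass(frozen=True)
class Partition:
    """One assignment of libraries to the two contrast classes."""

    class_a: frozenset
    class_b: frozenset
    category: str  # observed | move1 | swap1 | swap2 | random
    moved: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        # the permutation constructors keep class sizes (nearly) equal; the
        # type itself only requires a genuine two-class split
        if self.class_a & self.class_b:
            raise ValueError("partition classes must be disjoint")
        if not self.class_a or not self.class_b:
            raise ValueError("both classes must be non-empty")


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    """Observed DE count against a label-permutation distribution."""

    observed_stat: int
    alpha: float
    entries: list[tuple[Partition, int]]
    percentile: float
    libraries_in_exceeding: frozenset
    pit: float | None = None  # randomized PIT of the observed statistic

    def to_dict(self) -> dict:
        return {
            "observed": self.observed_stat,
            "alpha": self.alpha,
            "percentile": self.percentile,
            "pit": self.pit,
            "libraries_in_exceeding": sorted(self.libraries_in_exceeding),
            "permutations": [
                {
                    "class_a": sorted(p.class_a),
                    "class_b": sorted(p.class_b),
                    "category": p.category,
                    "moved_libraries": list(p.moved),
                    "de_count": int(c),
                }
                for p, c in self.entries
            ],
        }


def de_count_statistic(
    matrix: CountMatrix,
    partition: Partition,
    alpha: float = 0.01,
    dispersion: str = "tagwise",
) -> int:
    """Number of fragments with FDR < alpha under the full two-class pipeline."""
    libs_a, libs_b = sorted(partition.class_a), sorted(partition.class_b)
    if len(libs_a) < 2 or len(libs_b) < 2:
        raise ValueError("each class needs at least 2 libraries")
    result = de.two_group_de(matrix, libs_a, libs_b, dispersion=dispersion)
    return int((result["fdr"] < alpha).sum())


def observed_partition(meta: LibraryMeta, treatment: str | None = "ambient") -> Partition:
    """The genotype partition defined by the metadata (class A wild, B ins)."""
    wild = meta.libraries(genotype="wild", treatment=treatment)
    ins = meta.libraries(genotype="ins", treatment=treatment)
    return Partition(frozenset(wild), frozenset(ins), "observed")


def enumerate_sorted_reassignments(observed: Partition) -> list[Partition]:
    """All single moves, reciprocal 1-swaps, and reciprocal 2-swaps.

    Exactly n_A + n_B move1, n_A*n_B swap1 and C(n_A,2)*C(n_B,2) swap2
    partitions; the observed partition itself is excluded.
    """
    A = sorted(observed.class_a)
    B = sorted(observed.class_b)
    out: list[Partition] = []
    for a in A:
        out.append(Partition(frozenset(set(A) - {a}), frozenset(set(B) | {a}), "move1", (a,)))
    for b in B:
        out.append(Partition(frozenset(set(A) | {b}), frozenset(set(B) - {b}), "move1", (b,)))
    for a in A:
        for b in B:
            out.append(
                Partition(
                    frozenset(set(A) - {a} | {b}),
                    frozenset(set(B) - {b} | {a}),
                    "swap1",
                    (a, b),
                )
            )
    if len(A) < 2 or len(B) < 2:
        raise ValueError("reciprocal 2-swaps need at least 2 libraries per class")
    for a1, a2 in itertools.combinations(A, 2):
        for b1, b2 in itertools.combinations(B, 2):
            out.append(
                Partition(
                    frozenset(set(A) - {a1, a2} | {b1, b2}),
                    frozenset(set(B) - {b1, b2} | {a1, a2}),
                    "swap2",
                    (a1, a2, b1, b2),
                )
            )
    return out


def _summarize(
    observed_stat: int,
    entries: list[tuple[Partition, int]],
    alpha: float,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    counts = np.array([c for _, c in entries])
    n_less = int((counts < observed_stat).sum())
    percentile = 100.0 * n_less / len(entries)
    exceeding: set = set()
    for p, c in entries:
        if c > observed_stat:
            exceeding.update(p.moved if p.moved else (p.class_a | p.class_b))
    pit = None
    if rng is not None:
        # randomized PIT: uniform under exchangeability despite ties
        ties = int((counts == observed_stat).sum())
        pit = 100.0 * (n_less + rng.uniform() * (ties + 1)) / (len(entries) + 1)
    return PermutationResult(
        observed_stat, alpha, entries, percentile, frozenset(exceeding), pit
    )


def sorted_permutation_test(
    matrix: CountMatrix,
    meta: LibraryMeta,
    alpha: float = 0.01,
    treatment: str | None = "ambient",
    dispersion: str = "tagwise",
) -> PermutationResult:
    """Exhaustive near-observed reassignment test of the genotype partition."""
    obs = observed_partition(meta, treatment)
    observed_stat = de_count_statistic(matrix, obs, alpha, dispersion)
    entries = [
        (p, de_count_statistic(matrix, p, alpha, dispersion))
        for p in enumerate_sorted_reassignments(obs)
    ]
    return _summarize(observed_stat, entries, alpha)


def unsorted_permutation_test(
    matrix: CountMatrix,
    meta: LibraryMeta,
    K: int = 500,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
    treatment: str | None = "ambient",
    dispersion: str = "tagwise",
) -> PermutationResult:
    """Random equal-size repartition test of the genotype partition.

    Draws K partitions uniformly over the distinct unordered equal splits
    (the observed split may recur); duplicates across draws are allowed.
    """
    obs = observed_partition(meta, treatment)
    libs = sorted(obs.class_a | obs.class_b)
    if len(libs) % 2:
        raise ValueError("unsorted permutation needs an even library count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed_stat = de_count_statistic(matrix, obs, alpha, dispersion)
    half = len(libs) // 2
    entries = []
    for _ in range(K):
        perm = rng.permutation(libs)
        a, b = frozenset(perm[:half]), frozenset(perm[half:])
        part = Partition(a, b, "random", tuple(sorted(obs.class_a - a)))
        entries.append((part, de_count_statistic(matrix, part, alpha, dispersion)))
    return _summarize(observed_stat, entries, alpha, rng=rng)
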