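"""Library-size normalization: CPM, expression filtering, and TMM factors.

TMM (trimmed mean of M-values) estimates a composition factor per library
from weighted, doubly-trimmed log-ratios against a reference library; the
effective library size is ``library_size * factor``, and factors are scaled
to geometric mean 1 so they carry composition only, not depth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import CountMatrix


@dataclasses.dataclass(frozen=True)
class NormFactors:
    """Per-library TMM-style normalization factors (geometric mean 1)."""

    library_ids: tuple[str, ...]
    factors: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if f.shape != (len(self.library_ids),):
            raise ValueError("one factor per library required")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("normalization factors must be finite and positive")
        object.__setattr__(self, "factors", f)
        object.__setattr__(self, "library_ids", tuple(self.library_ids))

    @classmethod
    def unit(cls, library_ids) -> "NormFactors":
        return cls(tuple(library_ids), np.ones(len(tuple(library_ids))))

    def effective_sizes(self, matrix: CountMatrix) -> np.ndarray:
        if tuple(matrix.library_ids) != self.library_ids:
            raise ValueError("factor/library id mismatch")
        return matrix.library_sizes.astype(float) * self.factors


def cpm(matrix: CountMatrix, factors: NormFactors | None = None) -> np.ndarray:
    """Counts per million over (effective) library sizes."""
    if factors is None:
        sizes = matrix.library_sizes.astype(float)
    else:
        sizes = factors.effective_sizes(matrix)
    if np.any(sizes <= 0):
        bad = matrix.library_ids[int(np.argmax(sizes <= 0))]
        raise ValueError(f"library {bad!r} has zero total count")
    return matrix.counts / sizes * 1e6


def filter_expressed(
    matrix: CountMatrix, cpm_threshold: float = 1.0, min_libraries: int = 2
) -> CountMatrix:
    """Keep fragments with CPM strictly above threshold in >= min_libraries.

    CPM is computed with unit factors (raw library sizes): the filter runs
    before between-library normalization.
    """
    c = cpm(matrix)
    keep = (c > cpm_threshold).sum(axis=1) >= min_libraries
    return matrix.select_fragments(keep)


def tmm_factors(
    matrix: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values factors.

    Per library, the factor is 2**(weighted trimmed mean of per-fragment
    log2 ratios M against a reference library), the weights being inverse
    asymptotic binomial variances; fragments trimmed by the most extreme
    ``trim_m`` of M and ``trim_a`` of A (average abundance) are excluded,
    as are fragments with a zero in either library.  The reference defaults
    to the library whose upper-quartile CPM is closest to the mean
    upper-quartile.  Factors are rescaled to geometric mean 1.
    """
    y = matrix.counts.astype(float)
    sizes = matrix.library_sizes.astype(float)
    if matrix.n_libraries < 2:
        raise ValueError("TMM needs at least two libraries")
    if np.any(sizes <= 0):
        bad = matrix.library_ids[int(np.argmax(sizes <= 0))]
        raise ValueError(f"library {bad!r} has zero total count")

    if ref is None:
        uq = np.quantile(y, 0.75, axis=0) / sizes
        r = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        r = int(matrix.library_index([ref])[0])

    factors = np.ones(matrix.n_libraries)
    yr, nr = y[:, r], sizes[r]
    for k in range(matrix.n_libraries):
        if k == r:
            continue
        factors[k] = _tmm_pair(y[:, k], sizes[k], yr, nr, trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(matrix.library_ids, factors)


def _tmm_pair(yk, nk, yr, nr, trim_m, trim_a) -> float:
    ok = (yk > 0) & (yr > 0)
    yk, yr = yk[ok], yr[ok]
    if yk.size == 0:
        return 1.0
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    # delta-method variance of M under binomial sampling
    w = (nk - yk) / (nk * yk) + (nr - yr) / (nr * yr)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def _rank(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty_like(x)
    ranks[order] = np.arange(1, x.size + 1, dtype=float)
    # average tied groups
    sx = x[order]
    i = 0
    while i < sx.size:
        j = i
        while j + 1 < sx.size and sx[j + 1] == sx[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = 0.5 * (i + 1 + j + 1)
        i = j + 1
    return ranks
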