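"""Subset-specific conserved gene sets ("core additions") and their null.

A core addition for a strain subset is the set of ortholog groups present in
every subset member and absent from every other strain.  The null
distribution asks how large such a set is for arbitrary subsets of the same
size, enumerated exhaustively or sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import DomainError, ParameterError
from .matrix_io import OrthologMatrix

__all__ = ["CoreAdditionResult", "CoreAdditionNull", "core_addition", "core_addition_null"]

_EXHAUSTIVE_CAP = 500_000


@dataclass(frozen=True)
class CoreAdditionResult:
    subset: frozenset[str]
    groups: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.groups)


@dataclass
class CoreAdditionNull:
    """Core-addition sizes over subsets of one size (the null distribution)."""

    sizes: np.ndarray
    subset_size: int
    mode: str
    n_excluded: int = 0

    @property
    def mean(self) -> float:
        return float(self.sizes.mean())

    @property
    def n_subsets(self) -> int:
        return len(self.sizes)


def _subset_mask(matrix: OrthologMatrix, subset: frozenset[str]) -> np.ndarray:
    unknown = subset - set(matrix.strains)
    if unknown:
        raise DomainError(f"unknown strain ids: {sorted(unknown)}")
    return np.array([s in subset for s in matrix.strains])


def core_addition(matrix: OrthologMatrix, subset) -> CoreAdditionResult:
    """Groups conserved in every ``subset`` strain and absent from all others.

    Presence is binary (paralog multiplicity ignored).  With ``subset`` equal
    to all strains the complement condition is vacuous and the result is the
    core genome.
    """
    subset = frozenset(str(s) for s in subset)
    if not subset:
        raise ParameterError("subset must be non-empty")
    mask = _subset_mask(matrix, subset)
    P = matrix.presence
    inside = P[mask].all(axis=0)
    outside = ~P[~mask].any(axis=0) if (~mask).any() else np.ones(matrix.n_groups, bool)
    hit = inside & outside
    groups = frozenset(np.asarray(matrix.groups)[hit])
    return CoreAdditionResult(subset=subset, groups=groups)


def core_addition_null(
    matrix: OrthologMatrix,
    subset_size: int,
    mode: str = "exhaustive",
    n_samples: int = 10_000,
    seed: int | None = None,
    exclude=None,
) -> CoreAdditionNull:
    """Distribution of core-addition sizes over subsets of ``subset_size``.

    ``exhaustive`` enumerates all C(n, m) subsets; ``sample`` draws
    ``n_samples`` uniform subsets.  Subsets listed in ``exclude`` (an
    iterable of strain-id collections, e.g. the observed subspecies pair) are
    left out of the enumeration.
    """
    n = matrix.n_strains
    m = subset_size
    if not 1 <= m < n:
        raise ParameterError(f"subset_size must satisfy 1 <= m < n (got m={m}, n={n})")
    excluded = {frozenset(str(s) for s in sub) for sub in (exclude or [])}
    for sub in excluded:
        _subset_mask(matrix, sub)  # validates ids

    P = matrix.presence
    sizes: list[int] = []
    n_excluded = 0
    if mode == "exhaustive":
        total = math.comb(n, m)
        if total > _EXHAUSTIVE_CAP:
            raise ParameterError(
                f"C({n},{m}) = {total} exceeds the exhaustive cap; use mode='sample'"
            )
        for combo in combinations(range(n), m):
            names = frozenset(matrix.strains[i] for i in combo)
            if names in excluded:
                n_excluded += 1
                continue
            mask = np.zeros(n, bool)
            mask[list(combo)] = True
            hit = P[mask].all(axis=0) & ~P[~mask].any(axis=0)
            sizes.append(int(hit.sum()))
    elif mode == "sample":
        rng = np.random.default_rng(seed)
        drawn = 0
        while drawn < n_samples:
            combo = rng.choice(n, size=m, replace=False)
            names = frozenset(matrix.strains[i] for i in combo)
            if names in excluded:
                n_excluded += 1
                continue
            mask = np.zeros(n, bool)
            mask[combo] = True
            hit = P[mask].all(axis=0) & ~P[~mask].any(axis=0)
            sizes.append(int(hit.sum()))
            drawn += 1
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return CoreAdditionNull(
        sizes=np.asarray(sizes, dtype=np.int64),
        subset_size=m,
        mode=mode,
        n_excluded=n_excluded,
    )
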