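"""Pairwise compatibility (four-gamete) scoring of binary characters.

Two presence/absence characters are incompatible — evidence of homoplasy or
recombination — when all four joint states (0,0), (0,1), (1,0), (1,1) are
observed across strains.  The summary evaluates all character pairs and can
attach a permutation p-value obtained by independently shuffling each
character across strains (gene frequencies preserved, linkage broken).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .matrix_io import OrthologMatrix

__all__ = ["CompatibilityResult", "pair_compatible", "compatibility_summary"]


@dataclass(frozen=True)
class CompatibilityResult:
    n_pairs_evaluated: int
    n_incompatible: int
    permutation_p: float | None = None

    @property
    def incompatibility_fraction(self) -> float:
        if self.n_pairs_evaluated == 0:
            return 0.0
        return self.n_incompatible / self.n_pairs_evaluated


def pair_compatible(u, v) -> bool:
    """True unless all four joint states of the two binary characters occur."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("characters must be 1-D and of equal length")
    if len(u) < 2:
        raise ValueError("characters must cover at least 2 strains")
    if not (np.isin(u, (0, 1)).all() and np.isin(v, (0, 1)).all()):
        raise ValueError("characters must be binary")
    states = set(zip(u.tolist(), v.tolist()))
    return len(states) <= 3


def _incompatible_fraction(X: np.ndarray) -> tuple[int, int]:
    """(pairs evaluated, incompatible pairs) over all column pairs of X.

    Joint-state tallies come from four integer matrix products; a pair is
    incompatible iff all four tallies are positive.
    """
    g = X.shape[1]
    if g < 2:
        return 0, 0
    Xi = X.astype(np.int64)
    Ci = 1 - Xi
    n11 = Xi.T @ Xi
    n10 = Xi.T @ Ci
    n01 = Ci.T @ Xi
    n00 = Ci.T @ Ci
    incompat = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
    iu = np.triu_indices(g, k=1)
    return len(iu[0]), int(incompat[iu].sum())


def informative_mask(X: np.ndarray) -> np.ndarray:
    """Parsimony-informative columns: both states present in >= 2 rows."""
    ones = X.sum(axis=0)
    return (ones >= 2) & (X.shape[0] - ones >= 2)


def compatibility_summary(
    matrix: OrthologMatrix,
    informative_only: bool = True,
    n_perm: int = 0,
    seed: int | None = None,
) -> CompatibilityResult:
    """Incompatibility fraction over all (optionally informative) character
    pairs, with an optional permutation null.

    The null shuffles each character's values across strains independently
    ``n_perm`` times; ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if matrix.n_strains < 2:
        raise DomainError("need at least 2 strains")
    X = matrix.presence.astype(np.int8)
    if informative_only:
        X = X[:, informative_mask(X)]
    n_pairs, n_incomp = _incompatible_fraction(X)
    if n_pairs == 0:
        return CompatibilityResult(0, 0, None)
    observed = n_incomp / n_pairs

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n, g = X.shape
        at_least = 0
        for _ in range(n_perm):
            idx = np.argsort(rng.random((n, g)), axis=0)
            Y = np.take_along_axis(X, idx, axis=0)
            np_pairs, np_incomp = _incompatible_fraction(Y)
            if np_pairs and np_incomp / np_pairs >= observed:
                at_least += 1
        p = (1 + at_least) / (1 + n_perm)
    return CompatibilityResult(n_pairs, n_incomp, p)
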