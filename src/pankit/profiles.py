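"""Functional profiling and genome sequence statistics.

Covers GC content, genome-length summaries with an exact Mann-Whitney group
comparison, PCA of glycoside-hydrolase family counts (with the default
peptidoglycan-family exclusion), per-family Kruskal-Wallis tests under
Holm-Bonferroni control, and Fisher-exact functional-class enrichment across
pan-genome partitions under Benjamini-Hochberg control.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ParameterError
from .matrix_io import GroupPartition, OrthologMatrix

__all__ = [
    "FamilyProfile",
    "gc_content",
    "length_summary",
    "LengthSummary",
    "mann_whitney_exact",
    "gh_pca",
    "family_distribution_test",
    "partition_enrichment",
    "holm_adjust",
    "bh_adjust",
    "DEFAULT_EXCLUDED_FAMILIES",
]

#: Peptidoglycan hydrolase / lyase families excluded from metabolic profiling.
DEFAULT_EXCLUDED_FAMILIES = frozenset({"GH23", "GH25", "GH73", "GH103"})


def _canon_family(name: str) -> str:
    s = str(name).strip().upper()
    if not s.startswith("GH"):
        s = "GH" + s
    return s


@dataclass
class FamilyProfile:
    """Strains x GH-family count table with subspecies labels.

    Families in ``excluded_families`` (matched case-insensitively, with or
    without the ``GH`` prefix) are removed from the analysis table.
    """

    counts: pd.DataFrame
    labels: Mapping[str, str] | None = None
    excluded_families: frozenset[str] = DEFAULT_EXCLUDED_FAMILIES
    excluded_found: list[str] = field(init=False)

    def __post_init__(self) -> None:
        excl = {_canon_family(f) for f in self.excluded_families}
        cols = list(self.counts.columns)
        drop = [c for c in cols if _canon_family(c) in excl]
        self.excluded_found = drop
        self.counts = self.counts.drop(columns=drop)

    @property
    def strains(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def groups(self) -> dict[str, list[str]]:
        if self.labels is None:
            raise DomainError("profile has no group labels")
        out: dict[str, list[str]] = {}
        for s in self.strains:
            out.setdefault(str(self.labels[s]), []).append(s)
        return out


# ---------------------------------------------------------------------------
# Sequence statistics
# ---------------------------------------------------------------------------

def gc_content(sequences: Mapping[str, str] | str) -> float:
    """(G+C) / (A+C+G+T) over all contigs; ambiguous bases excluded.

    Case- and contig-order-insensitive; a reverse complement has identical GC.
    """
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    gc = at = 0
    for seq in sequences.values():
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        raise DomainError("no unambiguous bases; GC content undefined")
    return gc / denom


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Uses the exact permutation distribution (enumeration of all group
    assignments) when min(n1, n2) <= 8, otherwise the normal approximation
    with tie correction.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    U1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if min(n1, n2) <= 8:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        obs_dev = abs(U1 - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            u = float(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
            total += 1
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
        return U1, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return U1, float(res.pvalue)


@dataclass
class LengthSummary:
    lengths: pd.Series
    median: float
    comparison: dict | None = None


def length_summary(
    genomes: Mapping[str, Mapping[str, str] | float],
    labels: Mapping[str, str] | None = None,
    compare: tuple[str, str] | None = None,
) -> LengthSummary:
    """Per-genome summed contig lengths, median, optional group comparison.

    ``genomes`` maps id -> contig dict *or* a pre-summed length.  With
    ``labels`` and ``compare=(groupA, groupB)``, a two-sided exact
    Mann-Whitney U test compares the two labeled groups; a missing group
    skips the comparison.
    """
    if not genomes:
        raise DomainError("no genomes supplied")
    sums = {}
    for name, val in genomes.items():
        if isinstance(val, (int, float)):
            sums[name] = float(val)
        else:
            sums[name] = float(sum(len(s) for s in val.values()))
    lengths = pd.Series(sums)
    comparison = None
    if labels is not None and compare is not None:
        a, b = compare
        xa = [sums[s] for s in sums if str(labels.get(s)) == a]
        xb = [sums[s] for s in sums if str(labels.get(s)) == b]
        if xa and xb:
            U, p = mann_whitney_exact(xa, xb)
            comparison = {"groups": (a, b), "n": (len(xa), len(xb)), "U": U, "p": p}
    return LengthSummary(lengths=lengths, median=float(lengths.median()), comparison=comparison)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def gh_pca(profile: FamilyProfile, scaled: bool = True, n_components: int | None = None):
    """PCA of family counts: always mean-centered, unit-variance iff scaled.

    Zero-variance families are dropped (with scaling they would divide by
    zero; without, they carry no signal either way they are kept).  Component
    signs follow the convention that each component's largest-magnitude
    loading is positive.  Returns (coordinates, loadings,
    explained_variance_ratio) as pandas objects.
    """
    X = profile.counts.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise DomainError("PCA needs at least 3 strains")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0 if scaled else np.ones(X.shape[1], bool)
    families = [f for f, k in zip(profile.families, keep) if k]
    if len(families) < 2:
        raise DomainError("fewer than 2 usable families")
    X = X[:, keep]
    X = X - X.mean(axis=0)
    if scaled:
        X = X / X.std(axis=0, ddof=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components or min(X.shape)
    k = min(k, len(S))
    # deterministic sign: largest-|loading| positive per component
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    coords = U[:, :k] * S[:k]
    var = S**2
    evr = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    pcs = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=profile.strains, columns=pcs),
        pd.DataFrame(Vt[:k].T, index=families, columns=pcs),
        pd.Series(evr, index=pcs),
    )


# ---------------------------------------------------------------------------
# Multiple-testing adjustments
# ---------------------------------------------------------------------------

def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# Distribution and enrichment tests
# ---------------------------------------------------------------------------

def family_distribution_test(profile: FamilyProfile, alpha: float = 0.05) -> pd.DataFrame:
    """Per-family Kruskal-Wallis across labeled groups, Holm-adjusted.

    Constant families get p = 1 by convention.  The ``non_uniform`` flag
    marks adjusted p < ``alpha``.
    """
    groups = profile.groups()
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise DomainError("need >= 2 groups with >= 2 strains each")
    pvals = []
    for fam in profile.families:
        samples = [profile.counts.loc[members, fam].to_numpy() for members in groups.values()]
        if np.all(np.concatenate(samples) == samples[0][0]):
            pvals.append(1.0)
            continue
        stat, p = stats.kruskal(*samples)
        pvals.append(float(p))
    adj = holm_adjust(pvals)
    return pd.DataFrame(
        {
            "family": profile.families,
            "p": pvals,
            "p_adjusted": adj,
            "non_uniform": adj < alpha,
        }
    ).set_index("family")


def partition_enrichment(
    matrix: OrthologMatrix,
    partition: GroupPartition,
    classes: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Functional-class enrichment per pan-genome partition cell.

    For every class x cell (core/moderate/rare) a 2x2 Fisher exact test
    (class vs rest, cell vs rest) runs over *annotated* groups only; q-values
    are Benjamini-Hochberg over all class x cell tests.
    """
    if classes is None:
        if matrix.group_meta is None or "functional_class" not in matrix.group_meta:
            raise DomainError("no functional-class labels available")
        classes = matrix.group_meta["functional_class"].to_dict()
    labeled = {
        g: str(c)
        for g, c in classes.items()
        if c is not None and str(c) != "" and not (isinstance(c, float) and np.isnan(c))
    }
    labeled = {g: c for g, c in labeled.items() if g in set(matrix.groups)}
    if not labeled:
        return pd.DataFrame(
            columns=["class", "cell", "a", "b", "c", "d", "odds_ratio", "p", "q"]
        )
    cells = {"core": partition.core, "moderate": partition.moderate, "rare": partition.rare}
    rows = []
    class_names = sorted(set(labeled.values()))
    universe = list(labeled)
    for cls in class_names:
        in_class = {g for g, c in labeled.items() if c == cls}
        for cell_name, cell in cells.items():
            in_cell = {g for g in universe if g in cell}
            a = len(in_class & in_cell)
            b = len(in_class - in_cell)
            c = len(in_cell - in_class)
            d = len(universe) - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"class": cls, "cell": cell_name, "a": a, "b": b, "c": c, "d": d,
                 "odds_ratio": float(odds), "p": float(p)}
            )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    return df
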