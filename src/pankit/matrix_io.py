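"""Ortholog occurrence matrices: parsing, partitions, similarity, marker selection.

The central object is :class:`OrthologMatrix`, a strains x groups table of
gene-occurrence counts built from ortholog clustering output (OrthoMCL
"groups" text dialect) or a plain TSV.  Presence means count >= 1; paralogs
show up as counts > 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import DomainError, ParseError

__all__ = [
    "OrthologMatrix",
    "GroupPartition",
    "read_groups",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "partition_groups",
    "shared_matrix",
    "read_annotations",
    "select_marker_loci",
    "linkage_to_newick",
]

ANNOTATION_COLUMNS = [
    "gene_id",
    "strain",
    "contig",
    "start",
    "end",
    "strand",
    "functional_class",
    "gh_family",
    "has_gaps",
]


@dataclass
class OrthologMatrix:
    """Strains x ortholog-groups occurrence counts.

    Parameters
    ----------
    strains : ordered strain identifiers (rows).
    groups : ordered group identifiers (columns).
    occurrence : non-negative integer counts, shape ``(n_strains, n_groups)``.
    group_meta : optional per-group metadata indexed by group id; recognised
        columns include ``functional_class`` and ``gene_length``.
    """

    strains: list[str]
    groups: list[str]
    occurrence: np.ndarray
    group_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.strains = [str(s) for s in self.strains]
        self.groups = [str(g) for g in self.groups]
        self.occurrence = np.asarray(self.occurrence, dtype=np.int64)
        if self.occurrence.ndim != 2 or self.occurrence.shape != (
            len(self.strains),
            len(self.groups),
        ):
            raise ValueError(
                f"occurrence shape {self.occurrence.shape} does not match "
                f"{len(self.strains)} strains x {len(self.groups)} groups"
            )
        if (self.occurrence < 0).any():
            raise ValueError("occurrence counts must be non-negative")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain ids")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group ids")

    # -- basic views ----------------------------------------------------

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def presence(self) -> np.ndarray:
        """Binary presence/absence view (count >= 1)."""
        return self.occurrence >= 1

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain id: {strain!r}") from None

    def counts_per_strain(self) -> pd.Series:
        """Number of groups present in each strain."""
        return pd.Series(self.presence.sum(axis=1), index=self.strains)

    def group_frequency(self) -> pd.Series:
        """Number of strains each group is present in."""
        return pd.Series(self.presence.sum(axis=0), index=self.groups)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occurrence, index=self.strains, columns=self.groups)

    # -- subsetting -----------------------------------------------------

    def select_strains(self, keep: Sequence[str], drop_empty_groups: bool = True) -> "OrthologMatrix":
        """Restrict to a subset of strains, optionally dropping now-absent groups."""
        idx = [self.strain_index(s) for s in keep]
        occ = self.occurrence[idx, :]
        groups = list(self.groups)
        meta = self.group_meta
        if drop_empty_groups:
            mask = (occ >= 1).any(axis=0)
            occ = occ[:, mask]
            groups = [g for g, m in zip(groups, mask) if m]
            if meta is not None:
                meta = meta.loc[meta.index.intersection(groups)]
        return OrthologMatrix(list(keep), groups, occ, meta)

    def drop_groups(self, drop: Iterable[str]) -> "OrthologMatrix":
        """Remove the named groups (e.g. a functional category to exclude)."""
        drop = set(drop)
        keep = [g for g in self.groups if g not in drop]
        idx = [self.groups.index(g) for g in keep]
        meta = self.group_meta
        if meta is not None:
            meta = meta.loc[meta.index.intersection(keep)]
        return OrthologMatrix(list(self.strains), keep, self.occurrence[:, idx], meta)


@dataclass(frozen=True)
class GroupPartition:
    """Disjoint partition of ortholog groups by prevalence.

    ``core`` = present in all strains; ``rare`` = present in exactly one
    strain; ``moderate`` = everything in between.  With a single strain every
    group satisfies both the core and the rare definition; core wins.
    """

    core: frozenset[str]
    moderate: frozenset[str]
    rare: frozenset[str]

    def __len__(self) -> int:
        return len(self.core) + len(self.moderate) + len(self.rare)

    def label_of(self, group: str) -> str:
        if group in self.core:
            return "core"
        if group in self.moderate:
            return "moderate"
        if group in self.rare:
            return "rare"
        raise KeyError(group)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_groups(path: str | Path, strain_roster: Sequence[str] | None = None) -> OrthologMatrix:
    """Parse an OrthoMCL-style groups file into an occurrence matrix.

    Each line reads ``groupID: strainA|gene1 strainB|gene2 ...``; the strain
    id is everything before the *first* ``|`` of a member token (gene ids may
    themselves contain ``|``).  Occurrence counts are member genes per strain
    per group.  Strains in ``strain_roster`` but absent from the file appear
    as all-zero rows; the roster also fixes row order.
    """
    path = Path(path)
    group_ids: list[str] = []
    group_counts: list[dict[str, int]] = []
    seen_groups: set[str] = set()
    strain_order: list[str] = []
    strain_seen: set[str] = set()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            head, sep, members = line.partition(":")
            if not sep:
                raise ParseError(f"{path}:{lineno}: missing ':' separator")
            gid = head.strip()
            if not gid:
                raise ParseError(f"{path}:{lineno}: empty group id")
            if gid in seen_groups:
                raise ParseError(f"{path}:{lineno}: duplicate group id {gid!r}")
            seen_groups.add(gid)
            counts: dict[str, int] = {}
            tokens = members.split()
            if not tokens:
                raise ParseError(f"{path}:{lineno}: group {gid!r} has no members")
            for tok in tokens:
                strain, sep2, _gene = tok.partition("|")
                if not sep2 or not strain:
                    raise ParseError(
                        f"{path}:{lineno}: member token {tok!r} lacks 'strain|gene' form"
                    )
                counts[strain] = counts.get(strain, 0) + 1
                if strain not in strain_seen:
                    strain_seen.add(strain)
                    strain_order.append(strain)
            group_ids.append(gid)
            group_counts.append(counts)

    if strain_roster is not None:
        roster = [str(s) for s in strain_roster]
        extra = [s for s in strain_order if s not in set(roster)]
        if extra:
            raise ParseError(f"{path}: strains {extra} not in the supplied roster")
        strains = roster
    else:
        strains = strain_order

    occ = np.zeros((len(strains), len(group_ids)), dtype=np.int64)
    row = {s: i for i, s in enumerate(strains)}
    for j, counts in enumerate(group_counts):
        for s, c in counts.items():
            occ[row[s], j] = c
    return OrthologMatrix(strains, group_ids, occ)


def read_matrix_tsv(path: str | Path) -> OrthologMatrix:
    """Read a strain x group TSV (header = group ids, first column = strain id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OrthologMatrix(
        [str(s) for s in df.index],
        [str(g) for g in df.columns],
        df.to_numpy(dtype=np.int64),
    )


def write_matrix_tsv(matrix: OrthologMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="strain")


# ---------------------------------------------------------------------------
# Partition and similarity
# ---------------------------------------------------------------------------

def partition_groups(matrix: OrthologMatrix) -> GroupPartition:
    """Split groups into core / moderately common / rare by prevalence."""
    if matrix.n_strains < 1:
        raise DomainError("partition requires at least one strain")
    freq = matrix.presence.sum(axis=0)
    if (freq < 1).any():
        raise DomainError("matrix contains all-zero groups; drop them first")
    n = matrix.n_strains
    groups = np.asarray(matrix.groups)
    core = frozenset(groups[freq == n])
    rare = frozenset(groups[(freq == 1) & (freq != n)])
    moderate = frozenset(groups[(freq > 1) & (freq < n)])
    return GroupPartition(core=core, moderate=moderate, rare=rare)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        a, b = int(a), int(b)
        la = max(heights[i] - heights[a], 0.0)
        lb = max(heights[i] - heights[b], 0.0)
        return f"({node(a)}:{la:g},{node(b)}:{lb:g})"

    for idx, (_, _, h, _) in enumerate(Z):
        heights[n + idx] = float(h)
    return node(n + len(Z) - 1) + ";" if len(Z) else labels[0] + ";"


def shared_matrix(matrix: OrthologMatrix) -> tuple[pd.DataFrame, str | None]:
    """Pairwise counts of shared ortholog groups plus a complete-linkage tree.

    Sharing is binary (paralog multiplicity ignored).  The diagonal holds the
    per-strain group count.  Clustering distance is ``max_shared - shared``;
    the tree is returned as a Newick string (``None`` for a single strain).
    """
    P = matrix.presence.astype(np.int64)
    shared = P @ P.T
    df = pd.DataFrame(shared, index=matrix.strains, columns=matrix.strains)
    if matrix.n_strains < 2:
        return df, None
    dist = shared.max() - shared
    np.fill_diagonal(dist, 0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    return df, linkage_to_newick(Z, matrix.strains)


# ---------------------------------------------------------------------------
# Annotations and marker selection
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-gene annotation TSV into the canonical column layout.

    Expected columns (header required): gene_id, strain, contig, start, end,
    strand, functional_class, gh_family, has_gaps.  Coordinates are 1-based
    inclusive.  Missing optional columns are filled with defaults.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "strain": str, "contig": str})
    required = {"gene_id", "strain", "contig", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    for col, default in (
        ("strand", "+"),
        ("functional_class", ""),
        ("gh_family", ""),
        ("has_gaps", False),
    ):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df[(df["start"] > df["end"]) | (df["start"] < 1)]
    if len(bad):
        raise ParseError(f"{path}: invalid coordinates for genes {bad['gene_id'].tolist()}")
    return df[ANNOTATION_COLUMNS]


def select_marker_loci(
    annotations: pd.DataFrame,
    candidate_genes: Iterable[str],
    min_spacing: int = 10_000,
) -> list[str]:
    """Pick well-spaced marker genes on a reference genome.

    Candidates are kept only if separated from every already-kept gene by a
    gap (between the nearest coordinates) greater than ``min_spacing``; within
    a conflicting cluster the longest gene wins.  Selection is a greedy pass
    over candidates sorted by length descending (ties broken by genomic
    position), which makes the output deterministic and independent of the
    input ordering.  Returns gene ids sorted by genomic position.
    """
    if min_spacing <= 0:
        raise ValueError("min_spacing must be positive")
    candidates = [str(g) for g in candidate_genes]
    ann = annotations.set_index("gene_id")
    missing = [g for g in candidates if g not in ann.index]
    if missing:
        raise DomainError(f"candidates without coordinates: {missing}")
    rows = ann.loc[candidates]
    recs = [
        (gid, str(r["contig"]), int(r["start"]), int(r["end"]))
        for gid, r in rows.iterrows()
    ]
    recs.sort(key=lambda r: (-(r[3] - r[2] + 1), r[1], r[2], r[0]))

    kept: list[tuple[str, str, int, int]] = []
    for gid, contig, start, end in recs:
        ok = True
        for _, kc, ks, ke in kept:
            if kc != contig:
                continue
            if start > ke:
                gap = start - ke
            elif ks > end:
                gap = ks - end
            else:
                gap = 0  # overlapping
            if gap <= min_spacing:
                ok = False
                break
        if ok:
            kept.append((gid, contig, start, end))
    kept.sort(key=lambda r: (r[1], r[2]))
    return [gid for gid, *_ in kept]
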