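"""Fragment-based average nucleotide identity (ANIb-style).

One genome of a pair is cut into fixed-size fragments (default 1020 bp);
each fragment is locally aligned against the other genome and its best match
kept.  Matches are retained when the *overall* identity (identical bases
divided by the full fragment length) exceeds 30% and the alignable region
covers at least 70% of the fragment; the ANI of the direction is the mean
*local* identity (identities / alignment columns) of retained matches, in
percent.  The reported pairwise ANI is the mean of the two directions.

Two aligner backends satisfy the same contract: a dependency-free internal
seed-and-extend aligner (exact k-mer seeding plus local dynamic programming
via Biopython's PairwiseAligner) and an optional adapter shelling out to
NCBI ``blastn`` with JSpecies-like settings.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .errors import DomainError, ParameterError
from .matrix_io import linkage_to_newick

__all__ = [
    "Fragment",
    "FragmentMatch",
    "AniResult",
    "fragment_genome",
    "ani_pair",
    "ani_matrix",
    "read_fasta",
    "SeedExtendAligner",
    "BlastnAligner",
]

DEFAULT_FRAGMENT_SIZE = 1020
MIN_TRAILING_FRAGMENT = 100  # shorter trailing windows are dropped (configurable)
MIN_OVERALL_IDENTITY = 0.30
MIN_ALIGNABLE_FRACTION = 0.70

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Fragment:
    """A window of one contig; id encodes contig and 0-based start."""

    contig: str
    start: int
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.start}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentMatch:
    """Best local match of one fragment against a reference genome."""

    fragment_id: str
    fragment_length: int
    identities: int
    alignment_length: int
    fragment_span: int

    @property
    def overall_identity(self) -> float:
        return self.identities / self.fragment_length

    @property
    def local_identity(self) -> float:
        return self.identities / self.alignment_length if self.alignment_length else 0.0

    @property
    def alignable_fraction(self) -> float:
        return self.fragment_span / self.fragment_length


@dataclass
class AniResult:
    """Directional ANI with per-fragment diagnostics."""

    query: str
    reference: str
    n_fragments: int
    matches: list[FragmentMatch] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.matches)

    @property
    def ani(self) -> float:
        """Mean local identity of retained matches, percent; NaN if none."""
        if not self.matches:
            return float("nan")
        return 100.0 * float(np.mean([m.local_identity for m in self.matches]))

    @property
    def defined(self) -> bool:
        return bool(self.matches)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise DomainError(f"no sequences in {path}")
    return records


def fragment_genome(
    sequences: Mapping[str, str],
    size: int = DEFAULT_FRAGMENT_SIZE,
    min_trailing: int = MIN_TRAILING_FRAGMENT,
) -> list[Fragment]:
    """Cut each contig into consecutive non-overlapping windows of ``size``.

    The trailing partial window is kept only when at least ``min_trailing``
    bp long.  Fragments never span contig boundaries.
    """
    if size < 1:
        raise ParameterError("fragment size must be >= 1")
    if not sequences:
        raise DomainError("empty sequence set")
    frags: list[Fragment] = []
    for contig, seq in sequences.items():
        for start in range(0, len(seq), size):
            piece = seq[start : start + size]
            if len(piece) < size and len(piece) < min_trailing:
                continue
            frags.append(Fragment(contig=contig, start=start, sequence=piece))
    return frags


class Aligner(Protocol):
    """Contract: best local match per fragment against a reference genome."""

    def best_matches(
        self, fragments: Sequence[Fragment], reference: Mapping[str, str]
    ) -> list[FragmentMatch | None]:
        ...


class SeedExtendAligner:
    """Exact k-mer seeding plus banded-window local alignment.

    The reference is indexed by k-mers; each fragment's k-mers vote for a
    diagonal (reference offset) on each contig and strand, and the fragment
    is then locally aligned (match +2 / mismatch -3, gap open -5 / extend -2,
    blastn-like) against a padded window around the winning diagonal.
    Desk-scale by design: adequate for draft genomes up to a few Mbp.
    """

    def __init__(self, k: int = 16, seed_step: int = 8, pad: int = 80, max_hits_per_kmer: int = 100):
        if k < 4:
            raise ParameterError("k-mer size must be >= 4")
        self.k = k
        self.seed_step = seed_step
        self.pad = pad
        self.max_hits_per_kmer = max_hits_per_kmer
        self._pa = PairwiseAligner(
            mode="local",
            match_score=2,
            mismatch_score=-3,
            open_gap_score=-5,
            extend_gap_score=-2,
        )

    def _index(self, reference: Mapping[str, str]) -> dict[str, list[tuple[str, int]]]:
        idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
        k = self.k
        for contig, seq in reference.items():
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                hits = idx[kmer]
                if len(hits) < self.max_hits_per_kmer:
                    hits.append((contig, pos))
        return idx

    def _candidate_window(
        self,
        frag_seq: str,
        index: dict[str, list[tuple[str, int]]],
    ) -> tuple[str, int, int] | None:
        """Vote k-mer diagonals; return (contig, win_start, win_end) or None."""
        k = self.k
        votes: Counter[tuple[str, int]] = Counter()
        for qpos in range(0, max(1, len(frag_seq) - k + 1), self.seed_step):
            kmer = frag_seq[qpos : qpos + k]
            for contig, rpos in index.get(kmer, ()):
                # bucket diagonals to tolerate small indels
                diag = (rpos - qpos) // 32
                votes[(contig, diag)] += 1
        if not votes:
            return None
        (contig, diag), _ = votes.most_common(1)[0]
        start = diag * 32 - self.pad
        end = diag * 32 + 32 + len(frag_seq) + self.pad
        return contig, max(0, start), end

    def _align_window(self, frag_seq: str, window: str) -> tuple[int, int, int] | None:
        """(identities, alignment_length, fragment_span) of the best local
        alignment of the fragment against the window."""
        if not window:
            return None
        try:
            aln = self._pa.align(frag_seq, window)[0]
        except (IndexError, ValueError):
            return None
        counts = aln.counts()
        identities = counts.identities
        alignment_length = counts.identities + counts.mismatches + counts.gaps
        qblocks = aln.aligned[0]
        if len(qblocks) == 0:
            return None
        span = int(qblocks[-1][1] - qblocks[0][0])
        return identities, alignment_length, span

    def best_matches(
        self, fragments: Sequence[Fragment], reference: Mapping[str, str]
    ) -> list[FragmentMatch | None]:
        index = self._index(reference)
        out: list[FragmentMatch | None] = []
        for frag in fragments:
            best: tuple[int, int, int] | None = None
            for seq in (frag.sequence, _revcomp(frag.sequence)):
                cand = self._candidate_window(seq, index)
                if cand is None:
                    continue
                contig, ws, we = cand
                res = self._align_window(seq, reference[contig][ws:we])
                if res and (best is None or res[0] > best[0]):
                    best = res
            if best is None:
                out.append(None)
            else:
                out.append(
                    FragmentMatch(
                        fragment_id=frag.id,
                        fragment_length=len(frag),
                        identities=best[0],
                        alignment_length=best[1],
                        fragment_span=best[2],
                    )
                )
        return out


class BlastnAligner:
    """Adapter shelling out to NCBI blastn with JSpecies-like settings.

    Requires ``blastn`` and ``makeblastdb`` on PATH.  Settings follow the
    classic ANIb recipe: reward +1 / penalty -1, gapped X-dropoff 150, no
    dust filtering, e-value 1e-15; the best hit per fragment (by bit score)
    is used.
    """

    def __init__(self, evalue: float = 1e-15):
        self.evalue = evalue
        if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
            raise DomainError("blastn/makeblastdb not found on PATH")

    def best_matches(
        self, fragments: Sequence[Fragment], reference: Mapping[str, str]
    ) -> list[FragmentMatch | None]:
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            qpath = tmp / "query.fna"
            rpath = tmp / "ref.fna"
            with open(qpath, "w") as fh:
                for i, frag in enumerate(fragments):
                    fh.write(f">f{i}\n{frag.sequence}\n")
            with open(rpath, "w") as fh:
                for contig, seq in reference.items():
                    fh.write(f">{contig}\n{seq}\n")
            subprocess.run(
                ["makeblastdb", "-in", str(rpath), "-dbtype", "nucl"],
                check=True,
                capture_output=True,
            )
            proc = subprocess.run(
                [
                    "blastn",
                    "-task", "blastn",
                    "-query", str(qpath),
                    "-db", str(rpath),
                    "-reward", "1",
                    "-penalty", "-1",
                    "-xdrop_gap_final", "150",
                    "-dust", "no",
                    "-evalue", str(self.evalue),
                    "-max_target_seqs", "5",
                    "-outfmt", "6 qseqid nident length qstart qend bitscore",
                ],
                check=True,
                capture_output=True,
                text=True,
            )
        best: dict[int, tuple[float, FragmentMatch]] = {}
        for line in proc.stdout.splitlines():
            qid, nident, length, qstart, qend, bits = line.split("\t")
            i = int(qid[1:])
            bits = float(bits)
            match = FragmentMatch(
                fragment_id=fragments[i].id,
                fragment_length=len(fragments[i]),
                identities=int(nident),
                alignment_length=int(length),
                fragment_span=abs(int(qend) - int(qstart)) + 1,
            )
            if i not in best or bits > best[i][0]:
                best[i] = (bits, match)
        return [best[i][1] if i in best else None for i in range(len(fragments))]


def ani_pair(
    query: Mapping[str, str],
    reference: Mapping[str, str],
    aligner: Aligner | None = None,
    fragment_size: int = DEFAULT_FRAGMENT_SIZE,
    min_identity: float = MIN_OVERALL_IDENTITY,
    min_alignable: float = MIN_ALIGNABLE_FRACTION,
    query_id: str = "query",
    reference_id: str = "reference",
) -> AniResult:
    """Directional fragment ANI of ``query`` against ``reference``.

    Retains best matches with overall identity (identities / fragment
    length) > ``min_identity`` and alignable fraction >= ``min_alignable``.
    """
    if not query or not reference:
        raise DomainError("both genomes must be non-empty")
    aligner = aligner or SeedExtendAligner()
    fragments = fragment_genome(query, size=fragment_size)
    matches = aligner.best_matches(fragments, reference)
    retained = [
        m
        for m in matches
        if m is not None
        and m.overall_identity > min_identity
        and m.alignable_fraction >= min_alignable
    ]
    return AniResult(
        query=query_id,
        reference=reference_id,
        n_fragments=len(fragments),
        matches=retained,
    )


def ani_matrix(
    genomes: Mapping[str, Mapping[str, str]],
    aligner: Aligner | None = None,
    fragment_size: int = DEFAULT_FRAGMENT_SIZE,
) -> tuple[pd.DataFrame, str | None]:
    """Symmetricized ANI matrix (mean of the two directions) plus a
    complete-linkage Newick tree on distance ``100 - ANI``.

    Pairs undefined in either direction are left NaN and excluded from
    clustering (the tree is ``None`` if any pair is undefined).
    """
    names = list(genomes)
    if len(names) < 2:
        raise DomainError("need at least 2 genomes")
    aligner = aligner or SeedExtendAligner()
    n = len(names)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            fwd = ani_pair(
                genomes[names[i]], genomes[names[j]], aligner, fragment_size,
                query_id=names[i], reference_id=names[j],
            )
            rev = ani_pair(
                genomes[names[j]], genomes[names[i]], aligner, fragment_size,
                query_id=names[j], reference_id=names[i],
            )
            if fwd.defined and rev.defined:
                mat[i, j] = mat[j, i] = (fwd.ani + rev.ani) / 2.0
    df = pd.DataFrame(mat, index=names, columns=names)
    if np.isnan(mat).any():
        return df, None
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    dist = 100.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    return df, linkage_to_newick(Z, names)
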