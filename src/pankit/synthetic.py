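"""Synthetic pan-genome matrices and diverged genome pairs with known truth.

Two generators back the test battery for the whole pipeline:

* :func:`simulate_pangenome` builds binary/count occurrence matrices with a
  fixed core and an accessory component drawn either from a Beta gene
  frequency spectrum or from an "open stream" process in which every strain
  introduces new candidate genes that later strains retain with a fixed
  probability — the latter produces Heaps-like open accumulation behaviour
  with a tunable exponent.
* :func:`simulate_genome_pair` produces an ancestor sequence of controlled
  GC content and a derived copy with i.i.d. substitutions (uniform over the
  three alternative bases) and optional single-base indels.

Everything is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ParameterError
from .matrix_io import OrthologMatrix

__all__ = [
    "BetaSpectrum",
    "OpenStream",
    "PanGenomeSpec",
    "SequencePairSpec",
    "simulate_pangenome",
    "simulate_genome_pair",
    "write_groups_file",
    "write_fasta",
    "OPEN_STREAM_PRESET",
    "open_preset_spec",
]


@dataclass(frozen=True)
class BetaSpectrum:
    """Accessory model: per-group presence frequency ~ Beta(a, b)."""

    a: float
    b: float
    n_accessory: int

    def validate(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ParameterError("Beta shape parameters must be positive")
        if self.n_accessory < 0:
            raise ParameterError("n_accessory must be non-negative")


@dataclass(frozen=True)
class OpenStream:
    """Accessory model: each strain introduces ``theta`` candidate genes,
    each retained by every subsequently generated strain with probability
    ``f``.  Genes from late strains stay rare, genes from early strains grow
    common, yielding an open (Heaps-like) accumulation curve."""

    theta: int
    f: float

    def validate(self) -> None:
        if self.theta < 0:
            raise ParameterError("theta must be non-negative")
        if not 0.0 <= self.f <= 1.0:
            raise ParameterError("retention probability f must lie in [0, 1]")


@dataclass(frozen=True)
class PanGenomeSpec:
    """Generative parameters for a synthetic occurrence matrix."""

    n_strains: int
    n_core: int
    accessory_model: BetaSpectrum | OpenStream | None = None
    category_labels: Mapping[int, str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ParameterError("n_strains must be positive")
        if self.n_core < 0:
            raise ParameterError("n_core must be non-negative")
        if self.accessory_model is not None:
            self.accessory_model.validate()


#: Openness regime used in calibration tests: a clearly open pan-genome.
OPEN_STREAM_PRESET = OpenStream(theta=120, f=0.25)


def open_preset_spec(n_strains: int = 20, seed: int = 0) -> "PanGenomeSpec":
    """Convenience spec in the open regime: new-gene exponent lands around
    -0.8, safely inside (-1, 0), for 20 strains with a 100-group core."""
    return PanGenomeSpec(
        n_strains=n_strains, n_core=100, accessory_model=OPEN_STREAM_PRESET, seed=seed
    )


@dataclass(frozen=True)
class SequencePairSpec:
    """Generative parameters for an ancestor/descendant sequence pair."""

    length: int
    substitution_rate: float = 0.0
    gc_fraction: float = 0.5
    indel_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.length < 1:
            raise ParameterError("length must be >= 1")
        for name in ("substitution_rate", "gc_fraction", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class PanGenomeTruth:
    """Ground truth for a simulated matrix: the per-group presence frequency
    actually used (1.0 for core; Beta draws or retention-model marginals for
    accessory groups), keyed by group id."""

    frequencies: dict[str, float]
    model: str
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"model": self.model, "params": self.params, "frequencies": self.frequencies},
                fh,
                indent=2,
            )


def _group_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_pangenome(spec: PanGenomeSpec) -> tuple[OrthologMatrix, PanGenomeTruth]:
    """Simulate an occurrence matrix per ``spec``; returns matrix + truth.

    Core groups are present in every strain.  Accessory presence is sampled
    independently per strain per group (strains are exchangeable, matching
    the permutation machinery downstream).  All-zero accessory columns are
    dropped so the matrix invariant (no empty groups) holds; the truth record
    covers the retained groups.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strains

    blocks: list[np.ndarray] = []
    freqs: list[float] = []
    if spec.n_core:
        blocks.append(np.ones((n, spec.n_core), dtype=np.int64))
        freqs.extend([1.0] * spec.n_core)

    model = spec.accessory_model
    model_name = "none"
    params: dict = {}
    if isinstance(model, BetaSpectrum):
        model_name = "beta-spectrum"
        params = {"a": model.a, "b": model.b, "n_accessory": model.n_accessory}
        p = rng.beta(model.a, model.b, size=model.n_accessory)
        acc = (rng.random((n, model.n_accessory)) < p).astype(np.int64)
        keep = acc.any(axis=0)
        blocks.append(acc[:, keep])
        freqs.extend(p[keep].tolist())
    elif isinstance(model, OpenStream):
        model_name = "open-stream"
        params = {"theta": model.theta, "f": model.f}
        cols: list[np.ndarray] = []
        for i in range(n):
            block = np.zeros((n, model.theta), dtype=np.int64)
            block[i, :] = 1
            if i + 1 < n:
                block[i + 1 :, :] = (
                    rng.random((n - i - 1, model.theta)) < model.f
                ).astype(np.int64)
            cols.append(block)
            # marginal expected frequency of a gene introduced by strain i
            freqs.extend([(1 + (n - i - 1) * model.f) / n] * model.theta)
        if cols:
            blocks.append(np.concatenate(cols, axis=1))
    elif model is not None:
        raise ParameterError(f"unknown accessory model: {model!r}")

    occ = (
        np.concatenate(blocks, axis=1)
        if blocks
        else np.zeros((n, 0), dtype=np.int64)
    )
    gids = _group_ids(occ.shape[1])
    strains = [f"S{i}" for i in range(1, n + 1)]
    matrix = OrthologMatrix(strains, gids, occ)
    if spec.category_labels:
        import pandas as pd

        meta = pd.DataFrame(index=gids, data={"functional_class": ""})
        for idx, label in spec.category_labels.items():
            if 0 <= idx < len(gids):
                meta.loc[gids[idx], "functional_class"] = label
        matrix.group_meta = meta
    truth = PanGenomeTruth(
        frequencies=dict(zip(gids, freqs)), model=model_name, params=params
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Sequence pairs
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome_pair(spec: SequencePairSpec) -> tuple[str, str]:
    """Return (ancestor, derived) sequences per ``spec``.

    The ancestor is i.i.d. with P(G) = P(C) = gc/2.  The derived copy applies
    substitutions uniformly over the three alternative bases, then single-base
    indels (insertion or deletion with equal probability).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    anc = rng.choice(4, size=spec.length, p=probs).astype(np.uint8)

    der = anc.copy()
    if spec.substitution_rate > 0:
        hit = rng.random(spec.length) < spec.substitution_rate
        n_hit = int(hit.sum())
        if n_hit:
            # shift by 1..3 mod 4: uniform over the three alternative bases
            der[hit] = (der[hit] + rng.integers(1, 4, size=n_hit)) % 4

    if spec.indel_rate > 0:
        out: list[int] = []
        events = rng.random(der.shape[0]) < spec.indel_rate
        kinds = rng.random(der.shape[0]) < 0.5  # True: deletion
        inserts = rng.integers(0, 4, size=der.shape[0])
        for i, b in enumerate(der):
            if events[i]:
                if kinds[i]:
                    continue  # deletion
                out.append(int(inserts[i]))  # insertion before current base
            out.append(int(b))
        der = np.array(out, dtype=np.uint8)

    decode = np.array(list("ACGT"))
    return "".join(decode[anc]), "".join(decode[der])


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_groups_file(matrix: OrthologMatrix, path: str | Path) -> None:
    """Write a matrix in the OrthoMCL groups dialect.

    A strain with occurrence count c contributes c member tokens
    (``strain|<strain>_<group>_<copy>``), so paralog multiplicity round-trips
    through :func:`pankit.matrix_io.read_groups`.
    """
    if matrix.n_groups == 0:
        raise ValueError("refusing to write an empty matrix")
    with open(path, "w") as fh:
        for j, gid in enumerate(matrix.groups):
            members = []
            for i, strain in enumerate(matrix.strains):
                for copy in range(int(matrix.occurrence[i, j])):
                    members.append(f"{strain}|{strain}_{gid}_{copy + 1}")
            fh.write(f"{gid}: " + " ".join(members) + "\n")


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write sequences as uncompressed FASTA."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
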