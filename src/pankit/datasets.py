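"""Bundled reference tables.

Summed genome sequence lengths (Mbp) and subspecies assignments for the 28
published *Bifidobacterium longum* genomes used to validate the
genome-statistics routines.  Lengths are the deposited assembly sizes (sums
of contig lengths for drafts), rounded to 0.01 Mbp.
"""

from __future__ import annotations

#: strain -> (sequence length in Mbp, subspecies)
BLONGUM_GENOMES: dict[str, tuple[float, str]] = {
    "ATCC 15697": (2.83, "infantis"),
    "EK3": (2.56, "infantis"),
    "AGR2137": (2.27, "suis"),
    "JDM301": (2.48, "suis"),
    "LMG 21814": (2.34, "suis"),
    "12_1_47BFAA": (2.40, "longum"),
    "157F": (2.40, "longum"),
    "1-5B": (2.37, "longum"),
    "17-1B": (2.47, "longum"),
    "1-6B": (2.69, "longum"),
    "2-2B": (2.63, "longum"),
    "35B": (2.51, "longum"),
    "44B": (2.56, "longum"),
    "72B": (2.37, "longum"),
    "7-1B": (2.41, "longum"),
    "ATCC 55813": (2.37, "longum"),
    "BBMN68": (2.27, "longum"),
    "CCUG 52486": (2.45, "longum"),
    "CECT 7347": (2.33, "longum"),
    "DJO10A": (2.38, "longum"),
    "E18": (2.37, "longum"),
    "F8": (2.37, "longum"),
    "EK5": (2.23, "longum"),
    "EK13": (2.47, "longum"),
    "JCM 1217": (2.39, "longum"),
    "KACC 91563": (2.39, "longum"),
    "NCC2705": (2.26, "longum"),
    "VMKB44": (2.51, "longum"),
}


def genome_lengths_mbp() -> dict[str, float]:
    return {k: v[0] for k, v in BLONGUM_GENOMES.items()}


def subspecies_labels() -> dict[str, str]:
    return {k: v[1] for k, v in BLONGUM_GENOMES.items()}
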