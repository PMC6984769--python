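"""Conjoint-triad spectra and composition baselines.

For a protein ``P = P1..PL`` each residue is reduced to its 7-group class
and every window of three successive residues contributes one count to its
ordered group triad; the 343-dimensional spectrum holds the normalized
frequencies ``f_i = m_i / (L - 2)``, which therefore sum to 1 for L >= 3.

For an RNA ``w = R1..RN`` the spectrum counts all 256 4-mers over
``{A, C, G, U}``.  The published normalization divides the counts by
``N - 2`` even though a sequence of length N has ``N - 3`` windows of
length four, so under that convention the entries sum to ``(N-3)/(N-2)``;
it is kept as the default (``denominator_mode="paper"``) because
reproducing the method as published is this package's contract, and
``denominator_mode="exact"`` divides by the true window count instead.

Also here: the amino-acid composition (AAC, 20 letter frequencies) and
nucleotide composition (NC, 4 base frequencies) baselines.
"""

from __future__ import annotations

import numpy as np

from .seqio import (
    MolType,
    PROTEIN_ALPHABET,
    RNA_ALPHABET,
    SEVEN_GROUP_MAP,
    SequenceRecord,
    SequenceError,
)

N_TRIADS = 343
N_FOURMERS = 256

TRIAD_NAMES = tuple(
    f"{g1}{g2}{g3}"
    for g1 in range(1, 8) for g2 in range(1, 8) for g3 in range(1, 8)
)
FOURMER_NAMES = tuple(
    a + b + c + d
    for a in RNA_ALPHABET for b in RNA_ALPHABET
    for c in RNA_ALPHABET for d in RNA_ALPHABET
)

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
_AA_INDEX = {a: i for i, a in enumerate(PROTEIN_ALPHABET)}


def triad_index(g1: int, g2: int, g3: int) -> int:
    """0-based position of group triad (g1,g2,g3), lexicographic order."""
    return 49 * (g1 - 1) + 7 * (g2 - 1) + (g3 - 1)


def fourmer_index(kmer: str) -> int:
    """0-based position of a 4-mer over ACGU, lexicographic order."""
    i = 0
    for b in kmer:
        i = 4 * i + _BASE_INDEX[b]
    return i


def _require(record: SequenceRecord, moltype: MolType) -> None:
    if MolType(record.moltype) is not moltype:
        raise SequenceError(
            f"{record.id}: expected {moltype.value} record, got {record.moltype}"
        )


def encode_ctf_protein(record: SequenceRecord) -> np.ndarray:
    """343-dim conjoint-triad frequency spectrum, f_i = m_i / (L - 2)."""
    _require(record, MolType.protein)
    L = len(record.seq)
    if L < 3:
        raise SequenceError(f"{record.id}: sequence too short for triads (L={L})")
    groups = np.array([SEVEN_GROUP_MAP[a] for a in record.seq])
    idx = 49 * (groups[:-2] - 1) + 7 * (groups[1:-1] - 1) + (groups[2:] - 1)
    counts = np.bincount(idx, minlength=N_TRIADS).astype(float)
    return counts / (L - 2)


def encode_ctf_rna(record: SequenceRecord, *,
                   denominator_mode: str = "paper") -> np.ndarray:
    """256-dim 4-mer frequency spectrum over {A,C,G,U}.

    ``denominator_mode="paper"`` divides the N-3 window counts by N-2 as
    printed; ``"exact"`` divides by the true window count N-3.
    """
    _require(record, MolType.rna)
    if denominator_mode not in ("paper", "exact"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    N = len(record.seq)
    if N < 4:
        raise SequenceError(f"{record.id}: sequence too short for 4-mers (N={N})")
    base = np.array([_BASE_INDEX[b] for b in record.seq])
    idx = 64 * base[:-3] + 16 * base[1:-2] + 4 * base[2:-1] + base[3:]
    counts = np.bincount(idx, minlength=N_FOURMERS).astype(float)
    denom = (N - 2) if denominator_mode == "paper" else (N - 3)
    return counts / denom


def encode_aac(record: SequenceRecord) -> np.ndarray:
    """Amino-acid composition: 20 letter frequencies, alphabetical order."""
    _require(record, MolType.protein)
    idx = np.array([_AA_INDEX[a] for a in record.seq])
    return np.bincount(idx, minlength=20) / len(record.seq)


def encode_nc(record: SequenceRecord) -> np.ndarray:
    """Nucleotide composition: 4 base frequencies in A, C, G, U order."""
    _require(record, MolType.rna)
    idx = np.array([_BASE_INDEX[b] for b in record.seq])
    return np.bincount(idx, minlength=4) / len(record.seq)
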