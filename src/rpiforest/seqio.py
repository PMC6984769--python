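"""Sequence and pair-table I/O, alphabets, and residue-group maps.

Every encoder in the package works on :class:`SequenceRecord` objects whose
sequences have already been sanitized against a fixed alphabet: the 20
standard amino acids for proteins, ``{A, C, G, U}`` for RNA.  The reduced
alphabets used by the encoders also live here:

* the 7-group physicochemical partition of the amino acids used by the
  conjoint-triad encoder, ``{AGV} {ILFP} {YMTS} {HNQW} {RK} {DE} {C}``
  numbered 1..7 in that order;
* a 12-class partition assigning each amino acid to a vertex of the
  12-gon used by the protein chaos-game representation;
* the base-to-vertex map ``A=1, C=2, G=3, U=4`` for the RNA square CGR.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
RNA_ALPHABET = "ACGU"

#: Conjoint-triad 7-group partition, groups numbered 1..7 in printed order.
SEVEN_GROUPS: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

#: Default 12-class partition for the protein CGR 12-gon, obtained by
#: splitting within the 7 conjoint-triad groups.  The published CGR-24
#: variants differ only in this table, so it is data, not code, and can be
#: overridden from a config file (see :func:`load_group_map`).
TWELVE_GROUPS: tuple[str, ...] = (
    "A", "G", "V", "IL", "FP", "YW", "M", "TS", "HNQ", "RK", "DE", "C",
)

SEVEN_GROUP_MAP: dict[str, int] = {
    aa: i + 1 for i, grp in enumerate(SEVEN_GROUPS) for aa in grp
}
TWELVE_GROUP_MAP: dict[str, int] = {
    aa: i + 1 for i, grp in enumerate(TWELVE_GROUPS) for aa in grp
}
RNA_VERTEX_MAP: dict[str, int] = {"A": 1, "C": 2, "G": 3, "U": 4}


class MolType(str, Enum):
    protein = "protein"
    rna = "rna"


class SequenceError(ValueError):
    """Raised for invalid, empty, or unparseable sequence input."""


class PairTableError(ValueError):
    """Raised for malformed pair tables."""


def sanitize(seq: str, moltype: MolType, *, strict: bool = False,
             record_id: str = "<seq>") -> str:
    """Normalize a raw sequence string against the moltype's alphabet.

    Uppercases the input; for RNA maps ``T`` to ``U`` (DNA-style FASTA is
    common).  Remaining out-of-alphabet characters are dropped with a
    warning by default, or raise :class:`SequenceError` if ``strict``.
    """
    moltype = MolType(moltype)
    s = seq.upper().replace(" ", "").replace("\n", "")
    if moltype is MolType.rna:
        s = s.replace("T", "U")
    alphabet = PROTEIN_ALPHABET if moltype is MolType.protein else RNA_ALPHABET
    bad = set(s) - set(alphabet)
    if bad:
        if strict:
            raise SequenceError(
                f"{record_id}: invalid {moltype.value} characters {sorted(bad)}"
            )
        logger.warning(
            "%s: dropping %d non-standard character(s) %s",
            record_id, sum(s.count(c) for c in bad), sorted(bad),
        )
        s = "".join(c for c in s if c in alphabet)
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """An identifier plus a sanitized protein or RNA sequence."""

    id: str
    seq: str
    moltype: MolType

    def __post_init__(self) -> None:
        object.__setattr__(self, "moltype", MolType(self.moltype))
        if not self.seq:
            raise SequenceError(f"empty sequence {self.id}")
        alphabet = (PROTEIN_ALPHABET if self.moltype is MolType.protein
                    else RNA_ALPHABET)
        bad = set(self.seq) - set(alphabet)
        if bad:
            raise SequenceError(
                f"{self.id}: invalid {self.moltype.value} characters "
                f"{sorted(bad)} (sanitize first)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PairRecord:
    """One protein-RNA pair, optionally labeled (1 interacting / 0 not)."""

    protein_id: str
    rna_id: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise PairTableError(
                f"label for ({self.protein_id}, {self.rna_id}) must be 0 or 1, "
                f"got {self.label!r}"
            )


def read_fasta(path: Union[str, Path], moltype: MolType, *,
               strict: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into sanitized :class:`SequenceRecord` objects.

    Record ids are taken from the header up to the first whitespace; entry
    order is preserved.  An empty file, or a record whose sequence is empty
    after sanitization, is an error.
    """
    moltype = MolType(moltype)
    records: list[SequenceRecord] = []
    for entry in _BioSeqIO.parse(str(path), "fasta"):
        seq = sanitize(str(entry.seq), moltype, strict=strict, record_id=entry.id)
        if not seq:
            raise SequenceError(f"empty sequence {entry.id}")
        records.append(SequenceRecord(entry.id, seq, moltype))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    """Write records to FASTA, one entry per record, order preserved."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    _BioSeqIO.write(bio, str(path), "fasta-2line")


def read_pairs(path: Union[str, Path]) -> list[PairRecord]:
    """Read a pair table: TSV columns protein_id, rna_id[, label].

    A header line is optional and detected by a non-numeric third column or
    the literal column names.  The file must be uniformly labeled or
    uniformly unlabeled; labels must be 0 or 1.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) not in (2, 3):
                raise PairTableError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            rows.append([p.strip() for p in parts])
    if not rows:
        raise PairTableError(f"no pairs in {path}")
    first = [c.lower() for c in rows[0]]
    if first[0] in ("protein_id", "protein") and first[1] in ("rna_id", "rna"):
        rows = rows[1:]
        if not rows:
            raise PairTableError(f"no pairs in {path} (header only)")
    pairs: list[PairRecord] = []
    for row in rows:
        if len(row) == 2:
            pairs.append(PairRecord(row[0], row[1]))
        else:
            try:
                label = int(row[2])
            except ValueError:
                raise PairTableError(
                    f"label {row[2]!r} for ({row[0]}, {row[1]}) is not an integer"
                ) from None
            pairs.append(PairRecord(row[0], row[1], label))
    labeled = [p.label is not None for p in pairs]
    if any(labeled) and not all(labeled):
        raise PairTableError(
            f"{path}: mixed labeled and unlabeled rows are not allowed"
        )
    return pairs


def write_pairs(pairs: Iterable[PairRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            if p.label is None:
                fh.write(f"{p.protein_id}\t{p.rna_id}\n")
            else:
                fh.write(f"{p.protein_id}\t{p.rna_id}\t{p.label}\n")


def protein_group7(residue: str) -> int:
    """Group index (1..7) of an amino acid in the conjoint-triad partition."""
    try:
        return SEVEN_GROUP_MAP[residue.upper()]
    except KeyError:
        raise SequenceError(f"unknown amino acid {residue!r}") from None


def protein_group12(residue: str,
                    group_map: Optional[Mapping[str, int]] = None) -> int:
    """Vertex index (1..12) of an amino acid for the protein CGR 12-gon."""
    m = TWELVE_GROUP_MAP if group_map is None else group_map
    try:
        return m[residue.upper()]
    except KeyError:
        raise SequenceError(f"unknown amino acid {residue!r}") from None


def load_group_map(path: Union[str, Path], *, n_groups: int = 12) -> dict[str, int]:
    """Load an amino-acid -> group-index map from a JSON config file.

    The file maps single-letter amino-acid codes to integer group indices.
    The map must cover all 20 standard amino acids and its image must be
    exactly ``{1..n_groups}``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    m = {str(k).upper(): int(v) for k, v in raw.items()}
    missing = set(PROTEIN_ALPHABET) - set(m)
    if missing:
        raise SequenceError(f"group map missing amino acids {sorted(missing)}")
    image = set(m[aa] for aa in PROTEIN_ALPHABET)
    if image != set(range(1, n_groups + 1)):
        raise SequenceError(
            f"group map image {sorted(image)} != 1..{n_groups}"
        )
    return {aa: m[aa] for aa in PROTEIN_ALPHABET}


def index_records(records: Sequence[SequenceRecord]) -> dict[str, SequenceRecord]:
    """Map record id -> record, rejecting duplicate ids."""
    out: dict[str, SequenceRecord] = {}
    for r in records:
        if r.id in out:
            raise SequenceError(f"duplicate sequence id {r.id}")
        out[r.id] = r
    return out
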