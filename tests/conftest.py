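"""Shared fixtures: random sequence factories and tiny PDB complex writer."""

from __future__ import annotations

import numpy as np
import pytest

from rpiforest.seqio import (
    MolType,
    PROTEIN_ALPHABET,
    RNA_ALPHABET,
    SequenceRecord,
)

_PROTEIN_RESNAMES = ["ALA", "GLY", "VAL", "LEU", "SER", "LYS", "ARG", "ASP"]
_RNA_RESNAMES = ["A", "C", "G", "U"]


def random_protein(rng: np.random.Generator, length: int,
                   rec_id: str = "p") -> SequenceRecord:
    seq = "".join(PROTEIN_ALPHABET[i]
                  for i in rng.integers(0, 20, length))
    return SequenceRecord(rec_id, seq, MolType.protein)


def random_rna(rng: np.random.Generator, length: int,
               rec_id: str = "r") -> SequenceRecord:
    seq = "".join(RNA_ALPHABET[i] for i in rng.integers(0, 4, length))
    return SequenceRecord(rec_id, seq, MolType.rna)


def _atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
               x: float, y: float, z: float, occ: float = 1.0,
               altloc: str = " ", element: str = "C") -> str:
    name_field = name.ljust(4) if len(name) >= 4 else (" " + name).ljust(4)
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def make_complex_pdb(path, *, n_protein_res: int = 30, n_rna_res: int = 12,
                     distance: float = 3.0, extra_lines: tuple[str, ...] = (),
                     include_dna_chain: bool = False) -> None:
    """Write a minimal protein+RNA complex whose closest protein-RNA atom
    distance is exactly ``distance`` (for distance < 40).

    Chain A is a protein of CA atoms, chain B an RNA of P atoms; all atoms
    except the two contact atoms sit on rails 100 A apart.
    """
    lines = []
    serial = 1
    for i in range(n_protein_res):
        resname = _PROTEIN_RESNAMES[i % len(_PROTEIN_RESNAMES)]
        if i == 0:
            x, y, z = 0.0, 0.0, 0.0
        else:
            x, y, z = 10.0 * i, 50.0, 0.0
        lines.append(_atom_line(serial, "CA", resname, "A", i + 1, x, y, z))
        serial += 1
    for i in range(n_rna_res):
        resname = _RNA_RESNAMES[i % 4]
        if i == 0:
            x, y, z = distance, 0.0, 0.0
        else:
            x, y, z = 10.0 * i, -50.0, 0.0
        lines.append(_atom_line(serial, "P", resname, "B", i + 1, x, y, z,
                                element="P"))
        serial += 1
    if include_dna_chain:
        for i in range(4):
            lines.append(_atom_line(serial, "P", "DA", "C", i + 1,
                                    10.0 * i, 200.0, 0.0, element="P"))
            serial += 1
    lines.extend(extra_lines)
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def complex_pdb_factory(tmp_path):
    """Return a writer producing tiny PDB complexes in tmp_path."""
    counter = {"n": 0}

    def factory(**kwargs):
        counter["n"] += 1
        path = tmp_path / f"complex{counter['n']}.pdb"
        make_complex_pdb(path, **kwargs)
        return path

    return factory
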