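"""Structure parsing, the strict contact rule, length filters, dataset build."""

import numpy as np
import pytest

from rpiforest.seqio import MolType
from rpiforest.structures import (
    ContactPair,
    StructureError,
    apply_length_filter,
    build_dataset,
    contact_pair,
    extract_chains,
    find_interacting_pairs,
    min_atom_distance,
)

from conftest import make_complex_pdb


class TestExtractChains:
    def test_moltypes_and_sequences(self, complex_pdb_factory):
        path = complex_pdb_factory(n_protein_res=3, n_rna_res=4)
        chains = extract_chains(path)
        assert len(chains) == 2
        prot, rna = chains
        assert prot.moltype is MolType.protein and prot.length == 3
        assert rna.moltype is MolType.rna and rna.sequence == "ACGU"

    def test_dna_chain_skipped_with_warning(self, complex_pdb_factory, caplog):
        path = complex_pdb_factory(include_dna_chain=True)
        with caplog.at_level("WARNING"):
            chains = extract_chains(path)
        assert {c.moltype for c in chains} == {MolType.protein, MolType.rna}
        assert "skipping" in caplog.text

    def test_empty_file_errors(self, tmp_path):
        f = tmp_path / "empty.pdb"
        f.write_text("")
        with pytest.raises(StructureError):
            extract_chains(f)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        # one CA with two conformers: B has higher occupancy at x=7
        lines = [
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C",
            "ATOM      2  CA BALA A   1       7.000   0.000   0.000  0.70  0.00           C",
            "ATOM      3  P     A B   1       0.000   3.000   0.000  1.00  0.00           P",
            "END",
        ]
        f = tmp_path / "alt.pdb"
        f.write_text("\n".join(lines) + "\n")
        chains = extract_chains(f)
        prot = next(c for c in chains if c.moltype is MolType.protein)
        assert prot.n_atoms == 1
        assert prot.coords[0, 0] == pytest.approx(7.0)


class TestContactRule:
    @pytest.mark.parametrize("distance,interacting", [
        (3.0, True),    # under cutoff
        (3.4, False),   # exactly the cutoff: strict "less than"
        (3.5, False),   # over cutoff
    ])
    def test_strict_inequality(self, complex_pdb_factory, distance, interacting):
        chains = extract_chains(complex_pdb_factory(distance=distance))
        pairs = find_interacting_pairs(chains)
        assert bool(pairs) is interacting
        if pairs:
            assert pairs[0].min_atom_distance == pytest.approx(distance)
            assert pairs[0].n_contacts_under_cutoff >= 1

    def test_symmetry(self, complex_pdb_factory):
        prot, rna = extract_chains(complex_pdb_factory(distance=3.0))
        assert min_atom_distance(prot, rna) == pytest.approx(
            min_atom_distance(rna, prot))

    def test_cutoff_monotonicity(self, complex_pdb_factory):
        chains = extract_chains(complex_pdb_factory(distance=3.2))
        at_30 = find_interacting_pairs(chains, cutoff=3.0)
        at_34 = find_interacting_pairs(chains, cutoff=3.4)
        keys_30 = {(p.protein_chain.chain_id, p.rna_chain.chain_id)
                   for p in at_30}
        keys_34 = {(p.protein_chain.chain_id, p.rna_chain.chain_id)
                   for p in at_34}
        assert keys_30 <= keys_34 and keys_34

    def test_brute_force_min_distance(self, complex_pdb_factory):
        chains = extract_chains(
            complex_pdb_factory(n_protein_res=40, n_rna_res=20, distance=2.7))
        prot = next(c for c in chains if c.moltype is MolType.protein)
        rna = next(c for c in chains if c.moltype is MolType.rna)
        assert prot.n_atoms + rna.n_atoms <= 200
        brute = min(
            np.linalg.norm(a - b)
            for a in prot.coords for b in rna.coords
        )
        assert min_atom_distance(prot, rna) == pytest.approx(brute)

    def test_no_rna_chains_gives_empty_list(self, complex_pdb_factory):
        chains = extract_chains(complex_pdb_factory())
        proteins_only = [c for c in chains if c.moltype is MolType.protein]
        assert find_interacting_pairs(proteins_only) == []


class TestLengthFilter:
    def _pair(self, complex_pdb_factory, n_prot, n_rna):
        chains = extract_chains(
            complex_pdb_factory(n_protein_res=n_prot, n_rna_res=n_rna,
                                distance=3.0))
        return contact_pair(chains[0], chains[1])

    def test_default_policy(self, complex_pdb_factory):
        keep = self._pair(complex_pdb_factory, 30, 12)
        assert apply_length_filter(keep) is True
        drop = self._pair(complex_pdb_factory, 20, 12)
        assert apply_length_filter(drop) is False

    def test_both_short_policy(self, complex_pdb_factory):
        # protein short, RNA long: literal reading keeps it
        p = self._pair(complex_pdb_factory, 20, 12)
        assert apply_length_filter(p, mode="both-short") is True
        # both short: dropped under both readings
        p = self._pair(complex_pdb_factory, 24, 9)
        assert apply_length_filter(p) is False
        assert apply_length_filter(p, mode="both-short") is False

    def test_unknown_mode(self, complex_pdb_factory):
        p = self._pair(complex_pdb_factory, 30, 12)
        with pytest.raises(ValueError):
            apply_length_filter(p, mode="sometimes")


class TestBuildDataset:
    def test_single_complex(self, complex_pdb_factory, tmp_path):
        path = complex_pdb_factory(distance=3.0)
        result = build_dataset([path])
        assert len(result.pairs) == 1
        assert result.pairs[0].label == 1
        assert len(result.proteins) == 1 and len(result.rnas) == 1
        out = tmp_path / "ds"
        result.write(out)
        assert (out / "pairs.tsv").exists()
        assert (out / "proteins.fasta").exists()

    def test_date_window_excludes(self, complex_pdb_factory):
        path = complex_pdb_factory(distance=3.0)
        sid = extract_chains(path)[0].structure_id
        result = build_dataset(
            [path], metadata={sid: "2013-06-01"},
            date_from="2014-01-01", date_to="2016-12-31")
        assert result.pairs == []
        result = build_dataset(
            [path], metadata={sid: "2015-06-01"},
            date_from="2014-01-01", date_to="2016-12-31")
        assert len(result.pairs) == 1

    def test_duplicate_files_deduplicated(self, complex_pdb_factory, tmp_path):
        path = complex_pdb_factory(distance=3.0)
        copy = tmp_path / path.name  # same structure id (stem-based)
        copy.write_text(path.read_text())
        result = build_dataset([path, copy])
        assert len(result.pairs) == 1

    def test_parse_failures_skipped_and_counted(self, complex_pdb_factory,
                                                tmp_path):
        bad = tmp_path / "garbage.pdb"
        bad.write_text("this is not a structure\n")
        good = complex_pdb_factory(distance=3.0)
        result = build_dataset([bad, good])
        assert result.summary["parse_failures"] == 1
        assert len(result.pairs) == 1
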