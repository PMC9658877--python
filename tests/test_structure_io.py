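import numpy as np
import pytest

from oligoscan.errors import (DomainMapError, EmptyInputError,
                              EmptySelectionError, StructureParseError)
from oligoscan.structure_io import (AssemblyModel, AtomRecord, Chain, DomainMap,
                                    DomainSpan, Residue, extract_plddt,
                                    read_structure, select_atoms, write_structure)
from oligoscan.synthetic_data import SyntheticSpec, make_chain, make_cn_assembly

ATOM_LINE = ("ATOM      1  CA  ALA A   1       1.000   2.000   3.000"
             "  1.00 90.00           C")


def _model(n_chains=2, n_res=5, bfactor=90.0, atom_names=("N", "CA", "C")):
    chains = []
    serial = 0
    for ci in range(n_chains):
        residues = []
        for ri in range(1, n_res + 1):
            atoms = []
            for ai, name in enumerate(atom_names):
                serial += 1
                atoms.append(AtomRecord(serial, name, name[0], "ALA", ri, "",
                                        chr(65 + ci), (ci * 10.0 + ri, ai * 1.5, 0.25),
                                        1.0, bfactor))
            residues.append(Residue("ALA", ri, "", atoms))
        chains.append(Chain(chr(65 + ci), residues))
    return AssemblyModel(chains)


class TestReadPdb:
    def test_single_atom_field_mapping(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(ATOM_LINE + "\n")
        model = read_structure(path)
        atom = next(model.atoms())
        assert np.allclose(atom.position, [1.0, 2.0, 3.0])
        assert atom.atom_name == "CA" and atom.chain_id == "A"
        assert atom.bfactor == 90.0 and atom.element == "C"

    def test_five_chain_counts(self, tmp_path):
        model = _model(n_chains=5, n_res=100, atom_names=("CA",))
        path = tmp_path / "five.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.n_chains == 5
        assert back.residue_count == 500

    def test_truncated_line_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(ATOM_LINE[:40] + "\n")  # cut before the z field
        with pytest.raises(StructureParseError):
            read_structure(path)

    def test_empty_file_is_empty_input(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    NOTHING\n")
        with pytest.raises(EmptyInputError):
            read_structure(path)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40 10.00           C",
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60 20.00           C",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path)
        atom = next(model.atoms())
        assert atom.position[0] == 2.0 and atom.occupancy == 0.6

    def test_unknown_extension_rejected(self, tmp_path):
        path = tmp_path / "model.xyz"
        path.write_text(ATOM_LINE + "\n")
        with pytest.raises(StructureParseError):
            read_structure(path)


class TestReadMmcif:
    CIF = """data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 1 ? 1.000 2.000 3.000 1.00 88.00 1 ALA A CA 1
ATOM 2 C CA . GLY A 1 2 ? 4.000 5.000 6.000 1.00 77.00 2 GLY A CA 1
"""

    def test_minimal_loop(self, tmp_path):
        path = tmp_path / "mini.cif"
        path.write_text(self.CIF)
        model = read_structure(path)
        assert model.residue_count == 2
        atoms = list(model.atoms())
        assert np.allclose(atoms[0].position, [1.0, 2.0, 3.0])
        assert atoms[1].bfactor == 77.0


class TestWriteRoundTrip:
    def test_round_trip_identities_and_coords(self, tmp_path):
        model = _model(n_chains=2, n_res=7)
        path = tmp_path / "rt.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.chain_ids == model.chain_ids
        assert back.residue_count == model.residue_count
        assert np.allclose(back.coords(), model.coords(), atol=5e-4)

    def test_three_decimal_rounding(self, tmp_path):
        model = _model(n_chains=1, n_res=1, atom_names=("CA",))
        next(model.atoms()).position = np.array([1.23456, 0.0, 0.0])
        path = tmp_path / "round.pdb"
        write_structure(model, path)
        assert "   1.235" in path.read_text()

    def test_round_trip_idempotent(self, tmp_path):
        model = _model()
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(model, p1)
        m1 = read_structure(p1)
        write_structure(m1, p2)
        assert p1.read_text() == p2.read_text()

    def test_synthetic_assembly_round_trip(self, tmp_path):
        chain, _, _ = make_chain(SyntheticSpec(seed=5))
        assembly = make_cn_assembly(chain, 3, 10.0, seed=5)
        path = tmp_path / "asm.pdb"
        write_structure(assembly, path)
        back = read_structure(path)
        assert back.chain_ids == ["A", "B", "C"]
        assert np.allclose(back.coords(), assembly.coords(), atol=5e-4)

    def test_empty_model_rejected(self, tmp_path):
        with pytest.raises(EmptyInputError):
            AssemblyModel([])


class TestSelectAtoms:
    def test_domain_selection_counts(self):
        model = _model(n_chains=2, n_res=250)
        dm = DomainMap([DomainSpan("BTB", 1, 100)])
        sub = select_atoms(model, domain="BTB", domain_map=dm)
        assert all(len(c.residues) == 100 for c in sub.chains)

    def test_ca_selection_counts(self):
        model = _model(n_chains=1, n_res=9)
        sub = select_atoms(model, atom_names={"CA"})
        assert sub.atom_count == 9

    def test_missing_domain_errors(self):
        model = _model()
        dm = DomainMap([DomainSpan("BTB", 1, 3)])
        with pytest.raises(DomainMapError):
            select_atoms(model, domain="CTD", domain_map=dm)

    def test_missing_chain_errors(self):
        with pytest.raises(KeyError):
            select_atoms(_model(), chain_ids={"Z"})

    def test_empty_selection_errors(self):
        model = _model(atom_names=("CA",))
        with pytest.raises(EmptySelectionError):
            select_atoms(model, atom_names={"CB"})

    def test_selection_is_projection(self):
        model = _model(n_chains=3, n_res=20)
        dm = DomainMap([DomainSpan("BTB", 1, 10)])
        once = select_atoms(model, chain_ids={"A", "B"}, domain="BTB",
                            domain_map=dm, atom_names={"CA"})
        twice = select_atoms(once, chain_ids={"A", "B"}, domain="BTB",
                             domain_map=dm, atom_names={"CA"})
        assert np.allclose(once.coords(), twice.coords())
        assert once.segmentation() == twice.segmentation()


class TestExtractPlddt:
    def test_uniform_bfactors(self):
        series = extract_plddt(_model(bfactor=90.0))
        assert np.all(series.values == 90.0) and not series.out_of_range

    def test_mean_fallback_without_ca(self):
        model = _model(atom_names=("N", "C", "O"), bfactor=80.0)
        series = extract_plddt(model)
        assert np.all(series.values == 80.0)

    def test_out_of_range_flag(self):
        series = extract_plddt(_model(bfactor=250.0))
        assert series.out_of_range


class TestDomainMap:
    def test_tsv_round_trip(self, tmp_path):
        dm = DomainMap([DomainSpan("BTB", 1, 24), DomainSpan("hinge", 25, 28),
                        DomainSpan("CTD", 29, 58)])
        path = tmp_path / "domains.tsv"
        dm.to_tsv(path, protein="prot1")
        back = DomainMap.from_tsv(path)
        assert back.residues("BTB") == list(range(1, 25))
        assert back.residues("CTD") == list(range(29, 59))

    def test_overlap_rejected(self):
        with pytest.raises(DomainMapError):
            DomainMap([DomainSpan("BTB", 1, 10), DomainSpan("CTD", 10, 20)])

    def test_reversed_span_rejected(self):
        with pytest.raises(DomainMapError):
            DomainSpan("BTB", 10, 1)

    def test_domain_of(self, two_domain_map):
        assert two_domain_map.domain_of(1) == "BTB"
        assert two_domain_map.domain_of(26) == "hinge"
        assert two_domain_map.domain_of(58) == "CTD"
        assert two_domain_map.domain_of(59) is None


def test_segmentation_matches_pae_indexing(c5_assembly):
    # the shared segmentation object links structure order and PAE indexing
    seg = c5_assembly.segmentation()
    assert [cid for cid, _ in seg] == c5_assembly.chain_ids
    assert sum(n for _, n in seg) == c5_assembly.residue_count
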