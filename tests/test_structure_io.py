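"""Structure reading, annotation and conserved-disulfide detection."""

import numpy as np
import pytest

import tcrpmhc as t
from tcrpmhc.errors import AnnotationError, CysDetectionError
from tcrpmhc.structure import AtomRecord, Chain, Residue, StructureModel

TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.935  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
END
"""


def _cys_chain(sg_positions, chain_id="D", residue_names=None, with_sg=True):
    chain = Chain(chain_id)
    for i, pos in enumerate(sg_positions):
        seq = 20 + i * 10
        name = (residue_names or ["CYS"] * len(sg_positions))[i]
        res = Residue(name=name, seq=seq)
        atom_name = "SG" if with_sg else "CA"
        res.atoms.append(AtomRecord(
            name=atom_name, element="S" if with_sg else "C",
            coords=np.asarray(pos, float), residue_name=name,
            residue_seq=seq, chain_id=chain_id))
        chain.add_residue(res)
    return chain


class TestReadStructure:
    def test_toy_pdb_record_count(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        model = t.read_structure(path, format="pdb")
        assert len(model.chains) == 1
        assert model.n_atoms() == 3
        np.testing.assert_allclose(
            model.chain("A").get(1).find_atom("CA").coords,
            [11.639, 6.071, -5.147],
        )

    def test_mmcif_equivalence(self, tmp_path):
        """The same coordinates via mmCIF parse to identical atoms."""
        import gemmi

        pdb_path = tmp_path / "toy.pdb"
        pdb_path.write_text(TOY_PDB)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "toy.cif"
        st.make_mmcif_document().write_file(str(cif_path))

        from_pdb = t.read_structure(pdb_path, format="pdb")
        from_cif = t.read_structure(cif_path, format="mmcif")
        atoms_pdb = list(from_pdb.atoms())
        atoms_cif = list(from_cif.atoms())
        assert len(atoms_pdb) == len(atoms_cif)
        for a, b in zip(atoms_pdb, atoms_cif):
            assert a.name == b.name and a.residue_seq == b.residue_seq
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-3)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        model = t.read_structure(path, format="pdb")
        res = model.chain("A").get(1)
        assert len(res.atoms) == 1
        assert res.atoms[0].coords[0] == pytest.approx(1.0)  # occ 0.60 wins

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(t.errors.ParseError):
            t.read_structure(tmp_path / "missing.pdb")

    def test_unknown_format_raises(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        with pytest.raises(t.errors.FormatError):
            t.read_structure(path, format="xyz")

    def test_pdb_round_trip_preserves_coordinates(self, toy_complex, tmp_path):
        """Write + re-read reproduces coordinates at PDB 3-decimal precision."""
        path = tmp_path / "round.pdb"
        t.write_pdb(toy_complex.structure, path)
        back = t.read_structure(path, format="pdb")
        orig = np.array([a.coords for a in toy_complex.structure.atoms()])
        redo = np.array([a.coords for a in back.atoms()])
        assert orig.shape == redo.shape
        np.testing.assert_allclose(orig, redo, atol=5.1e-4)


class TestAnnotateComplex:
    def _five_chain_model(self, pep_lengths=(9,)):
        lengths = {"A": 20, "B": 15, "D": 20, "E": 20}
        chains = []
        y = 0.0
        for cid, n in lengths.items():
            chain = Chain(cid)
            for i in range(n):
                res = Residue(name="GLY", seq=i + 1)
                res.atoms.append(AtomRecord(
                    name="CA", element="C", coords=[i * 3.8, y, 0.0],
                    residue_name="GLY", residue_seq=i + 1, chain_id=cid))
                chain.add_residue(res)
            chains.append(chain)
            y += 10.0
        for k, n in enumerate(pep_lengths):
            cid = "C" if k == 0 else chr(ord("F") + k)
            chain = Chain(cid)
            for i in range(n):
                res = Residue(name="GLY", seq=i + 1)
                res.atoms.append(AtomRecord(
                    name="CA", element="C", coords=[i * 3.5, y, 0.0],
                    residue_name="GLY", residue_seq=i + 1, chain_id=cid))
                chain.add_residue(res)
            chains.append(chain)
            y += 10.0
        return StructureModel("five_chain", chains)

    ROLES = {"A": "mhc_heavy", "B": "b2m", "C": "peptide",
             "D": "tcr_alpha", "E": "tcr_beta"}

    def test_explicit_roles_pass_through(self):
        model = self._five_chain_model()
        ac = t.annotate_complex(model, {"roles": self.ROLES})
        assert ac.annotation.role_map == self.ROLES
        assert ac.annotation.has_roles(*self.ROLES.values())

    def test_peptide_auto_detection(self):
        model = self._five_chain_model()
        roles = {k: v for k, v in self.ROLES.items() if k != "C"}
        ac = t.annotate_complex(model, {"roles": roles, "peptide": "auto"})
        assert ac.annotation.chain_for_role("peptide") == "C"

    def test_peptide_auto_ambiguous_raises(self):
        model = self._five_chain_model(pep_lengths=(9, 9))
        roles = {k: v for k, v in self.ROLES.items() if k != "C"}
        with pytest.raises(AnnotationError, match="auto-detection"):
            t.annotate_complex(model, {"roles": roles, "peptide": "auto"})

    def test_duplicate_role_raises(self):
        model = self._five_chain_model()
        roles = dict(self.ROLES, B="mhc_heavy")
        with pytest.raises(AnnotationError):
            t.annotate_complex(model, {"roles": roles})

    def test_unknown_chain_raises(self):
        model = self._five_chain_model()
        with pytest.raises(AnnotationError):
            t.annotate_complex(model, {"roles": dict(self.ROLES, Z="peptide")})

    def test_annotation_idempotent(self, toy_complex):
        """Re-annotating with the same config changes nothing."""
        ann = toy_complex.annotation
        config = {
            "roles": dict(ann.role_map),
            "cdr_ranges": {cid: {k: list(v) for k, v in r.items()}
                           for cid, r in ann.cdr_ranges.items()},
            "helix_ranges": {k: list(v) for k, v in ann.helix_ranges.items()},
        }
        again = t.annotate_complex(toy_complex.structure, config)
        assert again.annotation.role_map == ann.role_map
        assert again.annotation.cdr_ranges == ann.cdr_ranges
        assert again.annotation.helix_ranges == ann.helix_ranges

    def test_default_loop_ranges_applied(self):
        model = self._five_chain_model()
        ac = t.annotate_complex(model, {"roles": self.ROLES})
        assert ac.annotation.cdr_ranges["D"]["CDR3"] == (105, 117)
        assert ac.annotation.helix_ranges["alpha2"] == (138, 176)


class TestDetectConservedCys:
    def test_single_disulfide_found(self):
        chain = _cys_chain([(0, 0, 0), (2.05, 0, 0)])
        pair = t.detect_conserved_cys(chain)
        assert pair.positions == ((20, ""), (30, ""))
        assert not pair.any_fallback

    def test_unique_qualifying_pair_among_three(self):
        """Three Cys: enumeration keeps only the pair within 2.5 A."""
        sgs = [(0, 0, 0), (2.05, 0, 0), (30, 0, 0)]
        chain = _cys_chain(sgs)
        # independent oracle: brute-force pair enumeration
        expected = [
            (i, j) for i in range(3) for j in range(i + 1, 3)
            if np.linalg.norm(np.subtract(sgs[i], sgs[j])) <= 2.5
        ]
        assert expected == [(0, 1)]
        pair = t.detect_conserved_cys(chain)
        assert pair.positions == ((20, ""), (30, ""))

    def test_override_with_ca_fallback_flagged(self):
        chain = Chain("D")
        for seq, with_sg in ((23, False), (104, True)):
            res = Residue(name="CYS" if with_sg else "GLY", seq=seq)
            if with_sg:
                res.atoms.append(AtomRecord(
                    name="SG", element="S", coords=[0, 4, 0],
                    residue_name="CYS", residue_seq=seq, chain_id="D"))
            res.atoms.append(AtomRecord(
                name="CA", element="C", coords=[0, 0, seq / 10],
                residue_name=res.name, residue_seq=seq, chain_id="D"))
            chain.add_residue(res)
        pair = t.detect_conserved_cys(chain, override=(23, 104))
        assert pair.used_ca == (True, False)
        assert pair.any_fallback

    def test_no_pair_raises(self):
        chain = _cys_chain([(0, 0, 0), (10, 0, 0)])
        with pytest.raises(CysDetectionError):
            t.detect_conserved_cys(chain)

    def test_invariant_under_rigid_motion(self, rigid_transform):
        chain = _cys_chain([(0, 0, 0), (2.05, 0, 0), (30, 0, 0)])
        pair = t.detect_conserved_cys(chain)
        rot, trans = rigid_transform(7)
        moved = StructureModel("m", [chain]).transformed(rot, trans)
        assert t.detect_conserved_cys(moved.chain("D")).positions == pair.positions
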