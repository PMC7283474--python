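"""pMHC reference frame and docking descriptors."""

import numpy as np
import pytest

import tcrpmhc as t
from tcrpmhc.errors import GeometryError, RankingError
from tcrpmhc.frames import (
    ReferenceFrame,
    incident_angle,
    rank_percentile,
)
from tcrpmhc.structure import AtomRecord, Chain, Residue, StructureModel

IDENTITY_FRAME = ReferenceFrame(
    origin=np.zeros(3),
    x_axis=np.array([1.0, 0, 0]),
    y_axis=np.array([0, 1.0, 0]),
    z_axis=np.array([0, 0, 1.0]),
)


def _translated(complex, shift):
    return complex.transformed(np.eye(3), np.asarray(shift, float))


class TestBuildMhcFrame:
    def test_canonical_toy_gives_identity_axes(self):
        """Helix C-alphas in z=0 with the peptide along +x give the canonical
        frame with origin at the helix C-alpha mean."""
        pmhc = t.make_toy_pmhc()
        frame = t.build_mhc_frame(pmhc)
        helix_cas = []
        heavy = pmhc.chain_for_role("mhc_heavy")
        for lo, hi in pmhc.annotation.helix_ranges.values():
            for res in heavy.polymer_residues():
                if lo <= res.seq <= hi:
                    helix_cas.append(res.find_atom("CA").coords)
        np.testing.assert_allclose(frame.origin, np.mean(helix_cas, axis=0),
                                   atol=1e-9)
        np.testing.assert_allclose(frame.x_axis, [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(frame.z_axis, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(frame.y_axis, [0, 1, 0], atol=1e-9)

    def test_translation_moves_origin_not_axes(self):
        pmhc = t.make_toy_pmhc()
        frame = t.build_mhc_frame(pmhc)
        moved = t.build_mhc_frame(_translated(pmhc, (5.0, 5.0, 5.0)))
        np.testing.assert_allclose(moved.origin, frame.origin + 5.0, atol=1e-9)
        for axis in ("x_axis", "y_axis", "z_axis"):
            np.testing.assert_allclose(getattr(moved, axis),
                                       getattr(frame, axis), atol=1e-9)

    def test_peptide_reversal_flips_x_axis(self):
        """Greater x must point toward the peptide C-terminus."""
        pmhc = t.make_toy_pmhc()
        frame = t.build_mhc_frame(pmhc)
        pep = pmhc.chain_for_role("peptide")
        coords = [r.find_atom("CA").coords.copy() for r in pep.residues]
        for res, xyz in zip(pep.residues, reversed(coords)):
            res.atoms[0].coords = xyz
        flipped = t.build_mhc_frame(pmhc)
        np.testing.assert_allclose(flipped.x_axis, -frame.x_axis, atol=1e-9)

    def test_axes_orthonormal_and_deterministic(self, toy_complex):
        f1 = t.build_mhc_frame(toy_complex)
        f2 = t.build_mhc_frame(toy_complex)
        axes = np.stack([f1.x_axis, f1.y_axis, f1.z_axis])
        np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(np.cross(f1.x_axis, f1.y_axis), f1.z_axis,
                                   atol=1e-12)
        np.testing.assert_allclose(f1.origin, f2.origin)

    def test_collinear_helices_raise(self):
        heavy = Chain("M")
        for i in range(80):
            seq = 50 + i if i < 40 else 138 + (i - 40)
            res = Residue(name="GLY", seq=seq)
            res.atoms.append(AtomRecord(
                name="CA", element="C", coords=[i * 1.5, 0, 0],
                residue_name="GLY", residue_seq=seq, chain_id="M"))
            heavy.add_residue(res)
        pep = Chain("C")
        for j in range(9):
            res = Residue(name="GLY", seq=j + 1)
            res.atoms.append(AtomRecord(
                name="CA", element="C", coords=[j * 3.5, 1, 0],
                residue_name="GLY", residue_seq=j + 1, chain_id="C"))
            pep.add_residue(res)
        ac = t.annotate_complex(
            StructureModel("degenerate", [heavy, pep]),
            {"roles": {"M": "mhc_heavy", "C": "peptide"}},
        )
        with pytest.raises(t.errors.FrameError):
            t.build_mhc_frame(ac)


class TestDomainCenterAndProjection:
    def test_center_is_anchor_midpoint(self):
        from tcrpmhc.structure import CysPair

        chain = Chain("D")
        for seq, xyz in ((23, (0, 0, 0)), (104, (2, 0, 0))):
            res = Residue(name="CYS", seq=seq)
            res.atoms.append(AtomRecord(
                name="SG", element="S", coords=list(xyz), residue_name="CYS",
                residue_seq=seq, chain_id="D"))
            chain.add_residue(res)
        center, fallback = t.domain_center(
            chain, CysPair(positions=((23, ""), (104, "")))
        )
        np.testing.assert_allclose(center, [1, 0, 0])
        assert not fallback

    def test_ca_fallback_midpoint_flagged(self):
        from tcrpmhc.structure import CysPair

        chain = Chain("D")
        res1 = Residue(name="CYS", seq=23)
        res1.atoms.append(AtomRecord(name="SG", element="S", coords=[0, 0, 0],
                                     residue_name="CYS", residue_seq=23,
                                     chain_id="D"))
        res2 = Residue(name="GLY", seq=104)
        res2.atoms.append(AtomRecord(name="CA", element="C", coords=[0, 4, 0],
                                     residue_name="GLY", residue_seq=104,
                                     chain_id="D"))
        chain.add_residue(res1)
        chain.add_residue(res2)
        center, fallback = t.domain_center(
            chain, CysPair(positions=((23, ""), (104, "")), used_ca=(False, True))
        )
        np.testing.assert_allclose(center, [0, 2, 0])
        assert fallback

    def test_same_atom_twice_raises(self):
        from tcrpmhc.structure import CysPair

        chain = Chain("D")
        for seq in (23, 104):
            res = Residue(name="CYS", seq=seq)
            res.atoms.append(AtomRecord(name="SG", element="S", coords=[1, 1, 1],
                                        residue_name="CYS", residue_seq=seq,
                                        chain_id="D"))
            chain.add_residue(res)
        with pytest.raises(GeometryError):
            t.domain_center(chain, CysPair(positions=((23, ""), (104, ""))))

    def test_projection_arithmetic(self):
        center, x, y = t.tcr_center_projection(
            np.array([10.0, 0, 8]), np.array([14.0, 4, 12]), IDENTITY_FRAME
        )
        np.testing.assert_allclose(center, [12, 2, 10])
        assert (x, y) == (12.0, 2.0)

    def test_symmetric_centers_project_to_origin(self):
        _, x, y = t.tcr_center_projection(
            np.array([3.0, -2, 5]), np.array([-3.0, 2, -5]), IDENTITY_FRAME
        )
        assert (x, y) == (0.0, 0.0)

    def test_projection_invariant_under_common_translation(self):
        va, vb = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        shift = np.array([7.0, -3, 2])
        frame = ReferenceFrame(origin=shift, x_axis=IDENTITY_FRAME.x_axis,
                               y_axis=IDENTITY_FRAME.y_axis,
                               z_axis=IDENTITY_FRAME.z_axis)
        _, x0, y0 = t.tcr_center_projection(va, vb, IDENTITY_FRAME)
        _, x1, y1 = t.tcr_center_projection(va + shift, vb + shift, frame)
        assert (x0, y0) == pytest.approx((x1, y1))


class TestAngles:
    def test_crossing_axis_aligned(self):
        va = np.zeros(3)
        assert t.crossing_angle(va, np.array([5.0, 0, 0]), IDENTITY_FRAME) == \
            pytest.approx(0.0)
        assert t.crossing_angle(va, np.array([0, 5.0, 0]), IDENTITY_FRAME) == \
            pytest.approx(90.0)

    def test_crossing_round_trip_through_generator(self):
        c = t.make_toy_tcr_pmhc(t.ToyComplexSpec(crossing_angle=51.0,
                                                 incident_angle=0.0))
        assert t.docking_geometry(c).crossing_angle == pytest.approx(51.0, abs=1e-6)

    def test_crossing_undefined_for_vertical_vector(self):
        with pytest.raises(GeometryError):
            t.crossing_angle(np.zeros(3), np.array([0, 0, 5.0]), IDENTITY_FRAME)

    def test_incident_in_plane_and_vertical(self):
        va = np.zeros(3)
        assert incident_angle(va, np.array([5.0, 3, 0]), IDENTITY_FRAME) == \
            pytest.approx(0.0)
        assert incident_angle(va, np.array([0, 0, 4.0]), IDENTITY_FRAME) == \
            pytest.approx(90.0)

    def test_incident_round_trip_through_generator(self):
        c = t.make_toy_tcr_pmhc(t.ToyComplexSpec(crossing_angle=30.0,
                                                 incident_angle=27.0))
        assert t.docking_geometry(c).incident_angle == pytest.approx(27.0, abs=1e-6)

    def test_zero_vector_raises(self):
        with pytest.raises(GeometryError):
            incident_angle(np.ones(3), np.ones(3), IDENTITY_FRAME)

    def test_unknown_strategy_raises(self):
        with pytest.raises(GeometryError):
            incident_angle(np.zeros(3), np.ones(3), IDENTITY_FRAME,
                           strategy="nonexistent")

    def test_crossing_angle_reflection_symmetric(self, toy_complex):
        """Reflecting the TCR across the x-z plane keeps the unsigned angle."""
        geom = t.docking_geometry(toy_complex)
        frame = t.build_mhc_frame(toy_complex)

        def reflect(p):
            rel = p - frame.origin
            y = np.dot(rel, frame.y_axis)
            return p - 2 * y * frame.y_axis

        mirrored = t.crossing_angle(reflect(geom.valpha_center),
                                    reflect(geom.vbeta_center), frame)
        assert mirrored == pytest.approx(geom.crossing_angle, abs=1e-9)


class TestRigidInvariance:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_descriptors_invariant_under_rigid_motion(self, seed, rigid_transform):
        spec = t.ToyComplexSpec(crossing_angle=34.0, incident_angle=27.0,
                                x_pos=1.5, y_pos=-2.0)
        complex = t.make_toy_tcr_pmhc(spec)
        rot, trans = rigid_transform(seed)
        moved = complex.transformed(rot, trans)
        g0 = t.docking_geometry(complex)
        g1 = t.docking_geometry(moved)
        for key, value in g0.as_dict().items():
            assert g1.as_dict()[key] == pytest.approx(value, abs=1e-6), key


class TestRankPercentile:
    def _table(self, n_above, n_rows=135, query=50.0):
        """Reference values giving the query a known rank among n_rows + 1."""
        above = query + 1 + np.arange(n_above)
        below = query - 1 - np.arange(n_rows - n_above)
        return np.concatenate([above, below])

    def test_rank_4_of_136_is_97th_percentile(self):
        rank, pct = rank_percentile(50.0, self._table(3))
        assert (rank, pct) == (4, 97)

    def test_rank_14_of_136_is_90th_percentile(self):
        rank, pct = rank_percentile(50.0, self._table(13))
        assert (rank, pct) == (14, 90)

    def test_query_above_all_rows_ranks_first(self):
        rank, pct = rank_percentile(1000.0, self._table(13))
        assert rank == 1

    def test_empty_table_raises(self):
        with pytest.raises(RankingError):
            rank_percentile(1.0, np.array([]))

    @pytest.mark.parametrize("n_above", [0, 1, 17, 135])
    def test_rank_counts_strictly_greater_rows(self, n_above):
        rank, pct = rank_percentile(50.0, self._table(n_above))
        assert rank == n_above + 1
        assert pct == int(np.floor(100 * (1 - rank / 136) + 0.5))
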