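"""3D screening: query embedding, rigid alignment, volumetric shape
similarity (incl. the analytic sphere check), pharmacophore fingerprints
and the full best-pair search against a brute-force oracle."""

import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdDepictor

from vscreen import dbprep, shape
from vscreen.models import ScreenDB, VScreenError
from conftest import record_from_smiles


class TestEmbedQuery:
    def test_existing_3d_coordinates_preserved(self, tmp_path):
        rec = dbprep.generate_conformers(record_from_smiles("CCO"), max_confs=1, seed=1)
        path = tmp_path / "pose.sdf"
        writer = Chem.SDWriter(str(path))
        mol = rec.to_mol(with_conformers=True)
        mol.SetProp("_Name", "pose")
        writer.write(mol)
        writer.close()
        loaded, _ = dbprep.parse_library(path)
        out = shape.embed_query(loaded[0])
        assert len(out.conformers) == 1
        assert np.allclose(out.conformers[0].coordinates, rec.conformers[0].coordinates, atol=1e-4)

    def test_2d_query_deterministic(self):
        a = shape.embed_query(record_from_smiles("CCOCCN"), n_confs=5, seed=3)
        b = shape.embed_query(record_from_smiles("CCOCCN"), n_confs=5, seed=3)
        assert len(a.conformers) == len(b.conformers)
        for ca, cb in zip(a.conformers, b.conformers):
            assert np.allclose(ca.coordinates, cb.coordinates, atol=1e-6)

    def test_rigid_ring_single_conformer(self):
        out = shape.embed_query(record_from_smiles("c1ccccc1"), n_confs=8, seed=2)
        assert len(out.conformers) == 1


def _rigid_motion(coords, angle=0.7, axis=(0.0, 0.0, 1.0), shift=(3.0, -1.0, 2.0)):
    axis = np.asarray(axis) / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    x, y, z = axis
    rot = np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])
    return coords @ rot.T + np.asarray(shift)


@pytest.fixture(scope="module")
def embedded():
    return dbprep.generate_conformers(
        record_from_smiles("Nc1ccc(C(=O)O)cc1"), max_confs=1, seed=6
    )


class TestAlignPair:

    def test_self_alignment_recovers_overlay(self, embedded):
        mol = embedded.to_mol(with_conformers=True)
        aln = shape.align_pair(mol, 0, Chem.Mol(mol), 0, weighting="mmff")
        rmsd = np.sqrt(
            ((aln.aligned_coords - embedded.conformers[0].coordinates) ** 2).sum(axis=1).mean()
        )
        assert rmsd < 1e-3

    def test_rotated_copy_recovered(self, embedded):
        mol = embedded.to_mol(with_conformers=True)
        moved = Chem.Mol(mol)
        new_coords = _rigid_motion(embedded.conformers[0].coordinates)
        conf = moved.GetConformer(0)
        for i, (x, y, z) in enumerate(new_coords):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        aln = shape.align_pair(mol, 0, moved, 0, weighting="mmff")
        rmsd = np.sqrt(
            ((aln.aligned_coords - embedded.conformers[0].coordinates) ** 2).sum(axis=1).mean()
        )
        assert rmsd < 1e-2

    @pytest.mark.parametrize("weighting", ["mmff", "crippen"])
    def test_transform_is_proper_rigid(self, embedded, weighting):
        mol = embedded.to_mol(with_conformers=True)
        aln = shape.align_pair(mol, 0, Chem.Mol(mol), 0, weighting=weighting)
        rot = aln.rotation
        assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-6)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-6)
        # aligned_coords must equal the transform applied to the inputs
        applied = aln.apply(embedded.conformers[0].coordinates)
        assert np.allclose(applied, aln.aligned_coords, atol=1e-6)

    def test_unknown_weighting_fatal(self, embedded):
        mol = embedded.to_mol(with_conformers=True)
        with pytest.raises(VScreenError, match="weighting"):
            shape.align_pair(mol, 0, mol, 0, weighting="gasteiger")


class TestShapeSimilarity:
    def test_identity_all_metrics(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.7, 1.2, 0]])
        for metric in shape.SHAPE_METRICS:
            assert shape.shape_similarity(coords, coords, metric) >= 0.99

    def test_disjoint_volumes(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[100.0, 0, 0]])
        assert shape.shape_similarity(a, b, "tanimoto") == pytest.approx(0.0, abs=1e-9)

    def test_unit_spheres_match_analytic_lens_volume(self):
        # two unit spheres, centers 1 Å apart: lens volume
        # V = pi (4r + d)(2r - d)^2 / 12, Tanimoto = V / (2*(4/3 pi) - V)
        d, r = 1.0, 1.0
        lens = math.pi * (4 * r + d) * (2 * r - d) ** 2 / 12
        sphere = 4 * math.pi * r**3 / 3
        analytic = lens / (2 * sphere - lens)
        grid = shape.shape_similarity(
            np.array([[0.0, 0, 0]]), np.array([[d, 0, 0]]),
            "tanimoto", radii_a=r, radii_b=r, spacing=0.2,
        )
        assert grid == pytest.approx(analytic, abs=0.02)

    def test_tversky_equal_weights_is_tanimoto(self):
        a = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        b = np.array([[0.5, 0.3, 0], [1.0, 0.4, 0]])
        tani = shape.shape_similarity(a, b, "tanimoto")
        tv = shape.shape_similarity(a, b, "tversky", alpha=1.0, beta=1.0)
        assert tv == pytest.approx(tani, abs=1e-12)

    def test_protrude_is_asymmetric(self):
        small = np.array([[0.0, 0, 0]])
        big = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        ab = shape.shape_similarity(small, big, "protrude")
        ba = shape.shape_similarity(big, small, "protrude")
        assert ab > ba  # the single atom is mostly inside the larger volume

    def test_symmetry_of_tanimoto(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(5, 3))
        assert shape.shape_similarity(a, b) == pytest.approx(
            shape.shape_similarity(b, a), abs=1e-12
        )

    def test_empty_coordinates_fatal(self):
        with pytest.raises(VScreenError):
            shape.shape_similarity(np.empty((0, 3)), np.array([[0.0, 0, 0]]))

    @pytest.mark.parametrize("pair", [("Nc1ccc(O)cc1", "O=C(O)c1ccccc1"),
                                      ("CCO", "CCN"),
                                      ("c1ccccc1", "C1CCCCC1")])
    def test_cross_check_against_independent_grid_encoder(self, pair):
        # rdShapeHelpers discretizes differently (soft spheres, its own
        # grid); the two estimates of the same overlap must agree closely
        from rdkit.Chem import rdShapeHelpers

        a = dbprep.generate_conformers(record_from_smiles(pair[0]), 1, seed=1)
        b = dbprep.generate_conformers(record_from_smiles(pair[1]), 1, seed=1)
        ma, mb = a.to_mol(with_conformers=True), b.to_mol(with_conformers=True)
        aln = shape.align_pair(ma, 0, mb, 0, "mmff")
        conf = mb.GetConformer(0)
        for i, (x, y, z) in enumerate(aln.aligned_coords):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        mine = shape.shape_similarity(
            a.conformers[0].coordinates, aln.aligned_coords,
            radii_a=shape.vdw_radii(ma), radii_b=shape.vdw_radii(mb),
        )
        ref = 1 - rdShapeHelpers.ShapeTanimotoDist(ma, mb, confId1=0, confId2=0)
        assert mine == pytest.approx(ref, abs=0.1)


class TestPharm3D:
    def test_self_similarity_is_one(self, conformer_db):
        rec = conformer_db.get("aminophenol")
        mol = rec.to_mol(with_conformers=True)
        coords = rec.conformers[0].coordinates
        assert shape.pharm3d_similarity(mol, coords, mol, coords) == 1.0

    def test_aromatic_bits_distinguish_aromatic_from_saturated_ring(self):
        # phenol vs cyclohexanol: aromatic-feature pairs exist only for the
        # aromatic ring (a 2-point schema needs a partner feature, so the
        # hydroxyl provides the second point in both molecules)
        benz = dbprep.generate_conformers(record_from_smiles("Oc1ccccc1"), 1, seed=1)
        cyhx = dbprep.generate_conformers(record_from_smiles("OC1CCCCC1"), 1, seed=1)
        bits_b = shape.pharm3d_fingerprint(
            benz.to_mol(with_conformers=True), benz.conformers[0].coordinates
        )
        bits_c = shape.pharm3d_fingerprint(
            cyhx.to_mol(with_conformers=True), cyhx.conformers[0].coordinates
        )
        assert bits_b != bits_c
        sim = shape.pharm3d_similarity(
            benz.to_mol(with_conformers=True), benz.conformers[0].coordinates,
            cyhx.to_mol(with_conformers=True), cyhx.conformers[0].coordinates,
        )
        assert sim < 1.0

    def test_featureless_molecule_scores_zero(self, conformer_db):
        pentane = dbprep.generate_conformers(record_from_smiles("CCCCC"), 1, seed=1)
        rec = conformer_db.get("aminophenol")
        sim = shape.pharm3d_similarity(
            rec.to_mol(with_conformers=True), rec.conformers[0].coordinates,
            pentane.to_mol(with_conformers=True), pentane.conformers[0].coordinates,
        )
        assert sim == 0.0

    def test_bit_vector_schema_size(self):
        # 6 feature families -> 21 unordered pairs x 5 distance bins
        assert shape.pharm_fp_size() == 105


class TestShapeSearch:
    def test_self_retrieval_rank_one(self, conformer_db):
        query = conformer_db.records[0].copy()
        query.record_id = "spiked_query"
        hits = shape.shape_search(query, conformer_db, top_k=3, seed=11)
        assert hits[0].record_id == conformer_db.records[0].record_id
        assert hits[0].shape_sim >= 0.99
        assert hits[0].combo >= 0.99

    def test_combo_is_arithmetic_mean(self, conformer_db):
        query = conformer_db.records[1].copy()
        for h in shape.shape_search(query, conformer_db, top_k=3, seed=11):
            assert h.combo == pytest.approx((h.shape_sim + h.pharm_sim) / 2, abs=1e-12)
            assert min(h.shape_sim, h.pharm_sim) <= h.combo <= max(h.shape_sim, h.pharm_sim)

    def test_best_pair_equals_exhaustive_double_loop(self, conformer_db):
        """The reported conformer pair and score must equal an independent
        exhaustive recomputation over all query x database conformer pairs."""
        query = shape.embed_query(
            record_from_smiles("Oc1ccc(N)cc1", "q"), n_confs=3, seed=13
        )
        hits = shape.shape_search(
            query, conformer_db, top_k=len(conformer_db), seed=13
        )
        qmol = query.to_mol(with_conformers=True)
        for hit in hits:
            rec = conformer_db.get(hit.record_id)
            dmol = rec.to_mol(with_conformers=True)
            best = (-1.0, None, None)
            for qc in query.conformers:
                for dc in rec.conformers:
                    aln = shape.align_pair(qmol, qc.conf_id, dmol, dc.conf_id, "mmff")
                    if aln is None:
                        continue
                    s = shape.shape_similarity(
                        qc.coordinates, aln.aligned_coords,
                        radii_a=shape.vdw_radii(qmol), radii_b=shape.vdw_radii(dmol),
                    )
                    if s > best[0]:
                        best = (s, qc.conf_id, dc.conf_id)
            assert hit.shape_sim == pytest.approx(best[0], abs=1e-12)
            assert (hit.best_query_conf, hit.best_db_conf) == (best[1], best[2])

    def test_ranking_invariant_to_db_order(self, conformer_db):
        query = conformer_db.records[0].copy()
        rev = ScreenDB(records=[r.copy() for r in reversed(conformer_db.records)])
        h1 = shape.shape_search(query, conformer_db, top_k=3, seed=11)
        h2 = shape.shape_search(query, rev, top_k=3, seed=11)
        assert [(h.record_id, h.combo) for h in h1] == [(h.record_id, h.combo) for h in h2]

    def test_database_without_conformers_fatal(self, library_db):
        with pytest.raises(VScreenError, match="conformer"):
            shape.shape_search(record_from_smiles("CCO"), library_db)
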