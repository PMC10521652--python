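"""Strand detection, barrel fits, shear measurement, superposition."""

import numpy as np
import pytest

from ovoidtim.structure_analysis import (
    BarrelError,
    assign_strands,
    fit_barrel_axis,
    fit_cross_section,
    measure_shear_from_structure,
    read_structure,
    repeat_symmetry_rmsd,
    small_residue_enrichment,
    superpose,
)
from ovoidtim.syntax import compute_shear, enumerate_cbeta_strips
from ovoidtim.synthetic_data import make_decoy, preset, preset_blueprint

from conftest import make_toy_model


def random_rotation(seed=0):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


class TestReadStructure:
    ALTLOC_PDB = (
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60 10.00           N\n"
        "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.40 10.00           N\n"
        "ATOM      3  CA AALA A   1       1.400   0.000   0.000  0.60 10.00           C\n"
        "ATOM      4  CA BALA A   1       9.400   0.000   0.000  0.40 10.00           C\n"
        "ATOM      5  C  AALA A   1       2.000   1.000   0.000  0.60 10.00           C\n"
        "ATOM      6  C  BALA A   1       9.000   1.000   0.000  0.40 10.00           C\n"
        "ATOM      7  O  AALA A   1       3.200   1.000   0.000  0.60 10.00           O\n"
        "ATOM      8  O  BALA A   1       9.200   1.000   0.000  0.40 10.00           O\n"
        "END\n"
    )

    INSCODE_PDB = (
        "ATOM      1  N   ALA A   1A      0.000   0.000   0.000  1.00 10.00           N\n"
        "ATOM      2  CA  ALA A   1A      1.400   0.000   0.000  1.00 10.00           C\n"
        "END\n"
    )

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(self.ALTLOC_PDB)
        model = read_structure(path)
        assert len(model) == 1
        assert np.allclose(model.residues[0].atoms["CA"], [1.4, 0.0, 0.0])

    def test_insertion_codes_rejected(self, tmp_path):
        path = tmp_path / "ins.pdb"
        path.write_text(self.INSCODE_PDB)
        with pytest.raises(ValueError, match="insertion"):
            read_structure(path)

    def test_missing_backbone_warns(self, tmp_path):
        path = tmp_path / "partial.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="backbone"):
            read_structure(path)


class TestAssignStrands:
    def test_ovoid_has_eight_strands(self, ovoid_strands, ovoid_bp):
        assert ovoid_strands.n_strands == 8
        assert ovoid_strands.closed
        # detected lengths no more than one residue short of the blueprint
        for (a, b), L in zip(ovoid_strands.strands, ovoid_bp.strand_lengths):
            assert b - a + 1 >= L - 1

    def test_helix_only_model_raises(self):
        # an isolated ideal helix has no beta ladder
        js = np.arange(30)
        ang = np.deg2rad(100.0) * js
        cas = np.column_stack(
            [2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * js]
        )
        from ovoidtim.model import BarrelModel, Residue

        residues = []
        for k, ca in enumerate(cas):
            atoms = {
                "CA": ca,
                "N": ca + np.array([-1.0, 0.4, -0.5]),
                "C": ca + np.array([1.0, 0.4, 0.5]),
                "O": ca + np.array([1.2, 1.5, 0.6]),
            }
            residues.append(Residue(index=k + 1, aa="ALA", atoms=atoms))
        with pytest.raises(BarrelError):
            assign_strands(BarrelModel(residues))

    def test_deleted_strand_gives_seven(self, ovoid_model):
        decoy = make_decoy(ovoid_model, "deleted_strand", strand=2)
        assert assign_strands(decoy).n_strands == 7

    def test_override_returned_verbatim(self, ovoid_model, ovoid_strands):
        assert assign_strands(ovoid_model, override=ovoid_strands) is ovoid_strands


class TestBarrelAxis:
    def test_generated_barrel_axis_is_z(self, ovoid_model, ovoid_strands):
        axis = fit_barrel_axis(ovoid_model, ovoid_strands)
        angle = np.degrees(np.arccos(abs(axis.direction[2])))
        assert angle < 2.0

    def test_axis_equivariance_under_rotation(self, ovoid_model, ovoid_strands):
        R = random_rotation(3)
        rotated = ovoid_model.transform(R, np.array([5.0, -3.0, 11.0]))
        axis0 = fit_barrel_axis(ovoid_model, ovoid_strands)
        axis1 = fit_barrel_axis(rotated, ovoid_strands)
        assert abs(np.dot(axis1.direction, R @ axis0.direction)) > 0.9999

    def test_axis_robust_to_noise(self, ovoid_model):
        angles = []
        for seed in range(5):
            noisy = make_decoy(ovoid_model, "noise", sigma=0.3, seed=seed)
            sa = assign_strands(noisy)
            axis = fit_barrel_axis(noisy, sa)
            angles.append(np.degrees(np.arccos(abs(axis.direction[2]))))
        assert np.median(angles) < 5.0


class TestCrossSection:
    def test_ovoid_axis_ratio_recovered(self, ovoid_shape):
        assert abs(ovoid_shape.semi_major_a / ovoid_shape.semi_minor_b - 13 / 9) < 0.1 * 13 / 9

    def test_long_strands_on_major_faces(self, ovoid_shape, ovoid_bp):
        lengths = ovoid_bp.strand_lengths
        for k, face in ovoid_shape.face_labels.items():
            assert face == ("major" if lengths[k] == 7 else "minor")

    def test_eccentricity_identity(self, ovoid_shape):
        e = np.sqrt(1 - (ovoid_shape.semi_minor_b / ovoid_shape.semi_major_a) ** 2)
        assert np.isclose(e, ovoid_shape.eccentricity)

    def test_fit_invariant_to_rigid_motion(self, ovoid_model, ovoid_strands, ovoid_shape):
        R = random_rotation(7)
        moved = ovoid_model.transform(R, np.array([-4.0, 9.0, 2.0]))
        shape2 = fit_cross_section(
            moved, ovoid_strands, fit_barrel_axis(moved, ovoid_strands)
        )
        assert np.isclose(shape2.eccentricity, ovoid_shape.eccentricity, atol=1e-3)
        assert np.isclose(shape2.semi_major_a, ovoid_shape.semi_major_a, atol=1e-2)
        for k in ovoid_shape.per_strand_radius:
            assert np.isclose(
                shape2.per_strand_radius[k], ovoid_shape.per_strand_radius[k], atol=1e-2
            )

    def test_ovoid_exceeds_circular(self, ovoid_shape, circular_model):
        sa = assign_strands(circular_model)
        circ = fit_cross_section(circular_model, sa, fit_barrel_axis(circular_model, sa))
        assert ovoid_shape.eccentricity > circ.eccentricity


class TestShearMeasurement:
    @pytest.mark.parametrize("name", ["ovoid", "circular", "zero_shear_toy", "porin_like"])
    def test_matches_blueprint_shear(self, name):
        bp, _ = preset_blueprint(name)
        model = preset(name)
        sa = assign_strands(model)
        assert measure_shear_from_structure(model, sa) == compute_shear(bp)

    def test_open_barrel_raises(self, ovoid_model):
        decoy = make_decoy(ovoid_model, "deleted_strand", strand=4)
        sa = assign_strands(decoy)
        if not sa.closed:
            with pytest.raises(BarrelError):
                measure_shear_from_structure(decoy, sa)


class TestSmallResidueEnrichment:
    def test_small_on_minor_face_is_negative(self, ovoid_bp, ovoid_model, ovoid_shape):
        strips = enumerate_cbeta_strips(ovoid_bp)
        report = small_residue_enrichment(
            ovoid_model, strips, ovoid_shape.face_labels, ovoid_bp.strand_ranges(), seed=0
        )
        assert report.volume_difference < 0
        assert report.mean_minor < report.mean_all

    def test_extreme_contrast_significant(self, ovoid_bp, ovoid_model, ovoid_shape):
        # permutation oracle: Ala at every minor-face position, Phe elsewhere
        contrived = ovoid_model.copy()
        strips = enumerate_cbeta_strips(ovoid_bp)
        ranges = ovoid_bp.strand_ranges()
        for strip in strips:
            for strand_idx, local in strip.positions:
                g = ranges[strand_idx][0] + local - 1
                r = contrived.residue(g)
                r.aa = "ALA" if ovoid_shape.face_labels[strand_idx] == "minor" else "PHE"
        report = small_residue_enrichment(
            contrived, strips, ovoid_shape.face_labels, ranges, seed=0
        )
        assert report.volume_difference < 0
        assert report.p_value < 0.01

    def test_homopolymer_difference_zero(self, ovoid_bp, ovoid_model, ovoid_shape):
        poly = ovoid_model.copy()
        for r in poly.residues:
            r.aa = "VAL"
        strips = enumerate_cbeta_strips(ovoid_bp)
        report = small_residue_enrichment(
            poly, strips, ovoid_shape.face_labels, ovoid_bp.strand_ranges(), seed=0
        )
        assert report.volume_difference == 0.0

    def test_no_minor_positions_raises(self, ovoid_bp, ovoid_model):
        strips = enumerate_cbeta_strips(ovoid_bp)
        faces = {k: "major" for k in range(8)}
        with pytest.raises(BarrelError):
            small_residue_enrichment(
                ovoid_model, strips, faces, ovoid_bp.strand_ranges()
            )


class TestSuperpose:
    def test_identity_rmsd_zero(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        assert superpose(X, X).rmsd < 1e-12

    def test_rigid_motion_invariance(self):
        X = np.random.default_rng(1).normal(size=(80, 3)) * 5
        R = random_rotation(2)
        Y = (R @ X.T).T + np.array([1.0, -2.0, 3.0])
        res = superpose(X, Y)
        assert res.rmsd < 1e-6
        assert np.isclose(np.linalg.det(res.rotation), 1.0)

    def test_noise_scaling_law(self):
        # RMSD of a noisy copy approaches sigma * sqrt(3) at large n
        rng = np.random.default_rng(42)
        X = rng.normal(size=(200, 3)) * 8
        sigma = 0.4
        rmsds = [
            superpose(X + rng.normal(0, sigma, X.shape), X).rmsd for _ in range(40)
        ]
        assert abs(np.mean(rmsds) - sigma * np.sqrt(3)) < 0.1 * sigma * np.sqrt(3)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRepeatSymmetry:
    def test_generated_twofold_under_0p1(self, ovoid_model):
        assert repeat_symmetry_rmsd(ovoid_model, 114) < 0.1

    def test_noisy_repeat_follows_noise_law(self, ovoid_model):
        rng = np.random.default_rng(11)
        sigma = 0.5
        vals = []
        for _ in range(10):
            noisy = ovoid_model.copy()
            for r in noisy.residues:
                if r.index > 114:
                    for k in r.atoms:
                        r.atoms[k] = r.atoms[k] + rng.normal(0, sigma, 3)
            vals.append(repeat_symmetry_rmsd(noisy, 114))
        assert abs(np.mean(vals) - sigma * np.sqrt(3)) < 0.15 * sigma * np.sqrt(3)

    def test_wrong_length_raises(self, ovoid_model):
        with pytest.raises(ValueError):
            repeat_symmetry_rmsd(ovoid_model, 100)
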