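"""Parametric barrel generation: closure, geometry, symmetry, search."""

import numpy as np
import pytest

from ovoidtim.backbone_gen import (
    BarrelParams,
    ClosureError,
    SearchState,
    autoregressive_search,
    generate_barrel,
    generate_full_timb,
    write_pdb,
)
from ovoidtim.structure_analysis import read_structure, superpose
from ovoidtim.syntax import Blueprint, SecondaryStructureElement, make_ovoid_blueprint


def shifted_blueprint(shifts):
    elems = []
    for k in range(len(shifts)):
        elems.append(SecondaryStructureElement("strand", 7, k + 1))
        elems.append(SecondaryStructureElement("loop", 7, k + 1))
    return Blueprint(tuple(elems), tuple(shifts))


class TestGenerateBarrel:
    def test_full_timb_has_228_residues(self, ovoid_model):
        assert len(ovoid_model) == 228
        assert [r.index for r in ovoid_model.residues] == list(range(1, 229))

    def test_chain_connectivity(self, ovoid_model):
        geom = ovoid_model.check_geometry()
        assert 3.6 <= geom["ca_ca_min"] and geom["ca_ca_max"] <= 4.1
        assert geom["cb_missing_non_gly"] == 0

    def test_cb_only_absent_for_gly(self, ovoid_model):
        for r in ovoid_model.residues:
            assert ("CB" in r.atoms) == (r.aa != "GLY")

    def test_strand_pairing_ladder_distances(self, ovoid_bp, ovoid_params):
        # adjacent-strand CA-CA ladder distances within [4.2, 5.4] for
        # >= 90% of paired positions
        model = generate_barrel(ovoid_bp, ovoid_params)
        ranges = ovoid_bp.strand_ranges()
        c = ovoid_bp.cumulative_shifts()
        lengths = ovoid_bp.strand_lengths
        n = ovoid_bp.n_strands
        dists = []
        for i in range(n):
            j = (i + 1) % n
            for local in range(1, lengths[i] + 1):
                m = local - c[i]
                partner_local = m + c[j] + (8 if j == 0 else 0)
                if 1 <= partner_local <= lengths[j]:
                    ca1 = model.residue(ranges[i][0] + local - 1).atoms["CA"]
                    ca2 = model.residue(ranges[j][0] + partner_local - 1).atoms["CA"]
                    dists.append(float(np.linalg.norm(ca1 - ca2)))
        dists = np.array(dists)
        assert len(dists) > 20
        assert np.mean((dists >= 4.2) & (dists <= 5.4)) >= 0.9

    def test_helices_outside_barrel_wall(self, ovoid_model):
        strand_r = [
            np.linalg.norm(r.atoms["CA"][:2])
            for r in ovoid_model.residues
            if r.element_label == "E"
        ]
        helix_centroids = []
        run = []
        for r in ovoid_model.residues:
            if r.element_label == "H":
                run.append(r.atoms["CA"])
            elif run:
                helix_centroids.append(np.mean(run, axis=0))
                run = []
        assert len(helix_centroids) == 8
        for cen in helix_centroids:
            assert np.linalg.norm(cen[:2]) > max(strand_r)

    def test_twofold_screw_symmetry_exact(self, ovoid_model):
        ca1 = ovoid_model.coords("CA", indices=range(1, 115))
        ca2 = ovoid_model.coords("CA", indices=range(115, 229))
        res = superpose(ca1, ca2)
        assert res.rmsd < 0.1
        # cross-check the optimal rotation with an independent solver
        from scipy.spatial.transform import Rotation

        rot, _ = Rotation.align_vectors(ca2 - ca2.mean(0), ca1 - ca1.mean(0))
        moved = rot.apply(ca1 - ca1.mean(0)) + ca2.mean(0)
        assert np.sqrt(np.mean(np.sum((moved - ca2) ** 2, axis=1))) < 0.1

    def test_circular_construction_is_round(self, circular_model):
        from ovoidtim.structure_analysis import (
            assign_strands,
            fit_barrel_axis,
            fit_cross_section,
        )

        sa = assign_strands(circular_model)
        shape = fit_cross_section(circular_model, sa, fit_barrel_axis(circular_model, sa))
        assert shape.eccentricity < 0.15

    def test_ovoid_eccentricity_matches_generating_ellipse(self, ovoid_shape):
        e_gen = np.sqrt(1 - (9.0 / 13.0) ** 2)
        assert abs(ovoid_shape.eccentricity - e_gen) < 0.05


class TestClosure:
    def test_even_shear_closes(self):
        generate_barrel(shifted_blueprint((1, 1, 1, 1, 1, 1, 1, 1)))

    @pytest.mark.parametrize("delta", [-1, 1])
    def test_single_shift_perturbation_fails(self, delta):
        shifts = [1] * 8
        shifts[3] += delta
        with pytest.raises(ClosureError):
            generate_barrel(shifted_blueprint(tuple(shifts)))

    def test_overlarge_shift_fails(self):
        # compensated but so large that two strands share no ladder rung
        shifts = (8, -8, 1, 1, 1, 1, 2, 2)
        with pytest.raises(ClosureError):
            generate_barrel(shifted_blueprint(shifts))


class TestWritePdb:
    def test_round_trip(self, tmp_path, ovoid_model):
        path = tmp_path / "model.pdb"
        write_pdb(ovoid_model, path)
        back = read_structure(path)
        assert len(back) == 228
        assert back.sequence == ovoid_model.sequence
        for r1, r2 in zip(ovoid_model.residues, back.residues):
            for name in r1.atoms:
                assert np.allclose(r1.atoms[name], r2.atoms[name], atol=1e-3)

    def test_gly_has_no_cb_on_disk(self, tmp_path, ovoid_model):
        path = tmp_path / "model.pdb"
        write_pdb(ovoid_model, path)
        back = read_structure(path)
        gly = [r for r in back.residues if r.aa == "GLY"]
        assert gly and all("CB" not in r.atoms for r in gly)


class TestAutoregressiveSearch:
    def test_unimodal_single_phase(self):
        st = SearchState(candidate_grid={"h": range(4, 12)})
        result, _ = autoregressive_search(st, lambda a: -abs(a["h"] - 7), ["h"])
        assert result["h"] == 7

    def test_two_phase_separable_equals_exhaustive(self):
        grid = {"x": [3, 4, 5], "y": [6, 7, 8]}

        def scorer(a):
            sc = 0.0
            if "x" in a:
                sc -= (a["x"] - 4.2) ** 2
            if "y" in a:
                sc -= (a["y"] - 7.8) ** 2
            return sc

        st = SearchState(candidate_grid=grid)
        result, _ = autoregressive_search(st, scorer, ["x", "y"])
        # brute-force 2-D argmax oracle
        best = max(
            ((x, y) for x in grid["x"] for y in grid["y"]),
            key=lambda p: scorer({"x": p[0], "y": p[1]}),
        )
        assert (result["x"], result["y"]) == best

    def test_single_phase_equals_exhaustive(self):
        grid = {"z": [2, 3, 5, 8, 13]}
        scorer = lambda a: np.sin(a["z"])
        st = SearchState(candidate_grid=grid)
        result, trace = autoregressive_search(st, scorer, ["z"])
        assert result["z"] == max(grid["z"], key=np.sin)
        assert len(trace) == len(grid["z"])

    def test_tie_breaks_to_smallest_with_warning(self):
        st = SearchState(candidate_grid={"h": [5, 6, 7]})
        with pytest.warns(UserWarning, match="tie"):
            result, _ = autoregressive_search(st, lambda a: 0.0, ["h"])
        assert result["h"] == 5

    def test_empty_grid_raises(self):
        st = SearchState(candidate_grid={})
        with pytest.raises(ValueError):
            autoregressive_search(st, lambda a: 0.0, ["h"])

    def test_builder_returns_blueprint(self):
        st = SearchState(candidate_grid={"helix": [12, 14, 16]})

        # builder closing the 114-residue budget around the chosen helix
        def budget_builder(assignment):
            h = assignment["helix"]
            leftover = 114 - 24 - 12 - 4 * h
            base = leftover // 4
            extra = leftover - 4 * base
            loops = tuple(base + (1 if i < extra else 0) for i in range(4))
            return make_ovoid_blueprint(helix_lengths=(h,) * 4, ba_loop_lengths=loops)

        result, _ = autoregressive_search(
            st, lambda a: -abs(a["helix"] - 14), ["helix"], builder=budget_builder
        )
        assert isinstance(result, Blueprint)
        assert result.total_residues == 228
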