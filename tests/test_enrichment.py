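"""Iterative-enrichment design loop: classification, sampling, profiling."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from ovoidtim.enrichment_design import (
    AMINO_ACIDS,
    PositionClass,
    classify_positions,
    iterate_enrichment,
    make_toy_contact_energy,
    null_energy,
    profile_and_restrict,
    run_trajectories,
)

from conftest import make_toy_model


def all_hydrophobic(model):
    return PositionClass(labels=["hydrophobic"] * len(model))


class TestClassifyPositions:
    def test_extended_isolated_chain_fully_exposed(self):
        model = make_toy_model("VVVVVV", spacing=6.0)
        classes = classify_positions(model)
        assert all(lab == "solvent-exposed" for lab in classes.labels)

    def test_core_facing_strand_positions_hydrophobic(self, ovoid_model):
        classes = classify_positions(ovoid_model)
        for k, r in enumerate(ovoid_model.residues):
            if r.facing == "core":
                assert classes.labels[k] == "hydrophobic"

    def test_override_returned_exactly(self, ovoid_model):
        override = ["boundary"] * len(ovoid_model)
        classes = classify_positions(ovoid_model, override=override)
        assert classes.labels == override

    def test_flipped_strand_flags_mismatch(self, ovoid_model):
        # facing flags are the oracle: after flipping strand 3's parity the
        # automatic classification disagrees with the stored flags there
        from ovoidtim.synthetic_data import make_decoy

        decoy = make_decoy(ovoid_model, "flipped_strand", strand=2)
        classes = classify_positions(decoy)
        mismatches = [
            k
            for k, r in enumerate(decoy.residues)
            if r.facing == "core" and classes.labels[k] != "hydrophobic"
        ]
        strand3 = [k for k, r in enumerate(decoy.residues) if 57 <= r.index <= 63]
        assert any(k in strand3 for k in mismatches)


class TestRunTrajectories:
    def test_null_energy_uniform_over_alphabet(self):
        model = make_toy_model("AAAA")
        classes = all_hydrophobic(model)
        seqs = run_trajectories(model, classes, null_energy, n_traj=1000, seed=0)
        # chi-square uniformity per position over the full alphabet
        for pos in range(4):
            counts = [sum(1 for s in seqs if s[pos] == aa) for aa in AMINO_ACIDS]
            assert chisquare(counts).pvalue > 1e-3

    def test_strong_preference_dominates(self):
        model = make_toy_model("AAAA")
        classes = all_hydrophobic(model)

        def favour_ala_at_2(seq):
            return 0.0 if seq[2] == "A" else 8.0

        seqs = run_trajectories(model, classes, favour_ala_at_2, n_traj=100, seed=1)
        frac = sum(1 for s in seqs if s[2] == "A") / len(seqs)
        # Boltzmann oracle at T=1: pi(A) = 1 / (1 + 19 exp(-8))
        assert frac >= 0.95
        assert frac >= 1.0 / (1.0 + 19 * np.exp(-8)) - 0.05

    def test_same_seed_reproduces(self):
        model = make_toy_model("AAAA")
        classes = all_hydrophobic(model)
        a = run_trajectories(model, classes, null_energy, n_traj=20, seed=3)
        b = run_trajectories(model, classes, null_energy, n_traj=20, seed=3)
        assert a == b

    def test_fixed_positions_keep_base(self):
        model = make_toy_model("AWAA")
        labels = ["hydrophobic", "solvent-exposed", "hydrophobic", "hydrophobic"]
        seqs = run_trajectories(
            model,
            PositionClass(labels=labels),
            null_energy,
            n_traj=10,
            seed=0,
            designable_classes=("hydrophobic",),
        )
        assert all(s[1] == "W" for s in seqs)

    def test_energy_failure_names_trajectory(self):
        model = make_toy_model("AAAA")

        def broken(seq):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="trajectory 0"):
            run_trajectories(model, all_hydrophobic(model), broken, n_traj=2, seed=0)


class TestProfileAndRestrict:
    def test_identical_sequences_collapse(self):
        profile = profile_and_restrict(["AW", "AW", "AW"])
        assert profile.allowed == [{"A"}, {"W"}]

    def test_min_frequency_zero_keeps_observed(self):
        profile = profile_and_restrict(["A", "A", "A", "V", "V", "A", "A", "V", "A", "A"])
        assert profile.allowed[0] == {"A", "V"}
        assert np.isclose(profile.frequencies[0][AMINO_ACIDS.index("A")], 0.7)
        assert np.isclose(profile.frequencies[0][AMINO_ACIDS.index("V")], 0.3)

    def test_hand_counted_toy_set(self):
        seqs = ["AVL", "AVL", "GVL", "AIL", "AVM"]
        profile = profile_and_restrict(seqs)
        assert np.isclose(profile.frequencies[0][AMINO_ACIDS.index("A")], 4 / 5)
        assert np.isclose(profile.frequencies[1][AMINO_ACIDS.index("V")], 4 / 5)
        assert np.isclose(profile.frequencies[2][AMINO_ACIDS.index("L")], 4 / 5)
        assert profile.allowed[0] == {"A", "G"}

    def test_alphabets_never_grow(self):
        first = profile_and_restrict(["AA", "AV"])
        second = profile_and_restrict(["AW", "AL"], current=first)
        assert second.allowed[1] <= first.allowed[1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            profile_and_restrict([])


class TestIterateEnrichment:
    def test_dominant_residue_converges_fast(self):
        model = make_toy_model("AA")

        def prefer_trp_at_0(seq):
            return 0.0 if seq[0] == "W" else 10.0

        profile, seqs, log = iterate_enrichment(
            model,
            all_hydrophobic(model),
            prefer_trp_at_0,
            schedule=[{"classes": ("hydrophobic",), "rounds": 3}],
            n_traj=50,
            seed=0,
            min_frequency=0.05,
        )
        assert profile.allowed[0] == {"W"}
        assert len(log) <= 3

    def test_two_position_potts_matches_enumeration(self):
        # exhaustive Boltzmann enumeration over all 400 pairs is the oracle
        model = make_toy_model("AA")
        rng = np.random.default_rng(12)
        fields = [
            {a: float(rng.normal(scale=1.5)) for a in AMINO_ACIDS} for _ in range(2)
        ]
        table = {
            (a, b): fields[0][a] + fields[1][b] + float(rng.normal(scale=0.3))
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
        }

        def potts(seq):
            return table[(seq[0], seq[1])]

        weights = {
            pair: np.exp(-e) for pair, e in table.items()
        }
        z = sum(weights.values())
        marg0 = {a: sum(w for (x, _), w in weights.items() if x == a) / z for a in AMINO_ACIDS}
        marg1 = {b: sum(w for (_, y), w in weights.items() if y == b) / z for b in AMINO_ACIDS}

        profile, _, _ = iterate_enrichment(
            model,
            all_hydrophobic(model),
            potts,
            schedule=[{"classes": ("hydrophobic",), "rounds": 2}],
            n_traj=400,
            seed=5,
        )
        top0 = AMINO_ACIDS[int(profile.frequencies[0].argmax())]
        top1 = AMINO_ACIDS[int(profile.frequencies[1].argmax())]
        # the converged profile's dominant residues are among the
        # enumeration's top choices
        best0 = sorted(marg0, key=marg0.get, reverse=True)[:3]
        best1 = sorted(marg1, key=marg1.get, reverse=True)[:3]
        assert top0 in best0
        assert top1 in best1

    def test_alphabet_sizes_monotone_every_round(self):
        model = make_toy_model("AAAA")
        profile, _, log = iterate_enrichment(
            model,
            all_hydrophobic(model),
            null_energy,
            schedule=[{"classes": ("hydrophobic",), "rounds": 4}],
            n_traj=30,
            seed=2,
            entropy_tolerance=0.0,
        )
        sizes = [entry["alphabet_sizes"] for entry in log]
        for before, after in zip(sizes, sizes[1:]):
            assert all(b >= a for b, a in zip(before, after))

    def test_phase_without_positions_rejected(self):
        model = make_toy_model("AA")
        with pytest.raises(ValueError):
            iterate_enrichment(
                model,
                all_hydrophobic(model),
                null_energy,
                schedule=[{"classes": ("solvent-exposed",)}],
            )

    def test_curation_hook_filters(self):
        model = make_toy_model("AA")
        profile, seqs, _ = iterate_enrichment(
            model,
            all_hydrophobic(model),
            null_energy,
            schedule=[{"classes": ("hydrophobic",), "rounds": 1}],
            n_traj=50,
            seed=4,
            curation=lambda s: "W" not in s,
        )
        assert all("W" not in s for s in seqs)


class TestToyContactEnergy:
    def test_prefers_hydrophobic_core(self, ovoid_model):
        energy = make_toy_contact_energy(ovoid_model)
        base = ovoid_model.sequence
        core_positions = [
            k for k, r in enumerate(ovoid_model.residues) if r.facing == "core"
        ]
        k = core_positions[0]
        polar = base[:k] + "E" + base[k + 1 :]
        assert energy(base) < energy(polar)

    def test_penalizes_oversized_core(self, ovoid_model):
        energy = make_toy_contact_energy(ovoid_model)
        base = ovoid_model.sequence
        k = next(k for k, r in enumerate(ovoid_model.residues) if r.one_letter == "A" and r.facing == "core")
        bulky = base[:k] + "W" + base[k + 1 :]
        assert energy(bulky) > energy(base)
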