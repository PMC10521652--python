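"""Iterative-enrichment fixed-backbone sequence design with a pluggable energy.

The design loop repeats three steps: (1) run many independent seeded
Monte-Carlo sequence-optimization trajectories against an energy function
(a toy contact/volume energy here — the loop's logic, not the physics, is
the point); (2) compute the per-position amino-acid frequency profile
over trajectory endpoints; (3) restrict each position's allowed alphabet
to the residues represented in the profile.  Alphabets never grow, so the
design space shrinks monotonically; the loop stops when the mean
per-position Shannon entropy stops changing or a round limit is reached.
Positions are classified hydrophobic / boundary / solvent-exposed from
burial and facing geometry; core positions are designed first with polar
positions held constant, then the exposed positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

import biotite.structure as struc

from ovoidtim.model import BarrelModel
from ovoidtim.volumes import HYDROPATHY, RESIDUE_VOLUMES

__all__ = [
    "AMINO_ACIDS",
    "PositionClass",
    "DesignProfile",
    "classify_positions",
    "run_trajectories",
    "profile_and_restrict",
    "iterate_enrichment",
    "null_energy",
    "make_toy_contact_energy",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Tien et al. theoretical maximum accessible surface areas (Å^2)
_MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass
class PositionClass:
    """Per-position design class labels."""

    labels: list[str]  # each in {'hydrophobic', 'boundary', 'solvent-exposed'}

    def positions(self, *classes: str) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab in classes]


@dataclass
class DesignProfile:
    """Per-position amino-acid frequencies and allowed alphabets."""

    frequencies: np.ndarray  # (L, 20), rows sum to 1
    allowed: list[set[str]]
    round_index: int = 0

    @property
    def length(self) -> int:
        return len(self.allowed)

    def entropy(self) -> np.ndarray:
        f = np.clip(self.frequencies, 1e-12, 1.0)
        return -(self.frequencies * np.log(f)).sum(axis=1)

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[k] for k in self.frequencies.argmax(axis=1))

    def to_table(self) -> str:
        header = "position\t" + "\t".join(AMINO_ACIDS)
        lines = [header]
        for i, row in enumerate(self.frequencies, start=1):
            lines.append(f"{i}\t" + "\t".join(f"{v:.4f}" for v in row))
        return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
def classify_positions(
    model: BarrelModel,
    buried_threshold: float = 0.25,
    exposed_threshold: float = 0.55,
    override: Sequence[str] | None = None,
) -> PositionClass:
    """Classify positions as hydrophobic / boundary / solvent-exposed.

    An automatic surrogate for manual inspection: relative side-chain
    solvent exposure below ``buried_threshold`` (or a core-facing strand
    position) maps to hydrophobic, above ``exposed_threshold`` to
    solvent-exposed, anything in between to boundary.  A user-supplied
    override is returned verbatim.
    """
    if override is not None:
        labels = list(override)
        if len(labels) != len(model):
            raise ValueError("override length mismatch")
        return PositionClass(labels=labels)
    # barrel geometry, if the model has one: strand residues whose CB
    # points at the axis are core positions regardless of residual SASA
    axis = None
    strand_label: dict[int, bool] = {}
    try:
        from ovoidtim.structure_analysis import assign_strands, fit_barrel_axis

        sa = assign_strands(model)
        axis = fit_barrel_axis(model, sa)
        strand_label = {i: True for i in sa.labels}
    except Exception:
        pass
    arr = model.to_atom_array()
    sasa = struc.sasa(arr, probe_radius=1.4, point_number=200, vdw_radii="Single")
    labels = []
    for r in model.residues:
        side_names = [a for a in r.atoms if a not in ("N", "CA", "C", "O")] or ["CA"]
        res_mask = arr.res_id == r.index
        side_mask = res_mask & np.isin(arr.atom_name, side_names)
        exposed = float(np.nansum(sasa[side_mask]))
        # exposure relative to the same side chain on the isolated residue
        alone = arr[res_mask]
        ref_sasa = struc.sasa(
            alone, probe_radius=1.4, point_number=200, vdw_radii="Single"
        )
        reference = float(np.nansum(ref_sasa[np.isin(alone.atom_name, side_names)]))
        rel = exposed / reference if reference > 0 else 0.0
        inward = None
        if axis is not None and strand_label.get(r.index) and "CB" in r.atoms:
            radial = r.atoms["CA"] - axis.centroid
            radial = radial - np.dot(radial, axis.direction) * axis.direction
            norm = np.linalg.norm(radial)
            if norm > 1e-6:
                inward = float(np.dot(r.atoms["CB"] - r.atoms["CA"], radial / norm)) < 0
        if inward:
            labels.append("hydrophobic")
        elif rel < buried_threshold and inward is None:
            labels.append("hydrophobic")
        elif rel > exposed_threshold:
            labels.append("solvent-exposed")
        else:
            labels.append("boundary")
    return PositionClass(labels=labels)


# ----------------------------------------------------------------------
def null_energy(sequence: str, model: BarrelModel | None = None) -> float:
    """Flat landscape: every sequence is equally good."""
    return 0.0


def make_toy_contact_energy(
    model: BarrelModel,
    contact_cutoff: float = 8.0,
    volume_slack: float = 30.0,
    clash_weight: float = 0.01,
    hydrophobic_weight: float = 1.0,
) -> Callable[[str], float]:
    """Toy contact/volume energy for sequence design on a fixed backbone.

    Contacting position pairs (CB within ``contact_cutoff``) are rewarded
    for hydrophobic complementarity (product of hydropathies when
    positive); every position pays a quadratic penalty for exceeding its
    cavity budget, taken as the generating model's residue volume plus
    ``volume_slack``.
    """
    cb = []
    for r in model.residues:
        cb.append(r.atoms.get("CB", r.atoms["CA"]))
    cb = np.array(cb)
    from scipy.spatial import cKDTree

    pairs = sorted(cKDTree(cb).query_pairs(contact_cutoff))
    budgets = np.array(
        [RESIDUE_VOLUMES[r.one_letter] + volume_slack for r in model.residues]
    )
    buried = np.array([r.facing == "core" for r in model.residues])

    def energy(sequence: str) -> float:
        h = np.array([HYDROPATHY[a] for a in sequence])
        v = np.array([RESIDUE_VOLUMES[a] for a in sequence])
        e = 0.0
        for i, j in pairs:
            if h[i] > 0 and h[j] > 0:
                e -= hydrophobic_weight * h[i] * h[j] / 20.25  # normalized to max 1
        over = np.clip(v - budgets, 0.0, None)
        e += clash_weight * float((over**2).sum())
        # polar residues buried in the core are penalized
        e += 0.5 * float(np.sum(np.clip(-h[buried], 0.0, None)))
        return e

    return energy


# ----------------------------------------------------------------------
def run_trajectories(
    model: BarrelModel,
    classes: PositionClass,
    energy: Callable[[str], float],
    n_traj: int = 100,
    seed: int = 0,
    designable_classes: Iterable[str] = ("hydrophobic", "boundary", "solvent-exposed"),
    allowed: Sequence[set[str]] | None = None,
    base_sequence: str | None = None,
    steps_per_position: int = 100,
    temperature: float = 1.0,
) -> list[str]:
    """Independent seeded Monte-Carlo sequence optimizations.

    Each trajectory starts from a random sequence over the allowed
    alphabets (fixed positions keep the base sequence), proposes
    single-position substitutions and accepts by the Metropolis rule at
    fixed temperature, and returns its final sequence.  The same seed
    reproduces the same sequence set; trajectories use independent
    spawned substreams.
    """
    L = len(model)
    base = base_sequence or model.sequence
    if len(base) != L:
        raise ValueError("base sequence length mismatch")
    allowed = [set(a) for a in allowed] if allowed is not None else [
        set(AMINO_ACIDS) for _ in range(L)
    ]
    design_pos = [i for i in classes.positions(*designable_classes) if len(allowed[i]) > 1]
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_traj)
    finals = []
    n_steps = steps_per_position * max(1, len(design_pos))
    for ti, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        seq = list(base)
        for i in design_pos:
            seq[i] = sorted(allowed[i])[rng.integers(len(allowed[i]))]
        try:
            e_cur = float(energy("".join(seq)))
            if not design_pos:
                finals.append("".join(seq))
                continue
            pos_choices = rng.integers(0, len(design_pos), size=n_steps)
            accept_u = rng.random(size=n_steps)
            for step in range(n_steps):
                i = design_pos[pos_choices[step]]
                options = sorted(allowed[i] - {seq[i]})
                if not options:
                    continue
                old = seq[i]
                seq[i] = options[rng.integers(len(options))]
                e_new = float(energy("".join(seq)))
                if e_new <= e_cur or accept_u[step] < np.exp(
                    -(e_new - e_cur) / temperature
                ):
                    e_cur = e_new
                else:
                    seq[i] = old
        except Exception as err:
            raise RuntimeError(f"energy failed in trajectory {ti}") from err
        finals.append("".join(seq))
    return finals


def profile_and_restrict(
    sequences: Sequence[str],
    current: DesignProfile | None = None,
    min_frequency: float = 0.0,
) -> DesignProfile:
    """Frequency profile over sequences; restrict alphabets to observed residues.

    The new allowed alphabet at each position keeps residues whose
    frequency is at least ``min_frequency`` (default: observed at least
    once); intersected with the current alphabet, so alphabets never grow.
    """
    if not sequences:
        raise ValueError("no sequences to profile")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences differ in length")
    counts = np.zeros((L, len(AMINO_ACIDS)))
    for s in sequences:
        for i, a in enumerate(s):
            counts[i, _AA_INDEX[a]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    allowed = []
    for i in range(L):
        keep = {
            AMINO_ACIDS[k]
            for k in range(len(AMINO_ACIDS))
            if freqs[i, k] > 0 and freqs[i, k] >= min_frequency
        }
        if current is not None:
            keep &= current.allowed[i]
            if not keep:  # observations outside the alphabet: no restriction
                keep = set(current.allowed[i])
        allowed.append(keep)
    return DesignProfile(
        frequencies=freqs,
        allowed=allowed,
        round_index=(current.round_index + 1) if current is not None else 1,
    )


def iterate_enrichment(
    model: BarrelModel,
    classes: PositionClass,
    energy: Callable[[str], float],
    schedule: Sequence[Mapping] | None = None,
    n_traj: int = 100,
    seed: int = 0,
    max_rounds: int = 5,
    entropy_tolerance: float = 0.01,
    min_frequency: float = 0.0,
    curation: Callable[[str], bool] | None = None,
) -> tuple[DesignProfile, list[str], list[dict]]:
    """Run the full iterative-enrichment loop.

    The default schedule designs hydrophobic+boundary positions first
    (solvent-exposed held constant), then the solvent-exposed positions.
    Each phase repeats sample -> profile -> restrict until the mean
    per-position entropy changes by less than ``entropy_tolerance`` nats
    or ``max_rounds`` is reached.  An optional curation predicate filters
    pathological sequences before profiling.  Returns the final profile,
    the last round's sequences, and an audit log of alphabet sizes and
    entropies per round.
    """
    if schedule is None:
        schedule = [
            {"classes": ("hydrophobic", "boundary")},
            {"classes": ("solvent-exposed",)},
        ]
    for phase in schedule:
        if not classes.positions(*phase["classes"]):
            raise ValueError(f"phase {phase} has no designable positions")
    profile: DesignProfile | None = None
    allowed = [set(AMINO_ACIDS) for _ in range(len(model))]
    base = model.sequence
    log: list[dict] = []
    sequences: list[str] = []
    round_seed = seed
    for phase_idx, phase in enumerate(schedule):
        prev_entropy = None
        rounds = int(phase.get("rounds", max_rounds))
        for rnd in range(rounds):
            sequences = run_trajectories(
                model,
                classes,
                energy,
                n_traj=int(phase.get("n_traj", n_traj)),
                seed=round_seed,
                designable_classes=phase["classes"],
                allowed=allowed,
                base_sequence=base,
            )
            round_seed += 1
            if curation is not None:
                kept = [s for s in sequences if curation(s)]
                sequences = kept or sequences
            profile = profile_and_restrict(sequences, profile, min_frequency)
            # restriction applies only to the positions designed this phase;
            # positions held constant keep their previous alphabet
            phase_pos = set(classes.positions(*phase["classes"]))
            for i in range(len(allowed)):
                if i not in phase_pos:
                    profile.allowed[i] = set(allowed[i])
            allowed = [set(a) for a in profile.allowed]
            ent = float(profile.entropy().mean())
            log.append(
                {
                    "phase": phase_idx,
                    "round": rnd,
                    "mean_entropy": ent,
                    "alphabet_sizes": [len(a) for a in profile.allowed],
                }
            )
            if prev_entropy is not None and abs(ent - prev_entropy) < entropy_tolerance:
                break
            prev_entropy = ent
        base = profile.consensus()
    assert profile is not None
    return profile, sequences, log
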