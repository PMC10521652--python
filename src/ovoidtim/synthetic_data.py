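"""Deterministic fixtures: preset barrels, decoys, variants, curve panels.

Everything every other module needs for testing is generated here from
first principles: idealized circular/ovoid TIM barrels with designed
ILV cores (and idealized side-chain pseudo-atoms so contact analysis has
heavy atoms to work with), decoy structures (coordinate noise, flipped
or deleted strands), the polar-variant (PV) and hollow-variant (HV)
mutation sets with automatic repeat-partner application, and panels of
simulated chemical-denaturation curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ovoidtim.backbone_gen import BarrelParams, generate_barrel, generate_full_timb
from ovoidtim.model import BarrelModel, Residue, aa1to3
from ovoidtim.stability import DenaturationCurve, simulate_curve
from ovoidtim.syntax import (
    Blueprint,
    SecondaryStructureElement,
    enumerate_layers,
    make_circular_blueprint,
    make_ovoid_blueprint,
    repeat_partner,
)

__all__ = [
    "MutationSet",
    "preset",
    "preset_blueprint",
    "make_decoy",
    "apply_variant",
    "make_curve_panel",
    "add_ilv_sidechains",
    "PV_VARIANTS",
    "HV_VARIANTS",
]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class MutationSet:
    """Point mutations as (1-based position, from, to) one-letter entries."""

    entries: list[tuple[int, str, str]] = field(default_factory=list)
    symmetric: bool = False

    def positions(self) -> list[int]:
        return [p for p, _, _ in self.entries]


# Polar variants: buried charged/polar substitutions of the ovoid design
PV_VARIANTS: dict[str, list[tuple[int, str, str]]] = {
    "PV1": [(60, "I", "K"), (174, "I", "A")],
    "PV2": [(174, "I", "E")],
    "PV3": [(60, "I", "K"), (174, "I", "E")],
    "PV4": [(4, "C", "S")],
    "PV5": [(93, "A", "K"), (148, "L", "A")],
}

# Hollow variants: layer sets ablated to alanine (top = high along the
# barrel axis).  The residue membership comes from the blueprint's layer
# enumeration; explicit position lists may be supplied instead.
HV_VARIANTS: dict[str, dict] = {
    "HV1": {"layers": "top", "count": 4},
    "HV2": {"layers": "top", "count": 5},
    "HV3": {"layers": "bottom", "count": 2},
    "HV4": {"layers": "top", "count": 3},
    "HV5": {"layers": "top", "count": 2},
    "HV6": {"layers": "top", "count": 1},
    "HV7": {"layers": "top", "count": 1, "long_strands_only": True},
}


# ----------------------------------------------------------------------
def _single_wall_blueprint(
    strand_length: int, loop_length: int, shift: int, n_strands: int = 8
) -> Blueprint:
    elements = []
    for k in range(n_strands):
        elements.append(SecondaryStructureElement("strand", strand_length, k + 1))
        elements.append(SecondaryStructureElement("loop", loop_length, k + 1))
    return Blueprint(
        elements=tuple(elements),
        register_shifts=(shift,) * n_strands,
        repeat_count=n_strands,
    )


def preset_blueprint(name: str) -> tuple[Blueprint, BarrelParams]:
    """Blueprint and geometric parameters behind each preset model."""
    if name == "ovoid":
        return make_ovoid_blueprint(), BarrelParams(semi_major_a=13.0, semi_minor_b=9.0)
    if name == "circular":
        return make_circular_blueprint(), BarrelParams(semi_major_a=10.0, semi_minor_b=10.0)
    if name == "zero_shear_toy":
        return (
            _single_wall_blueprint(6, 7, 0),
            BarrelParams(semi_major_a=10.0, semi_minor_b=10.0),
        )
    if name == "porin_like":
        return (
            _single_wall_blueprint(8, 7, 1),
            BarrelParams(semi_major_a=13.0, semi_minor_b=9.0),
        )
    raise ValueError(f"unknown preset {name!r}")


def _ovoid_sequence(bp: Blueprint) -> str:
    """Designed sequence of the ovoid preset (exactly twofold symmetric).

    Core-facing positions of the long (major-face) strands carry Ile/Leu/
    Val; short (minor-face) strand cores carry small residues; strand
    exteriors are Thr; helices cycle Leu/Ala/Glu/Lys; loops are
    Gly/Ser-rich.  A few positions are pinned so the named polar-variant
    sites carry their canonical residues (C4, L34/148, I60/174, A93/207).
    """
    seq = ["A"] * bp.total_residues
    for e, a, b in bp.element_ranges():
        if e.kind == "helix":
            pat = "LAEK"
            for k, g in enumerate(range(a, b + 1)):
                seq[g - 1] = pat[k % 4]
        elif e.kind == "loop":
            pat = "GSNG"
            for k, g in enumerate(range(a, b + 1)):
                seq[g - 1] = pat[k % 4]
    lengths = bp.strand_lengths
    ilv = "ILV"
    counter = 0
    for i, (a, b) in enumerate(bp.strand_ranges()):
        long_strand = lengths[i] >= 7
        for local, g in enumerate(range(a, b + 1), start=1):
            if bp.is_core_facing(i, local):
                if long_strand:
                    seq[g - 1] = ilv[counter % 3]
                    counter += 1
                else:
                    seq[g - 1] = "AVA"[local % 3]
            else:
                seq[g - 1] = "T"
    for g, aa in ((4, "C"), (34, "L"), (60, "I"), (93, "A")):
        seq[g - 1] = aa
    rpp = bp.residues_per_repeat
    for g in range(rpp):  # enforce exact twofold sequence symmetry
        seq[g + rpp] = seq[g]
    return "".join(seq)


def _generic_sequence(bp: Blueprint) -> str:
    seq = []
    for e, a, b in bp.element_ranges():
        for g in range(a, b + 1):
            seq.append({"strand": "V", "helix": "L", "loop": "G"}[e.kind])
    strands = bp.strand_ranges()
    out = list("".join(seq))
    for i, (a, b) in enumerate(strands):
        for local, g in enumerate(range(a, b + 1), start=1):
            out[g - 1] = "I" if bp.is_core_facing(i, local) else "T"
    return "".join(out)


def add_ilv_sidechains(model: BarrelModel) -> BarrelModel:
    """Attach idealized side-chain pseudo-atoms to Ile/Leu/Val residues.

    Branch atoms extend from CB along the CB direction with tetrahedral-
    like splay; purely geometric stand-ins so that contact and buried-
    area analysis has heavy atoms to work with.
    """
    for r in model.residues:
        if r.aa not in ("ILE", "LEU", "VAL") or "CB" not in r.atoms:
            continue
        d1 = r.atoms["CB"] - r.atoms["CA"]
        d1 = d1 / np.linalg.norm(d1)
        p = np.cross(d1, _Z)
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(d1, np.array([1.0, 0.0, 0.0]))
        p /= np.linalg.norm(p)
        split_a = (d1 + 0.8 * p) / np.linalg.norm(d1 + 0.8 * p)
        split_b = (d1 - 0.8 * p) / np.linalg.norm(d1 - 0.8 * p)
        cb = r.atoms["CB"]
        if r.aa == "VAL":
            r.atoms["CG1"] = cb + 1.53 * split_a
            r.atoms["CG2"] = cb + 1.53 * split_b
        elif r.aa == "ILE":
            r.atoms["CG1"] = cb + 1.53 * split_a
            r.atoms["CG2"] = cb + 1.53 * split_b
            r.atoms["CD1"] = r.atoms["CG1"] + 1.53 * d1
        else:  # LEU
            r.atoms["CG"] = cb + 1.53 * d1
            r.atoms["CD1"] = r.atoms["CG"] + 1.53 * split_a
            r.atoms["CD2"] = r.atoms["CG"] + 1.53 * split_b
    return model


def preset(name: str) -> BarrelModel:
    """Deterministic generated model for one of the named presets.

    ``ovoid`` and ``circular`` are full TIM barrels; ``zero_shear_toy``
    and ``porin_like`` are single-wall barrels.
    """
    bp, params = preset_blueprint(name)
    if name == "ovoid":
        model = generate_full_timb(bp, params, sequence=_ovoid_sequence(bp))
    elif name == "circular":
        model = generate_full_timb(bp, params, sequence=_generic_sequence(bp))
    elif name == "zero_shear_toy":
        model = generate_barrel(bp, params, sequence=_generic_sequence(bp))
    else:  # porin_like: wall only, crossover loops omitted
        model = generate_barrel(
            bp, params, sequence=_generic_sequence(bp), include_loops=False
        )
    return add_ilv_sidechains(model)


# ----------------------------------------------------------------------
def _strand_runs(model: BarrelModel) -> list[list[Residue]]:
    runs, cur = [], []
    for r in model.residues:
        if r.element_label == "E":
            if cur and r.index != cur[-1].index + 1:
                runs.append(cur)
                cur = []
            cur.append(r)
        else:
            if cur:
                runs.append(cur)
                cur = []
    if cur:
        runs.append(cur)
    return runs


def _strip_sidechain(r: Residue) -> None:
    for name in [a for a in r.atoms if a not in ("N", "CA", "C", "O", "CB")]:
        del r.atoms[name]


def _mutate_residue(model: BarrelModel, r: Residue, to_aa1: str) -> None:
    r.aa = aa1to3(to_aa1)
    _strip_sidechain(r)
    if r.aa == "GLY":
        r.atoms.pop("CB", None)
    elif "CB" not in r.atoms:
        ca_xy = np.array([r.atoms["CA"][0], r.atoms["CA"][1], 0.0])
        n = np.linalg.norm(ca_xy)
        d = ca_xy / n if n > 1e-6 else np.array([1.0, 0.0, 0.0])
        r.atoms["CB"] = r.atoms["CA"] + 1.53 * d
    if r.aa in ("ILE", "LEU", "VAL"):
        tmp = BarrelModel([r])
        add_ilv_sidechains(tmp)


def make_decoy(
    model: BarrelModel,
    kind: str,
    sigma: float = 0.5,
    strand: int = 0,
    seed: int = 0,
) -> BarrelModel:
    """Decoy structures: ``noise``, ``flipped_strand`` or ``deleted_strand``.

    * ``noise``: i.i.d. Gaussian displacement (sd ``sigma``) per coordinate.
    * ``flipped_strand``: facing parity of strand ``strand`` (0-based, in
      chain order) inverted — sequence swapped between in/out positions
      and facing flags flipped; backbone coordinates untouched.
    * ``deleted_strand``: residues of strand ``strand`` removed.
    """
    out = model.copy()
    if kind == "noise":
        rng = np.random.default_rng(seed)
        for r in out.residues:
            for k in r.atoms:
                r.atoms[k] = r.atoms[k] + rng.normal(0.0, sigma, size=3)
        return out
    runs = _strand_runs(out)
    if not 0 <= strand < len(runs):
        raise IndexError(f"strand index {strand} out of range (have {len(runs)})")
    if kind == "flipped_strand":
        run = runs[strand]
        for k in range(0, len(run) - 1, 2):
            a, b = run[k], run[k + 1]
            aa_a, aa_b = a.one_letter, b.one_letter
            _mutate_residue(out, a, aa_b)
            _mutate_residue(out, b, aa_a)
        for r in run:
            if r.facing is not None:
                r.facing = "exterior" if r.facing == "core" else "core"
        return out
    if kind == "deleted_strand":
        dead = {r.index for r in runs[strand]}
        out.residues = [r for r in out.residues if r.index not in dead]
        return out
    raise ValueError(f"unknown decoy kind {kind!r}")


# ----------------------------------------------------------------------
def _hv_mutation_set(model: BarrelModel, bp: Blueprint, rule: dict) -> MutationSet:
    layers = enumerate_layers(bp)
    layers = sorted(layers, key=lambda l: l.height_index, reverse=rule["layers"] == "top")
    chosen = layers[: rule["count"]]
    strand_ranges = bp.strand_ranges()
    lengths = bp.strand_lengths
    rpp = bp.residues_per_repeat
    entries = []
    seen = set()
    for layer in chosen:
        for strand_idx, local in layer.positions:
            if rule.get("long_strands_only") and lengths[strand_idx] < 7:
                continue
            g = strand_ranges[strand_idx][0] + local - 1
            if g > rpp:
                g -= rpp  # express everything in repeat-1 numbering
            if g in seen:
                continue
            seen.add(g)
            from_aa = model.residue(g).one_letter
            if from_aa == "A":
                continue
            entries.append((g, from_aa, "A"))
    entries.sort()
    return MutationSet(entries=entries, symmetric=True)


def apply_variant(
    model: BarrelModel,
    variant: str | MutationSet,
    bp: Blueprint | None = None,
) -> tuple[BarrelModel, MutationSet]:
    """Apply a named PV/HV variant or an explicit mutation set.

    HV variants ablate core layers to alanine and automatically apply the
    repeat-partner mutation (offset = residues per repeat); mismatching
    from-residues raise an error naming the position.  Backbone
    coordinates are preserved exactly.
    """
    if bp is None:
        bp = make_ovoid_blueprint()
    if isinstance(variant, str):
        if variant in PV_VARIANTS:
            mset = MutationSet(entries=list(PV_VARIANTS[variant]), symmetric=False)
        elif variant in HV_VARIANTS:
            mset = _hv_mutation_set(model, bp, HV_VARIANTS[variant])
        else:
            raise ValueError(f"unknown variant {variant!r}")
    else:
        mset = MutationSet(entries=list(variant.entries), symmetric=variant.symmetric)
    entries = list(mset.entries)
    if mset.symmetric:
        expanded = []
        for pos, from_aa, to_aa in entries:
            expanded.append((pos, from_aa, to_aa))
            partner = repeat_partner(pos, bp)
            expanded.append((partner, model.residue(partner).one_letter, to_aa))
        entries = sorted(set(expanded))
    out = model.copy()
    for pos, from_aa, to_aa in entries:
        r = out.residue(pos)
        if r.one_letter != from_aa:
            raise ValueError(
                f"position {pos}: expected {from_aa}, model has {r.one_letter}"
            )
        _mutate_residue(out, r, to_aa)
    return out, MutationSet(entries=entries, symmetric=mset.symmetric)


# ----------------------------------------------------------------------
def make_curve_panel(seed: int = 0) -> list[dict]:
    """Panel of simulated denaturation curves over a parameter grid.

    Includes the ovoid design's reference unfolding parameters
    (dG = 8.4 kcal/mol, m = 1.6 kcal/mol/M, midpoint 5.25 M) at several
    noise levels and baseline slopes; deterministic per seed.
    """
    grid = [
        dict(dG=8.4, m_value=1.6, baselines=(1.0, -0.02, 0.1, -0.01)),
        dict(dG=8.4, m_value=1.6, baselines=(1.0, 0.0, 0.0, 0.0)),
        dict(dG=5.0, m_value=1.2, baselines=(0.8, -0.01, 0.05, -0.005)),
        dict(dG=10.0, m_value=2.0, baselines=(1.2, -0.03, 0.15, -0.02)),
    ]
    noises = [0.0, 0.01, 0.02]
    x = np.linspace(0.0, 7.5, 30)
    rng = np.random.default_rng(seed)
    panel = []
    for params in grid:
        for noise in noises:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            curve = simulate_curve(
                params["dG"],
                params["m_value"],
                baselines=params["baselines"],
                x=x,
                noise_sd=noise,
                seed=sub_seed,
            )
            panel.append(dict(curve=curve, noise_sd=noise, seed=sub_seed, **params))
    return panel
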