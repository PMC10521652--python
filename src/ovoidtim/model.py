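"""In-memory structure container shared by the generator and the analysis code.

A :class:`BarrelModel` is an ordered list of residues, each holding backbone
atom coordinates (N, CA, C, O, and CB unless glycine; generated fixtures may
add idealized side-chain pseudo-atoms for Ile/Leu/Val), the amino-acid
identity, a secondary-structure label and — for generated strand residues —
the core/exterior facing flag.  Conversion to and from biotite
``AtomArray`` objects provides PDB round-tripping and SASA computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import biotite.structure as struc

__all__ = ["Residue", "BarrelModel", "BACKBONE_ATOMS"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}


@dataclass
class Residue:
    """One residue: 1-based index, identity, label and atom coordinates."""

    index: int
    aa: str  # three-letter code
    atoms: dict[str, np.ndarray]
    chain_id: str = "A"
    element_label: str = ""  # 'E' strand, 'H' helix, 'L' loop, '' unknown
    facing: Optional[str] = None  # 'core' | 'exterior' | None

    @property
    def one_letter(self) -> str:
        return _AA3_TO_1.get(self.aa, "X")

    def copy(self) -> "Residue":
        return Residue(
            index=self.index,
            aa=self.aa,
            atoms={k: v.copy() for k, v in self.atoms.items()},
            chain_id=self.chain_id,
            element_label=self.element_label,
            facing=self.facing,
        )


@dataclass
class BarrelModel:
    """Ordered residue records of one polypeptide chain."""

    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def coords(self, atom: str = "CA", indices: Iterable[int] | None = None) -> np.ndarray:
        """Coordinates of one backbone atom over (a selection of) residues.

        ``indices`` are 1-based residue indices; residues lacking the atom
        are skipped when selecting over the whole chain but raise when an
        explicit selection names them.
        """
        if indices is None:
            return np.array([r.atoms[atom] for r in self.residues if atom in r.atoms])
        by_id = {r.index: r for r in self.residues}
        return np.array([by_id[i].atoms[atom] for i in indices])

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue {index}")

    def copy(self) -> "BarrelModel":
        return BarrelModel([r.copy() for r in self.residues])

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "BarrelModel":
        """Rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        for r in out.residues:
            for k in r.atoms:
                r.atoms[k] = rotation @ r.atoms[k] + translation
        return out

    # ------------------------------------------------------------------
    def to_atom_array(self) -> struc.AtomArray:
        n_atoms = sum(len(r.atoms) for r in self.residues)
        arr = struc.AtomArray(n_atoms)
        i = 0
        for r in self.residues:
            names = [a for a in ("N", "CA", "C", "O", "CB") if a in r.atoms]
            names += sorted(a for a in r.atoms if a not in ("N", "CA", "C", "O", "CB"))
            for name in names:
                arr.coord[i] = r.atoms[name]
                arr.chain_id[i] = r.chain_id
                arr.res_id[i] = r.index
                arr.res_name[i] = r.aa
                arr.atom_name[i] = name
                arr.element[i] = name[0]
                arr.hetero[i] = False
                i += 1
        arr.set_annotation("occupancy", np.ones(n_atoms))
        arr.set_annotation("b_factor", np.zeros(n_atoms))
        return arr

    @classmethod
    def from_atom_array(cls, arr: struc.AtomArray) -> "BarrelModel":
        residues = []
        for start in struc.get_residue_starts(arr):
            res_id = int(arr.res_id[start])
            mask = (arr.res_id == res_id) & (arr.chain_id == arr.chain_id[start])
            sub = arr[mask]
            atoms = {str(n): sub.coord[k].astype(float) for k, n in enumerate(sub.atom_name)}
            residues.append(
                Residue(
                    index=res_id,
                    aa=str(arr.res_name[start]),
                    atoms=atoms,
                    chain_id=str(arr.chain_id[start]),
                )
            )
        residues.sort(key=lambda r: r.index)
        return cls(residues)

    # ------------------------------------------------------------------
    def check_geometry(self) -> dict:
        """Basic chain-geometry diagnostics on contiguous residue runs."""
        ca_gaps = []
        for r1, r2 in zip(self.residues, self.residues[1:]):
            if r2.index == r1.index + 1 and "CA" in r1.atoms and "CA" in r2.atoms:
                ca_gaps.append(float(np.linalg.norm(r2.atoms["CA"] - r1.atoms["CA"])))
        gaps = np.array(ca_gaps)
        return {
            "n_residues": len(self.residues),
            "ca_ca_min": float(gaps.min()) if len(gaps) else np.nan,
            "ca_ca_max": float(gaps.max()) if len(gaps) else np.nan,
            "cb_missing_non_gly": sum(
                1 for r in self.residues if r.aa != "GLY" and "CB" not in r.atoms
            ),
        }


def aa1to3(one: str) -> str:
    return _AA1_TO_3[one.upper()]


def aa3to1(three: str) -> str:
    return _AA3_TO_1[three.upper()]
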