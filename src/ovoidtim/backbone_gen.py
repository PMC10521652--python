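"""Parametric construction of idealized circular and ovoid barrel backbones.

The barrel wall is built on a sheared sheet lattice that is then rolled
onto an elliptic cylinder.  In the unrolled plane (circumferential
coordinate ``u``, axial coordinate ``v``) residue ``m`` (ladder
coordinate) of strand ``i`` sits at ``i*t + m*s`` where

* ``s = h (sin a, cos a)`` is the per-residue step along a strand
  (``h`` = rise per residue),
* ``t = d (cos a, -sin a)`` is the inter-strand step between
  hydrogen-bonded partners (``d`` = interstrand spacing),
* the strand tilt ``a`` follows the classical barrel relation
  ``tan a = -S h / (n d)`` for shear ``S`` and strand count ``n``.

With this tilt the seam closes exactly: traversing all ``n`` junctions
returns to strand 1 offset by ``S`` residues, and the circumference is
``C = n d cos a - S h sin a``.  The lattice is rolled onto an ellipse of
perimeter ``C`` whose axis ratio follows the requested semi-axes; the
pair of adjacent strands with the greatest combined length is centred on
a flat (co-vertex) face, realizing the long-strands-on-the-major-face
hypothesis of ovoid barrel design.  Alpha helices are placed outside the
wall, antiparallel to their preceding strand, and loops are routed along
arc-length-resampled Bezier curves.  Twofold blueprints yield exactly
screw-symmetric coordinates, because every construction step is
equivariant under rotation about the barrel axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure.io.pdb as pdb

from ovoidtim.model import BarrelModel, Residue
from ovoidtim.syntax import Blueprint, compute_shear

__all__ = [
    "BarrelParams",
    "SearchState",
    "ClosureError",
    "ClashError",
    "generate_barrel",
    "generate_full_timb",
    "write_pdb",
    "autoregressive_search",
]

logger = logging.getLogger(__name__)

_Z = np.array([0.0, 0.0, 1.0])


class ClosureError(ValueError):
    """The blueprint's shear/strand lengths cannot close the barrel."""


class ClashError(ValueError):
    """Generated backbone contains a steric clash."""


@dataclass(frozen=True)
class BarrelParams:
    """Geometric parameters of the idealized barrel (all lengths in Å)."""

    semi_major_a: float = 13.0
    semi_minor_b: float = 9.0
    rise_per_residue: float = 3.3
    interstrand_spacing: float = 4.8
    pleat: float = 0.8
    helix_radial_offset: float = 8.0
    helix_rise: float = 1.5
    helix_radius: float = 2.3
    helix_tilt_blend: float = 0.85  # 1 = fully antiparallel to the strand
    ca_ca: float = 3.8

    def __post_init__(self) -> None:
        if not self.semi_major_a >= self.semi_minor_b > 0:
            raise ValueError("need a >= b > 0")
        if not 3.0 <= self.rise_per_residue <= 3.6:
            raise ValueError("rise_per_residue outside [3.0, 3.6] Å")
        if not 4.2 <= self.interstrand_spacing <= 5.2:
            raise ValueError("interstrand_spacing outside [4.2, 5.2] Å")

    def strand_tilt(self, n_strands: int, shear: int) -> float:
        """Strand tilt angle (radians, negative by the sign convention)."""
        return -np.arctan2(
            shear * self.rise_per_residue, n_strands * self.interstrand_spacing
        )


# ----------------------------------------------------------------------
# Elliptic cross-section: exact arc-length parameterization with the
# quadrant symmetries enforced analytically, so antipodal points are
# exact central images of each other (twofold models come out exactly
# screw-symmetric).
# ----------------------------------------------------------------------
class _EllipseMapper:
    def __init__(self, a: float, b: float, n_grid: int = 4096):
        self.a, self.b = a, b
        theta = np.linspace(0.0, np.pi / 2, n_grid)
        speed = np.hypot(a * np.sin(theta), b * np.cos(theta))
        arc = np.concatenate(([0.0], np.cumsum(np.diff(theta) * 0.5 * (speed[1:] + speed[:-1]))))
        self._theta_grid = theta
        self._arc_grid = arc
        self.quarter = float(arc[-1])
        self.perimeter = 4.0 * self.quarter

    def _first_quadrant(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        th = float(np.interp(s, self._arc_grid, self._theta_grid))
        p = np.array([self.a * np.cos(th), self.b * np.sin(th)])
        tan = np.array([-self.a * np.sin(th), self.b * np.cos(th)])
        tan /= np.linalg.norm(tan)
        nrm = np.array([self.b * np.cos(th), self.a * np.sin(th)])
        nrm /= np.linalg.norm(nrm)
        return p, tan, nrm

    def at(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(point, ccw tangent, outward normal) at arc length ``s`` from (a, 0)."""
        s = float(s) % self.perimeter
        if s >= 2 * self.quarter:  # central symmetry, exact
            p, tan, nrm = self.at(s - 2 * self.quarter)
            return -p, -tan, -nrm
        if s > self.quarter:  # mirror across the y-axis
            p, tan, nrm = self._first_quadrant(2 * self.quarter - s)
            return (
                np.array([-p[0], p[1]]),
                np.array([tan[0], -tan[1]]),
                np.array([-nrm[0], nrm[1]]),
            )
        return self._first_quadrant(s)


# ----------------------------------------------------------------------
# Lattice bookkeeping
# ----------------------------------------------------------------------
@dataclass
class _Lattice:
    s_vec: np.ndarray  # (u, v) per-residue strand step
    t_vec: np.ndarray  # (u, v) inter-strand step
    circumference: float
    u_anchor: float
    mapper: _EllipseMapper
    tilt: float


def _build_lattice(bp: Blueprint, params: BarrelParams) -> _Lattice:
    n = bp.n_strands
    S = compute_shear(bp)
    if S % 2 != 0:
        raise ClosureError(
            f"shear {S} is odd: pleat parity cannot close around the barrel"
        )
    h, d = params.rise_per_residue, params.interstrand_spacing
    alpha = params.strand_tilt(n, S)
    s_vec = h * np.array([np.sin(alpha), np.cos(alpha)])
    t_vec = d * np.array([np.cos(alpha), -np.sin(alpha)])
    C = n * t_vec[0] - S * s_vec[0]

    # every junction must share at least one ladder rung
    c = bp.cumulative_shifts()
    lengths = bp.strand_lengths
    m_ranges = [(1 - c[i], lengths[i] - c[i]) for i in range(n)]
    for i in range(n):
        j = (i + 1) % n
        # across the seam, strand 1 reappears shifted down by the shear
        lo = max(m_ranges[i][0], m_ranges[j][0] - (S if j == 0 else 0))
        hi = min(m_ranges[i][1], m_ranges[j][1] - (S if j == 0 else 0))
        if lo > hi:
            raise ClosureError(
                f"strands {i + 1} and {j + 1} share no ladder rung: "
                "register shifts and strand lengths cannot close the barrel"
            )

    # strand centers in u; anchor the longest adjacent pair on a flat face
    centers = [
        i * t_vec[0] + ((lengths[i] + 1) / 2 - c[i]) * s_vec[0] for i in range(n)
    ]
    pair_len = [lengths[i] + lengths[(i + 1) % n] for i in range(n)]
    k = int(np.argmax(pair_len))
    u_next = centers[(k + 1) % n] + (C if (k + 1) % n == 0 else 0.0)
    u_anchor = 0.5 * (centers[k] + u_next)

    # scale requested semi-axes so the ellipse perimeter equals C
    trial = _EllipseMapper(params.semi_major_a, params.semi_minor_b)
    sigma = C / trial.perimeter
    mapper = _EllipseMapper(sigma * params.semi_major_a, sigma * params.semi_minor_b)
    return _Lattice(s_vec, t_vec, C, u_anchor, mapper, alpha)


def _strand_frame(lat: _Lattice, i: int, m: float):
    """3D position on the wall mid-surface plus local frame at (strand i, m)."""
    u = i * lat.t_vec[0] + m * lat.s_vec[0]
    v = i * lat.t_vec[1] + m * lat.s_vec[1]
    s_arc = (u - lat.u_anchor) + lat.mapper.quarter
    p2, tan2, nrm2 = lat.mapper.at(s_arc)
    pos = np.array([p2[0], p2[1], v])
    tangent = np.array([tan2[0], tan2[1], 0.0])
    normal = np.array([nrm2[0], nrm2[1], 0.0])
    # inter-strand (ladder) direction within the wall surface
    ca, sa = np.cos(lat.tilt), np.sin(lat.tilt)
    w_lad = ca * tangent - sa * _Z  # unit; points toward strand i+1
    return pos, tangent, normal, w_lad


# ----------------------------------------------------------------------
# Backbone atoms from a CA trace
# ----------------------------------------------------------------------
# Idealized in-plane peptide geometry: C sits ahead of CA along the
# chain, displaced to the residue's "carbonyl side" w; O extends from C
# mostly along w; N sits on the chain line.  For strand residues w is
# the ladder direction with alternating sign, which aims carbonyls at
# the neighbouring strand and produces N...O ladder distances near 3 Å.
_F_C = 1.15  # CA->C along-chain component
_G_C = 0.65  # CA->C lateral component
_F_N = 1.20  # CA->N along-chain (backwards) component
_O_W = 1.00  # O direction: lateral weight
_O_BACK = 0.30  # O direction: backwards weight


def _backbone_pass(
    cas: np.ndarray, w_vecs: np.ndarray, kinds: Sequence[str]
) -> list[dict[str, np.ndarray]]:
    n = len(cas)
    atoms: list[dict[str, np.ndarray]] = [dict() for _ in range(n)]
    units = np.zeros((n, 3))
    for k in range(n - 1):
        step = cas[k + 1] - cas[k]
        units[k] = step / np.linalg.norm(step)
    if n > 1:
        units[n - 1] = units[n - 2]
    for k in range(n):
        u_next = units[k]
        u_prev = units[k - 1] if k > 0 else units[k]
        helix_interior = (
            kinds[k] == "H"
            and 0 < k < n - 1
            and kinds[k - 1] == "H"
            and kinds[k + 1] == "H"
        )
        if helix_interior:
            # carbonyls run along the local helix axis, as in a real helix
            lo, hi = max(0, k - 2), min(n - 1, k + 2)
            axis = cas[hi] - cas[lo]
            na = np.linalg.norm(axis)
            w = axis / na if na > 1e-8 else u_next
            c = cas[k] + 0.9 * u_next + 0.5 * w
            atoms[k]["C"] = c
            atoms[k]["O"] = c + 1.23 * w
            atoms[k]["CA"] = cas[k]
            atoms[k]["N"] = cas[k] - _F_N * u_prev
            continue
        if kinds[k] != "E":
            # loop (or helix-terminal) carbonyl along the turn binormal:
            # out of the bend plane, clear of the i±2 backbone
            w = np.cross(u_prev, u_next)
            if np.linalg.norm(w) < 0.25:
                w = np.cross(u_next, _Z)
        else:
            w = w_vecs[k]
        w = w - np.dot(w, u_next) * u_next
        nw = np.linalg.norm(w)
        w = w / nw if nw > 1e-8 else np.array([1.0, 0.0, 0.0])
        atoms[k]["CA"] = cas[k]
        atoms[k]["N"] = cas[k] - _F_N * u_prev
        c = cas[k] + _F_C * u_next + _G_C * w
        o_dir = _O_W * w - _O_BACK * u_next
        atoms[k]["C"] = c
        atoms[k]["O"] = c + 1.23 * o_dir / np.linalg.norm(o_dir)
    return atoms


def _place_cb(atoms: dict[str, np.ndarray], direction: np.ndarray) -> None:
    d = direction / np.linalg.norm(direction)
    atoms["CB"] = atoms["CA"] + 1.53 * d


# ----------------------------------------------------------------------
# Loop routing: cubic Bezier with an outward bulge sized so the resampled
# polyline carries the loop's residues at ~3.8 Å spacing.
# ----------------------------------------------------------------------
def _bezier(p0, p1, p2, p3, t):
    t = np.asarray(t)[:, None]
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t**2 * p2
        + t**3 * p3
    )


def _route_loop(
    p_start: np.ndarray,
    dir_out: np.ndarray,
    p_end: np.ndarray,
    dir_in: np.ndarray,
    n_res: int,
    spacing: float,
    bulge_dir: np.ndarray,
) -> np.ndarray:
    target = spacing * (n_res + 1)
    chord = np.linalg.norm(p_end - p_start)
    if chord > target:
        raise ClosureError(
            f"loop of {n_res} residues cannot span {chord:.1f} Å "
            f"(max {target:.1f} Å)"
        )
    g = max(chord / 3.0, 1.0)
    ts = np.linspace(0.0, 1.0, 400)
    arm = 1.0  # control-arm scale; shrunk toward a straight line if needed

    def curve(bulge: float) -> np.ndarray:
        base1 = p_start + arm * g * dir_out
        base2 = p_end - arm * g * dir_in
        return _bezier(p_start, base1 + bulge * bulge_dir, base2 + bulge * bulge_dir, p_end, ts)

    def arclen(bulge: float) -> float:
        pts = curve(bulge)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    if arclen(0.0) > target:
        # tangent-following arms overshoot the arc budget: straighten
        lo_a, hi_a = 0.0, 1.0
        for _ in range(40):
            arm = 0.5 * (lo_a + hi_a)
            if arclen(0.0) > target:
                hi_a = arm
            else:
                lo_a = arm
        arm = lo_a

    def resample(dense: np.ndarray) -> np.ndarray:
        """Pick n_res interior points on the curve at near-equal chords."""
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        total = cum[-1]

        def at(svals: np.ndarray) -> np.ndarray:
            out = np.empty((len(svals), 3))
            for d in range(3):
                out[:, d] = np.interp(svals, cum, dense[:, d])
            return out

        ds = np.full(n_res + 1, total / (n_res + 1))
        for _ in range(6):
            s = np.concatenate(([0.0], np.cumsum(ds)))
            pts = at(s)
            chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            ds = ds * np.mean(chords) / np.maximum(chords, 1e-9)
            ds *= total / ds.sum()
        s = np.concatenate(([0.0], np.cumsum(ds)))
        return at(s)[1:-1]

    goal = target
    interior = None
    for _ in range(5):
        if arclen(0.0) >= goal:
            bulge = 0.0
        else:
            lo, hi = 0.0, 60.0
            while arclen(hi) < goal and hi < 400:
                hi *= 2
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if arclen(mid) < goal:
                    lo = mid
                else:
                    hi = mid
            bulge = 0.5 * (lo + hi)
        interior = resample(curve(bulge))
        path = np.vstack([p_start, interior, p_end])
        chords = np.linalg.norm(np.diff(path, axis=0), axis=1)
        mean_chord = float(chords.mean())
        if abs(mean_chord - spacing) < 0.01:
            break
        goal *= spacing / mean_chord
    return interior


# ----------------------------------------------------------------------
# Generators
# ----------------------------------------------------------------------
def _generate(
    bp: Blueprint,
    params: BarrelParams,
    include_helices: bool,
    sequence: str | None = None,
    check_clashes: bool = False,
    include_loops: bool | None = None,
) -> BarrelModel:
    lat = _build_lattice(bp, params)
    S = compute_shear(bp)
    c = bp.cumulative_shifts()
    elem_ranges = bp.element_ranges()

    # ---- strand CA traces -------------------------------------------
    strand_info = []  # per strand: dict with residues, cas, frames
    si = -1
    for e, a, b in elem_ranges:
        if e.kind != "strand":
            continue
        si += 1
        rows = []
        for local, g in enumerate(range(a, b + 1), start=1):
            m = local - c[si]
            pos, tangent, normal, w_lad = _strand_frame(lat, si, m)
            core = m % 2 == 0
            ca = pos + (-params.pleat if core else params.pleat) * normal
            rows.append(
                dict(g=g, local=local, m=m, ca=ca, normal=normal,
                     w_lad=w_lad, core=core)
            )
        cas = np.array([r["ca"] for r in rows])
        direction = cas[-1] - cas[0]
        strand_info.append(dict(index=si, rows=rows, cas=cas,
                                direction=direction / np.linalg.norm(direction)))

    n = bp.n_strands
    helix_elements = [e for e, _, _ in elem_ranges if e.kind == "helix"]
    build_loops = (
        include_loops
        if include_loops is not None
        else (include_helices or not helix_elements)
    )

    # ---- helix CA traces --------------------------------------------
    helix_traces: dict[int, np.ndarray] = {}
    if include_helices and helix_elements:
        hi = -1
        for idx, (e, a, b) in enumerate(elem_ranges):
            if e.kind != "helix":
                continue
            hi += 1
            prev_strand = strand_info[hi % n]
            next_strand = strand_info[(hi + 1) % n]
            # angular anchor between the two points the helix must bridge:
            # the preceding strand's top and the following strand's bottom
            # (using the seam image of strand 1 for the last helix)
            u_top = (
                prev_strand["index"] * lat.t_vec[0]
                + prev_strand["rows"][-1]["m"] * lat.s_vec[0]
            )
            m_bot = next_strand["rows"][0]["m"] - (S if hi + 1 == n else 0)
            u_bot = (hi + 1) * lat.t_vec[0] + m_bot * lat.s_vec[0]
            u_mid = 0.5 * (u_top + u_bot)
            p2, _, nrm2 = lat.mapper.at((u_mid - lat.u_anchor) + lat.mapper.quarter)
            base_xy = np.array([p2[0], p2[1], 0.0]) + params.helix_radial_offset * np.array(
                [nrm2[0], nrm2[1], 0.0]
            )
            sdir = prev_strand["direction"]
            axis_dir = -(params.helix_tilt_blend * sdir
                         + (1.0 - params.helix_tilt_blend) * _Z * np.sign(sdir[2]))
            axis_dir /= np.linalg.norm(axis_dir)
            z_top = prev_strand["cas"][-1][2]
            z_bot = next_strand["cas"][0][2]
            z_center = 0.5 * (z_top + z_bot)
            span = params.helix_rise * (e.length - 1)
            a0 = base_xy + np.array([0.0, 0.0, z_center]) - axis_dir * (span / 2.0)
            # slide along the axis so both flanking loops can span their gaps
            p_top_strand = prev_strand["cas"][-1]
            p_bot_strand = next_strand["cas"][0]
            end0 = a0 + axis_dir * span
            lb = elem_ranges[idx - 1][0].length if idx > 0 else 3
            la = (
                elem_ranges[idx + 1][0].length if idx + 1 < len(elem_ranges) else 3
            )
            budget_start = params.ca_ca * (lb + 1) - 2.5
            budget_end = params.ca_ca * (la + 1) - 2.5
            # slide the helix along its axis so both flanking loops can
            # span their gaps without excessive slack
            best, best_cost = 0.0, np.inf
            for slide in np.linspace(-8.0, 8.0, 161):
                d_start = np.linalg.norm((a0 + slide * axis_dir) - p_top_strand)
                d_end = np.linalg.norm((end0 + slide * axis_dir) - p_bot_strand)
                cost = (
                    10.0 * max(0.0, d_start - (budget_start - 1.0))
                    + 10.0 * max(0.0, d_end - (budget_end - 1.0))
                    + max(0.0, 7.0 - d_start)
                    + max(0.0, 7.0 - d_end)
                    + 0.02 * abs(slide)
                )
                if cost < best_cost:
                    best, best_cost = slide, cost
            a0 = a0 + best * axis_dir
            e1 = np.array([nrm2[0], nrm2[1], 0.0])
            e1 = e1 - np.dot(e1, axis_dir) * axis_dir
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis_dir, e1)
            js = np.arange(e.length)
            ang = np.deg2rad(100.0) * js
            helix_traces[idx] = (
                a0[None, :]
                + axis_dir[None, :] * (params.helix_rise * js)[:, None]
                + params.helix_radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
            )

    # ---- assemble chain CA trace in blueprint order ------------------
    chain: list[dict] = []  # per residue: g, ca (may be None for loops), kind, meta
    si = -1
    for idx, (e, a, b) in enumerate(elem_ranges):
        if e.kind == "strand":
            si += 1
            for r in strand_info[si]["rows"]:
                chain.append(dict(g=r["g"], ca=r["ca"], kind="E", core=r["core"],
                                  normal=r["normal"], w_lad=r["w_lad"], m=r["m"],
                                  strand=si))
        elif e.kind == "helix":
            if idx in helix_traces:
                for k, g in enumerate(range(a, b + 1)):
                    chain.append(dict(g=g, ca=helix_traces[idx][k], kind="H"))
        else:  # loop
            if build_loops:
                for g in range(a, b + 1):
                    chain.append(dict(g=g, ca=None, kind="L"))

    # route loop runs between placed flanks; terminal runs are extrapolated
    placed = {r["g"]: r for r in chain if r["ca"] is not None}
    runs: list[list[dict]] = []
    cur: list[dict] = []
    for rec in chain:
        if rec["ca"] is None:
            if cur and rec["g"] != cur[-1]["g"] + 1:
                runs.append(cur)
                cur = []
            cur.append(rec)
        else:
            if cur:
                runs.append(cur)
                cur = []
    if cur:
        runs.append(cur)
    drop: set[int] = set()
    z_vals = [r["ca"][2] for r in chain if r["ca"] is not None]
    z_center = 0.5 * (max(z_vals) + min(z_vals)) if z_vals else 0.0
    for run in runs:
        g0, g1 = run[0]["g"] - 1, run[-1]["g"] + 1
        if g0 not in placed and g1 not in placed:
            drop.update(r["g"] for r in run)
            continue
        if g1 not in placed or g0 not in placed:
            # terminal run: place as the repeat-symmetry image of its
            # partner run when possible (keeps twofold models exactly
            # screw-symmetric), otherwise extrapolate along the chain
            rpp = bp.residues_per_repeat
            partner_ok = (
                bp.repeat_count >= 2
                and all((r["g"] - rpp) in placed for r in run)
            )
            if partner_ok:
                pairs = [
                    (placed[g]["ca"], placed[g + rpp]["ca"])
                    for g in placed
                    if (g + rpp) in placed
                ]
                from ovoidtim._rigid import kabsch

                R, t, _ = kabsch(
                    np.array([p for p, _ in pairs]), np.array([q for _, q in pairs])
                )
                for rec in run:
                    rec["ca"] = R @ placed[rec["g"] - rpp]["ca"] + t
            else:
                anchor_g, step = (g0, 1) if g0 in placed else (g1, -1)
                p_a = placed[anchor_g]["ca"]
                nb = placed.get(anchor_g - step)
                d_dir = (
                    (p_a - nb["ca"]) / np.linalg.norm(p_a - nb["ca"])
                    if nb is not None
                    else np.array([0.0, 0.0, float(step)])
                )
                away = np.array([p_a[0], p_a[1], 0.0])
                na = np.linalg.norm(away)
                away = away / na if na > 1e-6 else np.array([1.0, 0.0, 0.0])
                d_dir = d_dir + 0.7 * away
                d_dir /= np.linalg.norm(d_dir)
                ordered = run if step == 1 else list(reversed(run))
                for k, rec in enumerate(ordered, start=1):
                    rec["ca"] = p_a + params.ca_ca * k * d_dir
            for rec in run:
                placed[rec["g"]] = rec
            continue
        p0, p3 = placed[g0]["ca"], placed[g1]["ca"]
        before = placed.get(g0 - 1)
        after = placed.get(g1 + 1)
        d_out = (
            (p0 - before["ca"]) / np.linalg.norm(p0 - before["ca"])
            if before is not None
            else np.array([0.0, 0.0, 1.0])
        )
        d_in = (
            (after["ca"] - p3) / np.linalg.norm(after["ca"] - p3)
            if after is not None
            else np.array([0.0, 0.0, -1.0])
        )
        mid_xy = 0.5 * (p0 + p3)
        nxy = np.linalg.norm(mid_xy[:2])
        radial = (
            np.array([mid_xy[0] / nxy, mid_xy[1] / nxy, 0.0])
            if nxy > 1e-6
            else np.array([1.0, 0.0, 0.0])
        )
        if not helix_elements:
            # single-wall barrel: bow the strand-to-strand crossovers
            # radially away from the wall
            bulge_dir = radial
        elif mid_xy[2] >= z_center:
            # top loops bow up and slightly outward, clear of strand tops
            bulge_dir = 0.35 * radial + np.array([0.0, 0.0, 1.0])
        else:
            # bottom turns bow straight down, clear of helix ends
            bulge_dir = np.array([0.0, 0.0, -1.0])
        bulge_dir = bulge_dir / np.linalg.norm(bulge_dir)
        pts = _route_loop(p0, d_out, p3, d_in, len(run), params.ca_ca, bulge_dir)
        for rec, p in zip(run, pts):
            rec["ca"] = p
            placed[rec["g"]] = rec

    chain = [r for r in chain if r["ca"] is not None and r["g"] not in drop]
    chain.sort(key=lambda r: r["g"])

    # ---- backbone atoms over contiguous runs -------------------------
    seq = sequence or "A" * bp.total_residues
    model = BarrelModel()
    i = 0
    while i < len(chain):
        j = i
        while j + 1 < len(chain) and chain[j + 1]["g"] == chain[j]["g"] + 1:
            j += 1
        segment = chain[i : j + 1]
        cas = np.array([r["ca"] for r in segment])
        ws = []
        for k, rec in enumerate(segment):
            if rec["kind"] == "E":
                sign = 1.0 if rec["m"] % 2 == 0 else -1.0
                ws.append(sign * rec["w_lad"])
            else:
                u = (
                    cas[min(k + 1, len(cas) - 1)] - cas[max(k - 1, 0)]
                )
                w = np.cross(u, _Z)
                nw = np.linalg.norm(w)
                ws.append(w / nw if nw > 1e-6 else np.array([1.0, 0.0, 0.0]))
        atoms_list = _backbone_pass(
            cas, np.array(ws), [rec["kind"] for rec in segment]
        )
        for rec, atoms in zip(segment, atoms_list):
            aa1 = seq[rec["g"] - 1]
            from ovoidtim.model import aa1to3

            aa = aa1to3(aa1)
            if aa != "GLY":
                if rec["kind"] == "E":
                    direction = (-1.0 if rec["core"] else 1.0) * rec["normal"]
                else:
                    ca_xy = np.array([rec["ca"][0], rec["ca"][1], 0.0])
                    nrm = np.linalg.norm(ca_xy)
                    direction = ca_xy / nrm if nrm > 1e-6 else np.array([1.0, 0, 0])
                _place_cb(atoms, direction)
            res = Residue(
                index=rec["g"],
                aa=aa,
                atoms=atoms,
                element_label=rec["kind"],
                facing=(
                    ("core" if rec["core"] else "exterior") if rec["kind"] == "E" else None
                ),
            )
            model.residues.append(res)
        i = j + 1

    if check_clashes:
        _check_clashes(model)
    return model


def _check_clashes(model: BarrelModel, cutoff: float = 2.5) -> None:
    coords, res_ids = [], []
    for r in model.residues:
        for name in ("N", "CA", "C", "O"):
            if name in r.atoms:
                coords.append(r.atoms[name])
                res_ids.append(r.index)
    coords = np.array(coords)
    res_ids = np.array(res_ids)
    first, last = int(res_ids.min()), int(res_ids.max())
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(cutoff):
        pair = {int(res_ids[a]), int(res_ids[b])}
        if pair == {first, last}:
            continue  # pseudo-cyclic seam: the tail closes onto strand 1
        if abs(res_ids[a] - res_ids[b]) >= 2:
            raise ClashError(
                f"backbone clash between residues {res_ids[a]} and {res_ids[b]}"
            )


def generate_barrel(
    bp: Blueprint,
    params: BarrelParams | None = None,
    sequence: str | None = None,
    include_loops: bool | None = None,
) -> BarrelModel:
    """Generate the closed beta-barrel wall of a blueprint.

    Strand residues are placed on the rolled sheet lattice; loops directly
    connecting strands (single-wall blueprints without helices) are routed
    too, while helices and their flanking loops are omitted.  Raises
    :class:`ClosureError` when the register shifts cannot close the barrel.
    """
    return _generate(bp, params or BarrelParams(), include_helices=False,
                     sequence=sequence, include_loops=include_loops)


def generate_full_timb(
    bp: Blueprint, params: BarrelParams | None = None, sequence: str | None = None
) -> BarrelModel:
    """Generate the complete TIM barrel: wall, outer helices and loops.

    The chain is a single connected backbone; a :class:`ClashError` is
    raised if non-bonded backbone atoms approach closer than 2.5 Å.
    """
    return _generate(bp, params or BarrelParams(), include_helices=True,
                     sequence=sequence, check_clashes=True)


def write_pdb(model: BarrelModel, path: str | Path) -> None:
    """Write the model as a single-chain, single-model PDB file."""
    f = pdb.PDBFile()
    pdb.set_structure(f, model.to_atom_array())
    f.write(str(path))


# ----------------------------------------------------------------------
# Autoregressive element-length search
# ----------------------------------------------------------------------
@dataclass
class SearchState:
    """State of the phase-wise element-length search."""

    fixed_prefix: dict[str, int] = field(default_factory=dict)
    candidate_grid: dict[str, Sequence[int]] = field(default_factory=dict)
    scores: dict = field(default_factory=dict)


def autoregressive_search(
    initial: SearchState,
    scorer: Callable[[Mapping[str, int]], float],
    phases: Sequence[str],
    builder: Callable[[Mapping[str, int]], Blueprint] | None = None,
):
    """Greedy phase-wise search over element lengths.

    For each phase (slot name) in order, every candidate length is scored
    with the already-fixed prefix held constant; the argmax is frozen and
    the search proceeds to the next slot.  Ties resolve to the smallest
    length (with a warning).  Returns ``(assignment_or_blueprint, trace)``
    where the trace records ``(slot, candidate, score)`` triples.
    """
    assignment = dict(initial.fixed_prefix)
    trace: list[tuple[str, int, float]] = []
    for slot in phases:
        grid = sorted(initial.candidate_grid.get(slot, ()))
        if not grid:
            raise ValueError(f"empty candidate grid for slot {slot!r}")
        best_len, best_score = None, -np.inf
        tied = False
        for cand in grid:
            trial = dict(assignment, **{slot: cand})
            sc = float(scorer(trial))
            trace.append((slot, cand, sc))
            initial.scores[(slot, cand)] = sc
            if sc > best_score + 1e-12:
                best_len, best_score, tied = cand, sc, False
            elif abs(sc - best_score) <= 1e-12:
                tied = True
        if tied:
            warnings.warn(
                f"score tie in slot {slot!r}; keeping smallest length {best_len}"
            )
        assignment[slot] = best_len
    result = builder(assignment) if builder is not None else assignment
    return result, trace
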