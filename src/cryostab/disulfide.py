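"""Geometric scan for engineerable disulfide (cysteine pair) sites.

Candidate residue pairs are screened by three criteria: local flexibility
(per-residue RMSF), a Cb-Cb distance near the ~4 A window compatible with
disulfide formation, and distance from the ice-binding site. A cheap
rotamer-grid geometry score checks whether an idealized S-S bond (Sg-Sg
2.05 A, chi3 near +/-87 deg) is reachable from the two backbones. The score
is a screening heuristic, not an energy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flexibility import FlexibilityProfile
from .structmodel import ResidueId, Structure

__all__ = [
    "ScanParams",
    "DisulfideCandidate",
    "virtual_cbeta",
    "cb_distance",
    "geometry_penalty",
    "scan_candidates",
]

CB_BOND = 1.53  # CA-CB, Angstrom
SG_BOND = 1.81  # CB-SG, Angstrom
SG_ANGLE = 114.0  # CA-CB-SG, degrees
SS_BOND = 2.05  # ideal Sg-Sg, Angstrom
CHI3_IDEAL = 87.0  # ideal |chi3|, degrees


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg) -> np.ndarray:
    """Place atom D from internal coordinates relative to chain A-B-C.

    |D-C| = bond, angle(B,C,D) = angle_deg, dihedral(A,B,C,D) = dihedral_deg.
    ``dihedral_deg`` may be an array; the result is then (n, 3).
    """
    dihedral = np.atleast_1d(np.deg2rad(np.asarray(dihedral_deg, dtype=float)))
    ang = np.deg2rad(angle_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("collinear reference atoms; dihedral frame undefined")
    n /= norm
    m = np.cross(n, bc)
    d2 = np.stack(
        [
            np.full_like(dihedral, -bond * np.cos(ang)),
            -bond * np.sin(ang) * np.cos(dihedral),
            -bond * np.sin(ang) * np.sin(dihedral),
        ],
        axis=-1,
    )
    basis = np.stack([bc, m, n], axis=0)  # rows
    out = c + d2 @ basis
    return out[0] if np.isscalar(dihedral_deg) or np.ndim(dihedral_deg) == 0 else out


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone(structure: Structure, residue: ResidueId) -> tuple[np.ndarray, ...]:
    coords = []
    for name in ("N", "CA", "C"):
        if not structure.has_atom(residue, name):
            raise ValueError(f"residue {residue} is missing backbone atom {name}")
        coords.append(structure.atom(residue, name).xyz)
    return tuple(coords)


def virtual_cbeta(structure: Structure, residue: ResidueId) -> np.ndarray:
    """Return the residue's Cb position, constructing an idealized one for
    glycine (or any residue without a stored CB) from its N/CA/C frame."""
    if structure.has_atom(residue, "CB"):
        return structure.atom(residue, "CB").xyz
    n, ca, c = _backbone(structure, residue)
    # Tetrahedral branch direction (standard virtual-Cb construction); the
    # coefficient form fixes L-amino-acid chirality.
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    raw = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec
    direction = raw / np.linalg.norm(raw)
    return ca + CB_BOND * direction


def cb_distance(structure: Structure, a: ResidueId, b: ResidueId) -> float:
    """Euclidean Cb-Cb distance (A), using virtual Cb where needed."""
    return float(np.linalg.norm(virtual_cbeta(structure, a) - virtual_cbeta(structure, b)))


def _sg_grid(structure: Structure, residue: ResidueId, chis: np.ndarray) -> np.ndarray:
    """Idealized Sg positions for an array of chi1 values (degrees)."""
    n, ca, _ = _backbone(structure, residue)
    cb = virtual_cbeta(structure, residue)
    return place_atom(n, ca, cb, SG_BOND, SG_ANGLE, chis)


def _penalty_matrix(
    cb_a: np.ndarray, sg_a: np.ndarray, cb_b: np.ndarray, sg_b: np.ndarray,
    w_d: float = 1.0, w_chi: float = 1.0,
) -> np.ndarray:
    """Penalty for every (chi1_a, chi1_b) combination; shape (na, nb)."""
    diff = sg_b[None, :, :] - sg_a[:, None, :]  # Sg_a -> Sg_b
    dss = np.linalg.norm(diff, axis=2)
    # chi3 = dihedral CBa-SGa-SGb-CBb over the grid
    b0 = sg_a - cb_a  # (na, 3)
    b1 = diff
    b2 = (cb_b - sg_b)  # (nb, 3)
    b1n = b1 / np.linalg.norm(b1, axis=2, keepdims=True)
    v = b0[:, None, :] - np.sum(b0[:, None, :] * b1n, axis=2, keepdims=True) * b1n
    w = b2[None, :, :] - np.sum(b2[None, :, :] * b1n, axis=2, keepdims=True) * b1n
    x = np.sum(v * w, axis=2)
    y = np.sum(np.cross(b1n, v) * w, axis=2)
    chi3 = np.degrees(np.arctan2(y, x))
    dev = np.minimum(np.abs(chi3 - CHI3_IDEAL), np.abs(chi3 + CHI3_IDEAL))
    return w_d * (dss - SS_BOND) ** 2 + w_chi * (dev / 30.0) ** 2


def geometry_penalty(
    structure: Structure,
    a: ResidueId,
    b: ResidueId,
    grid_step: float = 10.0,
    refine: bool = True,
) -> float:
    """Disulfide-feasibility screening score (dimensionless; lower is better).

    Idealized Sg atoms are swept over a chi1 grid on both residues; the score
    is the grid minimum of ``(d(Sg,Sg) - 2.05)^2 + (dev(chi3)/30)^2`` where
    dev is the angular distance of chi3 from the nearest of +/-87 deg. With
    ``refine`` the best coarse basins are re-scanned on a 1 deg local grid so
    the result is insensitive to the coarse step.
    """
    cb_a = virtual_cbeta(structure, a)
    cb_b = virtual_cbeta(structure, b)
    chis = np.arange(0.0, 360.0, grid_step)
    sg_a = _sg_grid(structure, a, chis)
    sg_b = _sg_grid(structure, b, chis)
    pen = _penalty_matrix(cb_a, sg_a, cb_b, sg_b)
    best = float(pen.min())
    if not refine or grid_step <= 1.0:
        return best
    # deterministic local 1-degree refinement around competitive coarse points
    coarse_pts = np.argwhere(pen <= best + 2.0)
    if len(coarse_pts) > 200:
        order = np.argsort(pen[coarse_pts[:, 0], coarse_pts[:, 1]], kind="stable")
        coarse_pts = coarse_pts[order[:200]]
    half = grid_step
    for ia, ib in coarse_pts:
        local_a = chis[ia] + np.arange(-half, half + 0.5, 1.0)
        local_b = chis[ib] + np.arange(-half, half + 0.5, 1.0)
        sga = _sg_grid(structure, a, local_a % 360.0)
        sgb = _sg_grid(structure, b, local_b % 360.0)
        best = min(best, float(_penalty_matrix(cb_a, sga, cb_b, sgb).min()))
    return best


@dataclass
class ScanParams:
    """Thresholds quantifying the three design criteria.

    "Close to 4 A" is the window [cb_min, cb_max] around target_cb; "high
    local fluctuation" is an RMSF threshold (default: 75th percentile of the
    supplied profile); "not close to the ice-binding site" is an any-atom
    distance cutoff from a user-supplied IBS residue list.
    """

    cb_min: float = 3.0
    cb_max: float = 5.0
    target_cb: float = 4.0
    min_seq_sep: int = 3
    rmsf_threshold: float | None = None  # None -> 75th percentile of profile
    ibs_residues: frozenset = field(default_factory=frozenset)
    ibs_cutoff: float = 8.0
    max_geometry_penalty: float = 10.0

    def __post_init__(self) -> None:
        if not (self.cb_min < self.target_cb < self.cb_max):
            raise ValueError("require cb_min < target_cb < cb_max")
        if self.min_seq_sep < 1:
            raise ValueError("min_seq_sep must be >= 1")
        if self.ibs_cutoff <= 0 or self.cb_min <= 0:
            raise ValueError("cutoffs must be positive")
        self.ibs_residues = frozenset(self.ibs_residues)


def _format_rid(rid: ResidueId) -> str:
    return f"{rid[0]}:{rid[1]}{rid[2]}"


@dataclass
class DisulfideCandidate:
    pair: tuple[ResidueId, ResidueId]
    cb_distance: float
    flex_score: float  # mean RMSF of the two residues, Angstrom
    geometry_penalty: float
    near_ibs: bool
    rank_score: float

    def to_dict(self) -> dict:
        return {
            "residue_a": _format_rid(self.pair[0]),
            "residue_b": _format_rid(self.pair[1]),
            "cb_distance_A": self.cb_distance,
            "flex_score_A": self.flex_score,
            "geometry_penalty": self.geometry_penalty,
            "near_ibs": self.near_ibs,
            "rank_score": self.rank_score,
        }


def _min_any_atom_distance(structure: Structure, rid: ResidueId, other_coords: np.ndarray) -> float:
    idx = structure.residues[rid]
    coords = np.array([structure.atoms[i].xyz for i in idx])
    d = np.linalg.norm(coords[:, None, :] - other_coords[None, :, :], axis=2)
    return float(d.min())


def scan_candidates(
    structure: Structure,
    profile: FlexibilityProfile,
    params: ScanParams | None = None,
) -> list[DisulfideCandidate]:
    """Enumerate and rank disulfide candidates under the three design criteria.

    A pair is accepted when sequence separation >= min_seq_sep, Cb distance in
    [cb_min, cb_max], at least one residue has rmsf >= rmsf_threshold, neither
    residue lies within ibs_cutoff (any-atom) of an IBS residue, and the
    geometry penalty is <= max_geometry_penalty. Ranking:
    flex / (1 + penalty + |d - target|), ties to lower penalty then residue ids.
    """
    if params is None:
        params = ScanParams()
    if len(profile.residue_ids) == 0:
        raise ValueError("empty flexibility profile")
    rmsf_by_res = dict(zip(profile.residue_ids, profile.rmsf))
    threshold = (
        params.rmsf_threshold
        if params.rmsf_threshold is not None
        else float(np.percentile(profile.rmsf, 75))
    )

    residues = []
    for rid in structure.residue_ids():
        if rid not in rmsf_by_res:
            warnings.warn(f"residue {rid} missing from profile; excluded", stacklevel=2)
            continue
        try:
            _backbone(structure, rid)
        except ValueError:
            warnings.warn(f"residue {rid} missing backbone atoms; excluded", stacklevel=2)
            continue
        residues.append(rid)

    ibs_coords = None
    if params.ibs_residues:
        pts = []
        for rid in params.ibs_residues:
            for i in structure.residues.get(rid, []):
                pts.append(structure.atoms[i].xyz)
        if pts:
            ibs_coords = np.asarray(pts)

    near_ibs_cache: dict[ResidueId, bool] = {}

    def near_ibs(rid: ResidueId) -> bool:
        if ibs_coords is None:
            return False
        if rid not in near_ibs_cache:
            near_ibs_cache[rid] = (
                _min_any_atom_distance(structure, rid, ibs_coords) < params.ibs_cutoff
            )
        return near_ibs_cache[rid]

    out: list[DisulfideCandidate] = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            a, b = residues[i], residues[j]
            if a[0] == b[0] and abs(a[1] - b[1]) < params.min_seq_sep:
                continue
            d = cb_distance(structure, a, b)
            if not (params.cb_min <= d <= params.cb_max):
                continue
            flex_a, flex_b = rmsf_by_res[a], rmsf_by_res[b]
            if max(flex_a, flex_b) < threshold:
                continue
            if near_ibs(a) or near_ibs(b):
                continue
            penalty = geometry_penalty(structure, a, b)
            if penalty > params.max_geometry_penalty:
                continue
            flex = float((flex_a + flex_b) / 2.0)
            rank = flex / (1.0 + penalty + abs(d - params.target_cb))
            out.append(
                DisulfideCandidate(
                    pair=(a, b),
                    cb_distance=d,
                    flex_score=flex,
                    geometry_penalty=penalty,
                    near_ibs=False,
                    rank_score=rank,
                )
            )
    out.sort(key=lambda c: (-c.rank_score, c.geometry_penalty, c.pair))
    return out


def candidates_to_frame(candidates: list[DisulfideCandidate]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in candidates])


def candidates_to_tsv(candidates: list[DisulfideCandidate], path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def candidates_to_json(candidates: list[DisulfideCandidate], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in candidates], fh, indent=2, sort_keys=True)
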