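"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
quaternion (Horn) superposition RMSD, rotamer-grid disulfide screening via
explicit axis-angle rotations, a plain brute-force candidate filter, and
all-pairs Feret diameters.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD by Horn's quaternion eigenvalue method."""
    x = np.asarray(mobile, float)
    y = np.asarray(reference, float)
    n = len(x)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    m = xc.T @ yc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    g = (xc**2).sum() + (yc**2).sum()
    return float(np.sqrt(max(0.0, (g - 2.0 * lam) / n)))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = _unit(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    ax = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return c * np.eye(3) + s * ax + (1 - c) * np.outer(a, a)


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(
        np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))
    )


def sg_positions(n: np.ndarray, ca: np.ndarray, cb: np.ndarray,
                 chi1_deg: np.ndarray,
                 bond: float = 1.81, angle_deg: float = 114.0) -> np.ndarray:
    """Sg positions over chi1 values via explicit axis-angle rotation about
    the CA-CB axis (self-calibrating sign convention)."""
    axis = _unit(cb - ca)
    # perpendicular reference direction: N projected off the axis (chi1 = 0
    # eclipses N)
    ref = (n - ca) - np.dot(n - ca, axis) * axis
    ref = _unit(ref)
    theta = np.deg2rad(angle_deg)
    # angle at CB between CB->CA (-axis) and CB->SG is theta
    base = cb + bond * (np.cos(np.pi - theta) * axis + np.sin(np.pi - theta) * ref)
    # calibrate rotation sign against the dihedral convention
    probe = _axis_rotation(axis, np.deg2rad(30.0)) @ (base - cb) + cb
    sign = 1.0 if abs(_dihedral(n, ca, cb, probe) - 30.0) < 1.0 else -1.0
    out = np.empty((len(chi1_deg), 3))
    for i, chi in enumerate(np.asarray(chi1_deg, float)):
        rot = _axis_rotation(axis, sign * np.deg2rad(chi))
        out[i] = rot @ (base - cb) + cb
    return out


def penalty_grid_oracle(structure, res_a, res_b, step: float = 1.0) -> float:
    """Exhaustive chi1 x chi1 grid minimum of the disulfide screening score,
    computed with the oracle's own Sg placement and dihedral code."""
    from cryostab.disulfide import virtual_cbeta

    def frame(rid):
        n = structure.atom(rid, "N").xyz
        ca = structure.atom(rid, "CA").xyz
        cb = virtual_cbeta(structure, rid)
        return n, ca, cb

    na, caa, cba = frame(res_a)
    nb, cab, cbb = frame(res_b)
    chis = np.arange(0.0, 360.0, step)
    sga = sg_positions(na, caa, cba, chis)
    sgb = sg_positions(nb, cab, cbb, chis)

    diff = sgb[None, :, :] - sga[:, None, :]
    dss = np.linalg.norm(diff, axis=2)
    b1 = diff / dss[:, :, None]
    b0 = (sga - cba)[:, None, :]
    b2 = (cbb - sgb)[None, :, :]
    v = b0 - np.sum(b0 * b1, axis=2, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=2, keepdims=True) * b1
    chi3 = np.degrees(
        np.arctan2(np.sum(np.cross(b1, v) * w, axis=2), np.sum(v * w, axis=2))
    )
    dev = np.minimum(np.abs(chi3 - 87.0), np.abs(chi3 + 87.0))
    pen = (dss - 2.05) ** 2 + (dev / 30.0) ** 2
    return float(pen.min())


def scan_bruteforce(structure, profile, params):
    """Independently coded all-pairs candidate filter and ranking."""
    from cryostab.disulfide import cb_distance, geometry_penalty

    rmsf = dict(zip(profile.residue_ids, profile.rmsf))
    thr = (
        params.rmsf_threshold
        if params.rmsf_threshold is not None
        else float(np.percentile(profile.rmsf, 75))
    )
    rids = [
        r
        for r in structure.residue_ids()
        if r in rmsf
        and all(structure.has_atom(r, nm) for nm in ("N", "CA", "C"))
    ]

    ibs_pts = []
    for rid in params.ibs_residues:
        for i in structure.residues.get(rid, []):
            ibs_pts.append(structure.atoms[i].xyz)
    ibs_pts = np.asarray(ibs_pts) if ibs_pts else None

    def near_ibs(rid):
        if ibs_pts is None:
            return False
        pts = np.array([structure.atoms[i].xyz for i in structure.residues[rid]])
        return np.min(
            np.linalg.norm(pts[:, None, :] - ibs_pts[None, :, :], axis=2)
        ) < params.ibs_cutoff

    accepted = []
    for x in range(len(rids)):
        for y in range(x + 1, len(rids)):
            a, b = rids[x], rids[y]
            if a[0] == b[0] and abs(a[1] - b[1]) < params.min_seq_sep:
                continue
            d = cb_distance(structure, a, b)
            if d < params.cb_min or d > params.cb_max:
                continue
            if rmsf[a] < thr and rmsf[b] < thr:
                continue
            if near_ibs(a) or near_ibs(b):
                continue
            pen = geometry_penalty(structure, a, b)
            if pen > params.max_geometry_penalty:
                continue
            flex = 0.5 * (rmsf[a] + rmsf[b])
            score = flex / (1.0 + pen + abs(d - params.target_cb))
            accepted.append((a, b, d, flex, pen, score))
    accepted.sort(key=lambda t: (-t[5], t[4], (t[0], t[1])))
    return accepted


def feret_bruteforce(coords: np.ndarray) -> float:
    """All-pairs max distance over every pixel of a region (exact on ints)."""
    coords = np.asarray(coords)
    if len(coords) == 1:
        return 0.0
    best = 0
    pts = coords.astype(np.int64)
    for i in range(len(pts) - 1):
        d = pts[i + 1 :] - pts[i]
        best = max(best, int(np.max(d[:, 0] ** 2 + d[:, 1] ** 2)))
    return float(np.sqrt(best))
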