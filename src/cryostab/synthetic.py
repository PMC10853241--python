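"""Seeded generators emulating each pipeline stage's data-generating process.

Every generator is a pure function of its parameters and an integer seed and
produces output the corresponding analysis module accepts at default settings:

* toy poly-alanine scaffolds with an optionally planted ideal disulfide pair,
* harmonic (Gaussian) positional fluctuation about a reference structure with
  per-frame global rigid motion, standing in for an MD trajectory,
* two-state fluorescence-ratio melt curves over the 35-95 degC ramp,
* CD spectral series as noisy simplex mixtures of the packaged basis on the
  20-90 degC / 2 degC grid,
* splat-cooling micrographs as Voronoi grain mosaics with per-grain ground
  truth (rasterized max Feret diameter and border flags).

These emulate the statistics each estimator assumes (stationary positional
noise, two-state equilibrium, linear mixing, bright-grain/dark-boundary
mosaics) — not MD physics, photophysics, or polarized-light optics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cd_deconv import BasisSet, CDSpectrum, reference_basis
from .disulfide import CB_BOND, SG_ANGLE, SG_BOND, SS_BOND, place_atom, virtual_cbeta
from .iri_quant import GrainImage, max_feret
from .melt import KELVIN, MeltCurve, R_KJ, two_state_ratio
from .structmodel import Atom, Ensemble, Structure

__all__ = [
    "synth_toy_structure",
    "synth_trajectory",
    "synth_melt_curve",
    "synth_cd_series",
    "two_state_schedule",
    "synth_splat_image",
]


def _rotation_from_rng(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _ideal_residue() -> dict[str, np.ndarray]:
    """One alanine-like residue in a canonical local frame (CA at origin)."""
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    ang = np.deg2rad(111.0)
    c = 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    o = place_atom(n, ca, c, 1.23, 121.0, 180.0)
    # idealized CB from the backbone frame (same construction as the scanner)
    tmp = Structure(
        [
            Atom(1, "N", "", "ALA", "A", 1, "", n),
            Atom(2, "CA", "", "ALA", "A", 1, "", ca),
            Atom(3, "C", "", "ALA", "A", 1, "", c),
        ]
    )
    cb = virtual_cbeta(tmp, ("A", 1, ""))
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def _ideal_disulfide_pair() -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Two residues posed with exact ideal disulfide geometry and Cb-Cb = 4.0 A.

    Sg-Sg = 2.05 A, chi3 = +87 deg, CA-CB-SG = 114 deg on both sides; the two
    CB-SG-SG angles are tuned symmetrically so the Cb separation is exactly
    4.0 A (they land in the natural ~100-115 deg range).
    """
    res_a = _ideal_residue()

    def build(theta: float):
        sg_a = place_atom(res_a["N"], res_a["CA"], res_a["CB"], SG_BOND, SG_ANGLE, -60.0)
        sg_b = place_atom(res_a["CA"], res_a["CB"], sg_a, SS_BOND, theta, -80.0)
        cb_b = place_atom(res_a["CB"], sg_a, sg_b, SG_BOND, theta, 87.0)
        return sg_a, sg_b, cb_b

    def cb_gap(theta: float) -> float:
        _, _, cb_b = build(theta)
        return float(np.linalg.norm(cb_b - res_a["CB"])) - 4.0

    theta = brentq(cb_gap, 95.0, 120.0, xtol=1e-10)
    sg_a, sg_b, cb_b = build(theta)
    ca_b = place_atom(sg_a, sg_b, cb_b, CB_BOND, SG_ANGLE, -60.0)
    n_b = place_atom(sg_b, cb_b, ca_b, 1.458, 110.5, 60.0)
    c_b = place_atom(sg_b, cb_b, ca_b, 1.525, 110.1, 60.0 + 122.6)
    o_b = place_atom(n_b, ca_b, c_b, 1.23, 121.0, 180.0)
    res_b = {"N": n_b, "CA": ca_b, "C": c_b, "O": o_b, "CB": cb_b}
    return res_a, res_b


_ATOM_ORDER = ("N", "CA", "C", "O", "CB")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def synth_toy_structure(
    n_residues: int = 10,
    planted_pair: tuple[int, int] | None = None,
    seed: int = 0,
    spacing: float = 6.5,
    radius: float | None = None,
) -> Structure:
    """Poly-alanine scaffold on a circular arc, optionally with one planted
    disulfide-compatible pair.

    Residues are rigid idealized units spaced ``spacing`` A apart along an arc
    of the given radius, side chains pointing outward, with a small seeded
    orientation jitter. If ``planted_pair`` (1-based residue numbers) is
    given, those two residues are re-posed as an exact ideal disulfide pair
    (Cb-Cb = 4.0 A) lifted above the arc plane; every other residue pair ends
    up with a Cb distance outside the [3, 5] A scan window (verified, else a
    planting error is raised).
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if planted_pair is not None:
        i, j = planted_pair
        if not (1 <= i <= n_residues and 1 <= j <= n_residues) or i == j:
            raise ValueError(f"planted pair {planted_pair} not plantable in {n_residues} residues")
    if radius is None:
        # keep the arc from wrapping onto itself for long chains
        radius = max(40.0, 1.5 * spacing * n_residues / (2.0 * np.pi))
    rng = np.random.default_rng(seed)
    template = _ideal_residue()

    poses: list[dict[str, np.ndarray]] = []
    arc_step = spacing / radius
    for k in range(n_residues):
        angle = k * arc_step
        center = radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        # outward-facing local frame with a small seeded twist about the radial axis
        radial = np.array([np.cos(angle), np.sin(angle), 0.0])
        tangent = np.array([-np.sin(angle), np.cos(angle), 0.0])
        normal = np.array([0.0, 0.0, 1.0])
        frame = np.column_stack([radial, tangent, normal])
        twist = np.deg2rad(rng.uniform(-10.0, 10.0))
        ct, st = np.cos(twist), np.sin(twist)
        twist_mat = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]])
        rot = frame @ twist_mat
        poses.append({name: rot @ xyz + center for name, xyz in template.items()})

    if planted_pair is not None:
        res_a, res_b = _ideal_disulfide_pair()
        pair_center = 0.5 * (res_a["CA"] + res_b["CA"])
        target = np.array([radius, 0.0, 12.0])  # lifted well above the arc plane
        i, j = planted_pair
        poses[i - 1] = {k: v - pair_center + target for k, v in res_a.items()}
        poses[j - 1] = {k: v - pair_center + target for k, v in res_b.items()}

    atoms: list[Atom] = []
    serial = 1
    for k, pose in enumerate(poses, start=1):
        for name in _ATOM_ORDER:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    altloc="",
                    resname="ALA",
                    chain="A",
                    resseq=k,
                    icode="",
                    xyz=np.round(pose[name], 3),  # PDB precision by construction
                    occupancy=1.0,
                    bfactor=0.0,
                    element=_ELEMENTS[name],
                )
            )
            serial += 1
    structure = Structure(atoms, metadata=f"synthetic toy scaffold seed={seed}")

    # verify the planting contract
    cbs = {
        rid: virtual_cbeta(structure, rid) for rid in structure.residue_ids()
    }
    rids = list(cbs)
    planted = (
        {("A", planted_pair[0], ""), ("A", planted_pair[1], "")}
        if planted_pair is not None
        else set()
    )
    for a in range(len(rids)):
        for b in range(a + 1, len(rids)):
            d = float(np.linalg.norm(cbs[rids[a]] - cbs[rids[b]]))
            if {rids[a], rids[b]} == planted:
                if not (3.95 <= d <= 4.05):
                    raise ValueError(f"planting failed: planted Cb distance {d:.3f} A")
            elif 3.0 <= d <= 5.0:
                raise ValueError(
                    f"planting infeasible: stray pair {rids[a]}-{rids[b]} at {d:.2f} A"
                )
    return structure


def synth_trajectory(
    structure: Structure,
    amplitudes,
    n_frames: int,
    seed: int = 0,
    rigid_motion: bool = True,
) -> Ensemble:
    """Ensemble of frames: reference + per-atom isotropic Gaussian displacement
    (per-coordinate sigma set by each atom's residue) + a random global rigid
    motion per frame to exercise superposition.

    ``amplitudes``: scalar sigma (A), mapping residue-id -> sigma, or a
    sequence over the roster's residues in order.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rids = structure.residue_ids()
    if np.isscalar(amplitudes):
        sigma_by_res = {rid: float(amplitudes) for rid in rids}
    elif isinstance(amplitudes, dict):
        sigma_by_res = {rid: float(amplitudes[rid]) for rid in rids}
    else:
        amplitudes = list(amplitudes)
        if len(amplitudes) != len(rids):
            raise ValueError("amplitudes must cover every residue")
        sigma_by_res = {rid: float(a) for rid, a in zip(rids, amplitudes)}
    if any(s < 0 for s in sigma_by_res.values()):
        raise ValueError("amplitudes must be non-negative")

    sigma_per_atom = np.zeros(len(structure))
    for rid, idx in structure.residues.items():
        for i in idx:
            sigma_per_atom[i] = sigma_by_res[rid]

    rng = np.random.default_rng(seed)
    ref = structure.coords()
    frames = np.empty((n_frames, len(structure), 3))
    for f in range(n_frames):
        disp = rng.normal(size=ref.shape) * sigma_per_atom[:, None]
        coords = ref + disp
        if rigid_motion:
            rot = _rotation_from_rng(rng)
            trans = rng.normal(scale=5.0, size=3)
            coords = coords @ rot.T + trans
        frames[f] = coords
    return Ensemble(structure, frames)


def synth_melt_curve(
    tm: float,
    dH: float,
    baselines: tuple[float, float, float, float] = (0.85, 0.0002, 1.05, 0.0005),
    noise_sd: float = 0.0,
    grid: tuple[float, float, float] = (35.0, 95.0, 0.5),
    seed: int = 0,
    sample: str = "synthetic",
    condition: str = "",
) -> MeltCurve:
    """Two-state fluorescence-ratio melt curve with i.i.d. Gaussian noise.

    ``baselines`` = (folded intercept, folded slope, unfolded intercept,
    unfolded slope). Default ramp 35-95 degC at 0.5 degC steps.
    """
    lo, hi, step = grid
    if not (lo < tm < hi):
        raise ValueError(f"tm={tm} outside the scan grid ({lo}, {hi})")
    if dH <= 0:
        raise ValueError("dH must be positive")
    t = np.arange(lo, hi + step / 2, step)
    ratio = two_state_ratio(t, tm, dH, *baselines)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio + rng.normal(scale=noise_sd, size=t.shape)
    return MeltCurve(t, ratio, sample=sample, condition=condition)


def two_state_schedule(
    temperatures: np.ndarray,
    tm: float,
    dH: float,
    folded: tuple[float, float, float, float] = (0.62, 0.20, 0.08, 0.10),
    unfolded: tuple[float, float, float, float] = (0.04, 0.10, 0.14, 0.72),
) -> np.ndarray:
    """Secondary-structure fraction schedule for a two-state unfolding: each
    row interpolates between ``folded`` and ``unfolded`` compositions with the
    van 't Hoff folded fraction at that temperature."""
    t = np.asarray(temperatures, dtype=float)
    k = np.exp(-(dH / R_KJ) * (1.0 / (t + KELVIN) - 1.0 / (tm + KELVIN)))
    frac_folded = 1.0 / (1.0 + k)
    folded = np.asarray(folded, dtype=float)
    unfolded = np.asarray(unfolded, dtype=float)
    return frac_folded[:, None] * folded[None, :] + (1 - frac_folded)[:, None] * unfolded[None, :]


def synth_cd_series(
    schedule: np.ndarray,
    temperatures: np.ndarray | None = None,
    basis: BasisSet | None = None,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> list[CDSpectrum]:
    """CD spectra as simplex mixtures of the basis plus Gaussian noise.

    ``schedule`` is an (n_temps, 4) fraction table (rows on the simplex);
    ``temperatures`` defaults to the 20-90 degC / 2 degC ramp. Noise SD is
    ``noise_frac`` x max |basis|.
    """
    if basis is None:
        basis = reference_basis()
    schedule = np.atleast_2d(np.asarray(schedule, dtype=float))
    if temperatures is None:
        temperatures = np.arange(20.0, 90.0 + 1.0, 2.0)[: len(schedule)]
    temperatures = np.asarray(temperatures, dtype=float)
    if len(temperatures) != len(schedule):
        raise ValueError("temperatures and schedule lengths differ")
    if schedule.shape[1] != len(basis.names):
        raise ValueError("schedule rows must have one fraction per basis component")
    if np.any(schedule < -1e-9) or np.any(np.abs(schedule.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("every schedule row must lie on the simplex")
    rng = np.random.default_rng(seed)
    scale = noise_frac * float(np.max(np.abs(basis.spectra)))
    out = []
    for t, row in zip(temperatures, schedule):
        spec = row @ basis.spectra
        if scale > 0:
            spec = spec + rng.normal(scale=scale, size=spec.shape)
        out.append(CDSpectrum(basis.wavelength.copy(), spec, float(t)))
    return out


def synth_splat_image(
    n_seeds: int,
    size: tuple[int, int] = (512, 512),
    mean_grain_um: float | None = None,
    pixel_size: float = 1.0,
    boundary_px: int = 2,
    seed: int = 0,
    label: str = "synthetic splat",
) -> tuple[GrainImage, pd.DataFrame]:
    """Voronoi grain mosaic: bright per-grain-constant interiors (0.7-1.0),
    dark boundary channels (~``boundary_px`` wide, intensity 0.05).

    If ``mean_grain_um`` is given the pixel size is derived so the mean
    equivalent grain diameter equals it. Returns the image and a ground-truth
    table with, per grain: seed position, interior pixel count, rasterized
    max Feret diameter (um), and whether the grain touches the image border.
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seed points")
    if boundary_px < 1:
        raise ValueError("boundary_px must be >= 1")
    h, w = size
    if mean_grain_um is not None:
        mean_diam_px = float(np.sqrt(4.0 * h * w / (np.pi * n_seeds)))
        pixel_size = mean_grain_um / mean_diam_px
    rng = np.random.default_rng(seed)

    min_sep = 4.0 * boundary_px + 6.0
    pts: list[np.ndarray] = []
    for _ in range(20000):
        cand = rng.uniform([0, 0], [h, w])
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
            if len(pts) == n_seeds:
                break
    if len(pts) < n_seeds:
        raise ValueError(
            f"cannot place {n_seeds} seeds at separation {min_sep:.0f}px in {h}x{w}: "
            "seeds too dense for the boundary width"
        )
    seeds = np.array(pts)

    rows, cols = np.mgrid[0:h, 0:w]
    grid = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    # distances to all seeds, chunked to bound memory
    nearest = np.empty(h * w, dtype=int)
    d1 = np.empty(h * w)
    d2 = np.empty(h * w)
    chunk = 65536
    for start in range(0, h * w, chunk):
        block = grid[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - seeds[None, :, :], axis=2)
        nearest[start : start + chunk] = np.argmin(d, axis=1)
        part = np.partition(d, 1, axis=1)
        d1[start : start + chunk] = part[:, 0]
        d2[start : start + chunk] = part[:, 1]
    cell = nearest.reshape(h, w)
    boundary = (d2 - d1).reshape(h, w) <= boundary_px

    brightness = rng.uniform(0.7, 1.0, size=n_seeds)
    img = brightness[cell]
    img[boundary] = 0.05
    # quantize exactly as an 8-bit file would store it
    img = np.round(img * 255.0) / 255.0

    records = []
    for g in range(n_seeds):
        interior = np.argwhere((cell == g) & ~boundary)
        if len(interior) == 0:
            raise ValueError("a grain has no interior pixels: seeds too dense")
        touches = bool(
            (interior[:, 0].min() == 0)
            or (interior[:, 0].max() == h - 1)
            or (interior[:, 1].min() == 0)
            or (interior[:, 1].max() == w - 1)
        )
        records.append(
            {
                "grain": g + 1,
                "seed_row": seeds[g, 0],
                "seed_col": seeds[g, 1],
                "n_pixels": int(len(interior)),
                "feret_um": max_feret(interior, method="brute" if len(interior) < 200 else "auto")
                * pixel_size,
                "border": touches,
            }
        )
    truth = pd.DataFrame.from_records(records)
    return GrainImage(img, pixel_size, label=label), truth
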