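"""Rigid-body superposition and per-residue flexibility (RMSF) profiling.

An ensemble of frames is iteratively superposed onto its mean structure, the
root-mean-square fluctuation of each atom about its mean position is computed,
and atoms are reduced to a per-residue profile. Contiguous runs of residues
above a threshold are reported as flexible regions — the kind of profile used
to pick mutation sites in loop/capping regions of an ice-binding protein.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .structmodel import BACKBONE_NAMES, Ensemble, ResidueId, select

__all__ = [
    "SuperpositionResult",
    "FlexibilityProfile",
    "FlexibleRegion",
    "GeometryError",
    "kabsch_superpose",
    "apply_transform",
    "rmsf_profile",
    "flexible_regions",
    "region_mean",
]


class GeometryError(ValueError):
    """Degenerate point configuration (too few or rank-deficient points)."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,), Angstrom
    rmsd: float  # Angstrom over the fitted selection


@dataclass
class FlexibilityProfile:
    residue_ids: list[ResidueId]
    rmsf: np.ndarray  # Angstrom, one value per residue
    fit_selection: str = "CA"
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if len(self.residue_ids) != self.rmsf.shape[0]:
            raise ValueError("residue_ids and rmsf lengths differ")
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be non-negative")

    def value(self, residue: ResidueId) -> float:
        return float(self.rmsf[self.residue_ids.index(residue)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [r[0] for r in self.residue_ids],
                "resseq": [r[1] for r in self.residue_ids],
                "icode": [r[2] for r in self.residue_ids],
                "rmsf_A": self.rmsf,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FlexibilityProfile":
        df = pd.read_csv(path, sep="\t", dtype={"icode": str}, keep_default_na=False)
        ids = [
            (str(c), int(r), str(i) if i else "")
            for c, r, i in zip(df["chain"], df["resseq"], df["icode"])
        ]
        return cls(ids, df["rmsf_A"].to_numpy(dtype=float))


@dataclass
class FlexibleRegion:
    start: ResidueId
    end: ResidueId
    mean_rmsf: float
    peak_rmsf: float

    def to_dict(self) -> dict:
        return asdict(self)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimising the (weighted)
    RMSD of ``mobile @ R.T + t`` against ``reference``. Reflections are
    corrected by flipping the sign of the smallest singular vector.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("mobile and reference must both be (n, 3) with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    # rank of the weighted point cloud: collinear sets cannot fix a rotation
    if np.linalg.matrix_rank(mob_c, tol=1e-9) < 2:
        raise GeometryError("degenerate (collinear) point configuration")

    cov = mob_c.T @ (w[:, None] * ref_c)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    rotation = Vt.T @ D @ U.T
    translation = (w[:, None] * reference).sum(axis=0) - rotation @ (
        (w[:, None] * mobile).sum(axis=0)
    )
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def _superpose_frames(frames: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    """Iteratively superpose every frame onto the evolving mean structure."""
    aligned = frames.copy()
    # initial reference: first frame
    for f in range(aligned.shape[0]):
        res = kabsch_superpose(aligned[f, fit_idx], aligned[0, fit_idx])
        aligned[f] = apply_transform(aligned[f], res)
    mean = aligned.mean(axis=0)
    for _ in range(10):
        for f in range(aligned.shape[0]):
            res = kabsch_superpose(aligned[f, fit_idx], mean[fit_idx])
            aligned[f] = apply_transform(aligned[f], res)
        new_mean = aligned.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < 1e-6:
            break
    return aligned


_PROFILE_SELECTIONS = {
    "CA": lambda a: a.name == "CA",
    "backbone": lambda a: a.name in BACKBONE_NAMES,
    "heavy": lambda a: a.element != "H" and not a.name.startswith("H"),
}


def rmsf_profile(
    ensemble: Ensemble,
    fit_selection: list[int] | None = None,
    profile_selection: str = "CA",
) -> FlexibilityProfile:
    """Per-residue RMSF (A) of an ensemble after iterative mean-structure fit.

    ``fit_selection`` is a roster atom-index list (default: all CA atoms);
    ``profile_selection`` chooses which atoms are averaged into each residue's
    value: "CA", "backbone" (N/CA/C/O) or "heavy".
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if profile_selection not in _PROFILE_SELECTIONS:
        raise ValueError(f"unknown profile_selection {profile_selection!r}")
    roster = ensemble.roster
    if fit_selection is None:
        fit_selection = select(roster, atom_names={"CA"})
    fit_idx = np.asarray(fit_selection, dtype=int)
    if fit_idx.size < 3:
        raise GeometryError("fit selection must contain at least 3 atoms")

    if np.all(ensemble.frames == ensemble.frames[0]):
        # a static ensemble has exactly zero fluctuation by definition; skip
        # the fit so SVD roundoff cannot manufacture ~1e-14 A of it
        per_atom = np.zeros(ensemble.frames.shape[1])
    else:
        aligned = _superpose_frames(ensemble.frames, fit_idx)
        mean = aligned.mean(axis=0)
        per_atom = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))

    keep = _PROFILE_SELECTIONS[profile_selection]
    ids: list[ResidueId] = []
    values: list[float] = []
    for rid, atom_indices in roster.residues.items():
        sel = [i for i in atom_indices if keep(roster.atoms[i])]
        if not sel:
            warnings.warn(
                f"residue {rid} has no {profile_selection} atoms; omitted from profile",
                stacklevel=2,
            )
            continue
        ids.append(rid)
        values.append(float(per_atom[sel].mean()))
    return FlexibilityProfile(
        ids,
        np.array(values),
        fit_selection=f"{len(fit_idx)} atoms",
        n_frames=ensemble.n_frames,
    )


def flexible_regions(
    profile: FlexibilityProfile,
    threshold: float,
    min_length: int = 1,
) -> list[FlexibleRegion]:
    """Maximal runs of consecutive residues with rmsf >= threshold and length
    >= min_length, in sequence order."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    regions: list[FlexibleRegion] = []
    run_start: int | None = None
    hot = profile.rmsf >= threshold
    for i in range(len(profile.residue_ids) + 1):
        if i < len(profile.residue_ids) and hot[i]:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            length = i - run_start
            if length >= min_length:
                chunk = profile.rmsf[run_start:i]
                regions.append(
                    FlexibleRegion(
                        start=profile.residue_ids[run_start],
                        end=profile.residue_ids[i - 1],
                        mean_rmsf=float(chunk.mean()),
                        peak_rmsf=float(chunk.max()),
                    )
                )
            run_start = None
    return regions


def region_mean(profile: FlexibilityProfile, residue_range: tuple[int, int]) -> float:
    """Arithmetic mean RMSF over author residue numbers in the inclusive range."""
    lo, hi = residue_range
    mask = np.array([lo <= rid[1] <= hi for rid in profile.residue_ids])
    if not mask.any():
        raise ValueError(f"residue range {residue_range} does not overlap the profile")
    return float(profile.rmsf[mask].mean())


def regions_to_json(regions: list[FlexibleRegion], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in regions], fh, indent=2, sort_keys=True)
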