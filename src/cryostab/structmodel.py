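"""Minimal coordinate layer: fixed-column PDB I/O, residue indexing, selection.

The rest of the package works on protein coordinates only; waters (HOH) are
dropped on read and non-protein heteroatoms are kept out of the residue index
unless explicitly requested. Multi-model files are treated as conformational
ensembles sharing one atom roster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "PDBParseError",
    "EnsembleError",
    "read_pdb",
    "write_pdb",
    "select",
    "ResidueId",
]

#: (chain, author residue number, insertion code or "")
ResidueId = tuple[str, int, str]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """A malformed fixed-width record; message names the offending line."""


class EnsembleError(ValueError):
    """Models in a multi-model file do not share one atom roster."""


@dataclass
class Atom:
    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    hetatm: bool = False

    def residue_id(self) -> ResidueId:
        return (self.chain, self.resseq, self.icode)


@dataclass
class Structure:
    """An ordered atom list plus a residue index keyed by (chain, resseq, icode)."""

    atoms: list[Atom]
    metadata: str = ""
    include_hetero: bool = False
    _residues: dict[ResidueId, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._residues = {}
        for i, atom in enumerate(self.atoms):
            if atom.hetatm and not self.include_hetero:
                continue
            self._residues.setdefault(atom.residue_id(), []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> dict[ResidueId, list[int]]:
        return self._residues

    def residue_ids(self) -> list[ResidueId]:
        return list(self._residues.keys())

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def atom(self, residue: ResidueId, name: str) -> Atom:
        for i in self._residues.get(residue, []):
            if self.atoms[i].name == name:
                return self.atoms[i]
        raise KeyError(f"residue {residue} has no atom {name!r}")

    def has_atom(self, residue: ResidueId, name: str) -> bool:
        try:
            self.atom(residue, name)
            return True
        except KeyError:
            return False


@dataclass
class Ensemble:
    """F >= 1 coordinate frames over the atom roster of frame 0."""

    roster: Structure
    frames: np.ndarray  # (F, n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise EnsembleError("frames must have shape (F, n_atoms, 3)")
        if self.frames.shape[1] != len(self.roster):
            raise EnsembleError(
                f"frames have {self.frames.shape[1]} atoms; roster has {len(self.roster)}"
            )
        if self.n_frames < 1:
            raise EnsembleError("an ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)


def _parse_atom_line(line: str, lineno: int) -> Atom:
    # PDB v3.3 fixed columns (0-based slices).
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    occ_field = line[54:60].strip()
    bf_field = line[60:66].strip()
    try:
        occupancy = float(occ_field) if occ_field else 1.0
        bfactor = float(bf_field) if bf_field else 0.0
    except ValueError as exc:
        raise PDBParseError(f"malformed occupancy/B-factor at line {lineno}: {exc}") from exc
    if not (0.0 <= occupancy <= 1.0):
        warnings.warn(
            f"occupancy {occupancy} out of [0, 1] at line {lineno}; clamping", stacklevel=3
        )
        occupancy = min(max(occupancy, 0.0), 1.0)
    xyz = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise PDBParseError(f"non-finite coordinates at line {lineno}")
    element = line[76:78].strip() if len(line) >= 78 else ""
    return Atom(
        serial=serial,
        name=name,
        altloc=altloc,
        resname=resname,
        chain=chain,
        resseq=resseq,
        icode=icode,
        xyz=xyz,
        occupancy=occupancy,
        bfactor=bfactor,
        element=element,
        hetatm=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per (residue, name): highest occupancy, ties to the
    alphabetically first altloc."""
    best: dict[tuple[ResidueId, str], Atom] = {}
    order: list[tuple[ResidueId, str]] = []
    for atom in atoms:
        key = (atom.residue_id(), atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
            continue
        incumbent = best[key]
        if atom.occupancy > incumbent.occupancy or (
            atom.occupancy == incumbent.occupancy and atom.altloc < incumbent.altloc
        ):
            best[key] = atom
    return [best[key] for key in order]


def read_pdb(
    path,
    model_policy: str = "first",
    include_hetero: bool = False,
) -> Structure | Ensemble:
    """Read a PDB file.

    model_policy="first" returns a :class:`Structure` from the first model;
    "all" returns an :class:`Ensemble` whose frames are the MODEL blocks.
    Waters (HOH) are always dropped; other HETATM records are kept on the
    atom list but excluded from the residue index unless ``include_hetero``.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    models: list[list[Atom]] = []
    current: list[Atom] = []
    header_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                    current = []
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line.rstrip("\n"), lineno)
                if atom.hetatm and atom.resname == "HOH":
                    continue
                current.append(atom)
            elif rec.startswith(("HEADER", "TITLE ")):
                header_lines.append(line.rstrip())
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    models = [_resolve_altlocs(m) for m in models]
    metadata = "\n".join(header_lines)

    if model_policy == "first":
        return Structure(models[0], metadata=metadata, include_hetero=include_hetero)

    roster = Structure(models[0], metadata=metadata, include_hetero=include_hetero)
    n = len(roster)
    frames = np.empty((len(models), n, 3), dtype=float)
    for f, model in enumerate(models):
        if len(model) != n:
            raise EnsembleError(
                f"model {f + 1} has {len(model)} atoms; expected {n} (roster of model 1)"
            )
        for a, (ref, atom) in enumerate(zip(roster.atoms, model)):
            if (ref.name, ref.residue_id()) != (atom.name, atom.residue_id()):
                raise EnsembleError(
                    f"model {f + 1} atom {a + 1} ({atom.name}) does not match roster "
                    f"({ref.name})"
                )
            frames[f, a] = atom.xyz
    return Ensemble(roster, frames)


def write_pdb(structure: Structure, path) -> None:
    """Write fixed-column PDB; round-trips identities and coordinates to 1e-3 A."""
    if len(structure) == 0:
        raise ValueError("cannot write an empty structure")
    with open(path, "w") as fh:
        for i, atom in enumerate(structure.atoms, start=1):
            if atom.resseq > 9999 or atom.resseq < -999:
                raise ValueError(f"residue number {atom.resseq} does not fit PDB columns")
            if i > 99999:
                raise ValueError("more than 99999 atoms cannot be serialized")
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            record = "HETATM" if atom.hetatm else "ATOM  "
            fh.write(
                f"{record}{i:5d} {name:<4s}{atom.altloc or ' ':1s}{atom.resname:>3s} "
                f"{atom.chain or ' ':1s}{atom.resseq:4d}{atom.icode or ' ':1s}   "
                f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
                f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
                f"{atom.element:>2s}\n"
            )
        fh.write("END\n")


def write_ensemble_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a MODEL/ENDMDL multi-model PDB."""
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, atom in enumerate(ensemble.roster.atoms, start=1):
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                record = "HETATM" if atom.hetatm else "ATOM  "
                x, y, z = ensemble.frames[f, i - 1]
                fh.write(
                    f"{record}{i:5d} {name:<4s}{atom.altloc or ' ':1s}{atom.resname:>3s} "
                    f"{atom.chain or ' ':1s}{atom.resseq:4d}{atom.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def select(
    structure: Structure,
    chain: str | None = None,
    atom_names: Sequence[str] | set[str] | None = None,
    residue_range: tuple[int, int] | None = None,
) -> list[int]:
    """Return roster-order atom indices matching all given filters.

    ``residue_range`` is an inclusive (start, end) pair of author residue
    numbers. An empty selection is valid and returned as an empty list.
    """
    names = set(atom_names) if atom_names is not None else None
    out: list[int] = []
    for i, atom in enumerate(structure.atoms):
        if atom.hetatm and not structure.include_hetero:
            continue
        if chain is not None and atom.chain != chain:
            continue
        if names is not None and atom.name not in names:
            continue
        if residue_range is not None and not (
            residue_range[0] <= atom.resseq <= residue_range[1]
        ):
            continue
        out.append(i)
    return out
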