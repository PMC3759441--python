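"""Structures and conformational ensembles: PDB I/O, roles, scoring atom types.

Every downstream stage (scoring, PCA, pocket analysis) consumes the in-memory
representation defined here: an :class:`Ensemble` of :class:`Frame` objects
holding ordered :class:`AtomRecord` lists.  Multi-model PDB is the interchange
format; coordinates are Å with the fixed-width ``%8.3f`` PDB precision.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AtomTypingError,
    PDBParseError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "Role",
    "AtomRecord",
    "Frame",
    "Ensemble",
    "read_ensemble",
    "write_ensemble",
    "assign_atom_types",
    "assign_roles",
    "topology_hash",
]

#: Standard amino-acid residue names (3-letter), used for backbone selections.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "HID", "HIE", "HIP", "CYX",
}


class Role(str, Enum):
    """Scoring role of an atom within a complex."""

    RECEPTOR = "receptor"
    LIGAND = "ligand"
    COFACTOR = "cofactor"


@dataclass
class AtomRecord:
    """One atom of one frame.

    ``atom_type`` is the label consumed by the statistical potential; it is
    assigned by :func:`assign_atom_types`, never parsed from the file.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray
    role: Role | None = None
    atom_type: str | None = None
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValidationError(f"atom {self.serial}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.serial}: non-finite coordinates")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)

    def identity(self) -> tuple:
        """Topology identity: everything except coordinates and per-frame state."""
        return (
            self.serial,
            self.name,
            self.element,
            self.residue_name,
            self.residue_number,
            self.chain_id,
            self.is_hetatm,
        )


@dataclass
class Frame:
    """One snapshot: an ordered atom list at a given simulation time."""

    index: int
    time_ps: float
    atoms: list[AtomRecord]
    _serial_index: dict[int, int] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValidationError("frame index must be >= 0")
        if self.time_ps < 0:
            raise ValidationError("time_ps must be >= 0")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValidationError(f"frame {self.index}: duplicate atom serials")
        self._serial_index = {s: i for i, s in enumerate(serials)}

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """(N, 3) coordinate array, optionally restricted to atom indices."""
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([a.coords for a in atoms], dtype=float)

    def atom_by_serial(self, serial: int) -> AtomRecord:
        try:
            return self.atoms[self._serial_index[serial]]
        except KeyError:
            raise KeyError(f"no atom with serial {serial} in frame {self.index}") from None

    def with_coords(self, coords: np.ndarray) -> "Frame":
        """Copy of this frame with replaced coordinates (topology preserved)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValidationError("coordinate array shape mismatch")
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Frame(index=self.index, time_ps=self.time_ps, atoms=atoms)


def topology_hash(frame: Frame) -> str:
    """Opaque digest of the atom layout; invariant under coordinate changes."""
    h = hashlib.sha1()
    for atom in frame.atoms:
        h.update(repr(atom.identity()).encode())
    return h.hexdigest()


@dataclass
class Ensemble:
    """Ordered frames sharing one topology."""

    frames: list[Frame]
    topology_hash: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("ensemble must contain at least one frame")
        ref_hash = topology_hash(self.frames[0])
        for f in self.frames:
            if len(f) != len(self.frames[0]):
                raise TopologyError(
                    f"frame {f.index} has {len(f)} atoms, expected {len(self.frames[0])}"
                )
            if topology_hash(f) != ref_hash:
                raise TopologyError(f"frame {f.index} does not share the ensemble topology")
        times = [f.time_ps for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValidationError("time_ps must be strictly increasing with frame index")
        self.topology_hash = ref_hash

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames], dtype=float)


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------

_COORD_RECORDS = ("ATOM  ", "HETATM", "ATOM ")


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    # PDB v3.3 fixed columns (0-based slices).
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip()
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        bf_field = line[60:66].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        bfactor = float(bf_field) if bf_field else 0.0
        element = line[76:78].strip()
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record ({exc})", lineno) from None
    if not element:
        # Fall back on the atom name: leading alphabetic characters.
        letters = "".join(c for c in name.lstrip("0123456789") if c.isalpha()).upper()
        two = letters[:2]
        metals = {"FE", "ZN", "MG", "MN", "CU", "CO", "NI", "NA", "CL", "BR"}
        element = two if two in metals else letters[:1]
    return AtomRecord(
        serial=serial,
        name=name,
        element=element.upper() if len(element) > 1 else element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain_id=chain_id,
        coords=np.array([x, y, z]),
        altloc=altloc,
        occupancy=occupancy,
        bfactor=bfactor,
        is_hetatm=line.startswith("HETATM"),
    )


def read_ensemble(
    path,
    format: str = "multi_model_pdb",
    dt_ps: float = 1.0,
    t0_ps: float = 0.0,
) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    MODEL/ENDMDL blocks become frames in file order; a file without MODEL
    records yields a single-frame ensemble.  HETATM records are retained.
    Alternate locations other than "A"/blank are dropped.  Frame times are
    synthesized as ``t0_ps + index * dt_ps`` (PDB carries no time axis).
    """
    if format not in ("pdb", "multi_model_pdb"):
        raise ValueError(f"unsupported format: {format!r}")
    frames: list[Frame] = []
    current: list[AtomRecord] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                frames.append(_new_frame(len(frames), current, dt_ps, t0_ps))
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line.rstrip("\n"), lineno)
                if atom.altloc in ("", "A"):
                    current.append(atom)
    if current:
        if in_model:
            raise PDBParseError("MODEL record without matching ENDMDL")
        frames.append(_new_frame(len(frames), current, dt_ps, t0_ps))
    if not frames:
        raise PDBParseError("no ATOM/HETATM records found")
    return Ensemble(frames=frames)


def _new_frame(index: int, atoms: list[AtomRecord], dt_ps: float, t0_ps: float) -> Frame:
    return Frame(index=index, time_ps=t0_ps + index * dt_ps, atoms=list(atoms))


def _format_atom_name(name: str) -> str:
    # 1-3 character names start in column 14; 4-character names in column 13.
    return name if len(name) >= 4 else f" {name:<3}"


def _format_atom_line(atom: AtomRecord) -> str:
    rec = "HETATM" if atom.is_hetatm else "ATOM  "
    x, y, z = atom.coords
    for v in (x, y, z):
        if not -999.999 <= v <= 9999.999:
            raise ValidationError(f"atom {atom.serial}: coordinate {v} outside PDB range")
    element = atom.element[:2].rjust(2)
    return (
        f"{rec}{atom.serial:>5d} {_format_atom_name(atom.name):<4s}{atom.altloc:1.1s}"
        f"{atom.residue_name:>3.3s} {atom.chain_id:1.1s}{atom.residue_number:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
        f"          {element}"
    )


def format_ensemble(ensemble: Ensemble) -> str:
    """Render an ensemble as multi-model PDB text."""
    lines: list[str] = []
    multi = len(ensemble) > 1
    for frame in ensemble:
        if multi:
            lines.append(f"MODEL {frame.index + 1:>8d}")
        lines.extend(_format_atom_line(a) for a in frame.atoms)
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write a multi-model PDB; round-trips coordinates to 1e-3 Å."""
    text = format_ensemble(ensemble)
    with open(path, "w") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# Roles and scoring atom types
# ---------------------------------------------------------------------------


def assign_roles(
    ensemble_or_frame,
    ligand_resnames: Iterable[str],
    cofactor_resnames: Iterable[str] = (),
) -> None:
    """Assign receptor/ligand/cofactor roles in place, by residue name.

    The ligand and cofactor are fixed identities of the system under study,
    so a residue-name rule is sufficient and deterministic.
    """
    ligand = {r.upper() for r in ligand_resnames}
    cofactor = {r.upper() for r in cofactor_resnames}
    frames = ensemble_or_frame.frames if isinstance(ensemble_or_frame, Ensemble) else [ensemble_or_frame]
    for frame in frames:
        for atom in frame.atoms:
            rn = atom.residue_name.upper()
            if rn in ligand:
                atom.role = Role.LIGAND
            elif rn in cofactor:
                atom.role = Role.COFACTOR
            else:
                atom.role = Role.RECEPTOR


_COVALENT_CUTOFF = 1.8  # heavy-atom bond heuristic, Å
_DOUBLE_BOND_CO = 1.30  # C=O carbonyl distance heuristic, Å


def _neighbor_indices(frame: Frame, i: int, cutoff: float) -> list[int]:
    xi = frame.atoms[i].coords
    out = []
    for j, atom in enumerate(frame.atoms):
        if j == i or atom.element == "H":
            continue
        if 0.0 < float(np.linalg.norm(atom.coords - xi)) <= cutoff:
            out.append(j)
    return out


def _context_type(frame: Frame, i: int) -> str:
    """Element plus a carbonyl/aromatic/sp3 flag from covalent-distance neighbors."""
    atom = frame.atoms[i]
    el = atom.element.upper()
    if el not in ("C", "N", "O"):
        return el
    neighbors = _neighbor_indices(frame, i, _COVALENT_CUTOFF)
    if el == "O":
        for j in neighbors:
            nb = frame.atoms[j]
            if nb.element.upper() != "C":
                continue
            # carbonyl: bonded C carries a second O/N neighbor
            for k in _neighbor_indices(frame, j, _COVALENT_CUTOFF):
                if k != i and frame.atoms[k].element.upper() in ("O", "N"):
                    return "O.carbonyl"
        return "O.sp3"
    if el == "C":
        xi = atom.coords
        for j in neighbors:
            nb = frame.atoms[j]
            if nb.element.upper() == "O" and float(np.linalg.norm(nb.coords - xi)) <= _DOUBLE_BOND_CO:
                return "C.carbonyl"
        if len(neighbors) == 3:
            return "C.aromatic"
        return "C.sp3"
    # nitrogen
    for j in neighbors:
        nb = frame.atoms[j]
        if nb.element.upper() != "C":
            continue
        xj = nb.coords
        for k in _neighbor_indices(frame, j, _COVALENT_CUTOFF):
            other = frame.atoms[k]
            if other.element.upper() == "O" and float(np.linalg.norm(other.coords - xj)) <= _DOUBLE_BOND_CO:
                return "N.amide"
    return "N.sp3"


def assign_atom_types(frame: Frame, scheme: str = "element") -> Frame:
    """Return a copy of *frame* with ``atom_type`` populated on every atom.

    scheme="element" copies the element symbol; scheme="element_context"
    appends a carbonyl/aromatic/sp3 context flag derived from bonded
    neighbors under covalent-distance heuristics.
    """
    if scheme not in ("element", "element_context"):
        raise ValueError(f"unknown typing scheme: {scheme!r}")
    for atom in frame.atoms:
        if not atom.element or not atom.element.strip():
            raise AtomTypingError(
                f"atom serial {atom.serial} ({atom.name!r} in "
                f"{atom.residue_name} {atom.residue_number}) has no element"
            )
    atoms = []
    for i, atom in enumerate(frame.atoms):
        if scheme == "element":
            atype = atom.element.upper()
        else:
            atype = _context_type(frame, i)
        atoms.append(replace(atom, atom_type=atype))
    return Frame(index=frame.index, time_ps=frame.time_ps, atoms=atoms)


def type_ensemble(ensemble: Ensemble, scheme: str = "element") -> Ensemble:
    """Apply :func:`assign_atom_types` frame-wise (topology is preserved)."""
    return Ensemble(frames=[assign_atom_types(f, scheme) for f in ensemble])
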