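"""Multi-model PDB reading/writing and atom-selection resolution.

Coordinates are read from the fixed PDB columns and kept in Angstrom.
Only the record types the downstream geometry needs are handled
(ATOM/HETATM/MODEL/ENDMDL); mmCIF, insertion codes and connectivity are
out of scope.  NMR-style files without MODEL records are treated as a
single model.  The "lowest energy" member of an NMR ensemble is taken to
be MODEL 1 by convention unless the caller passes another index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "AtomSelection",
    "PDBError",
    "SelectionError",
    "parse_pdb",
    "select_atoms",
    "write_pdb",
]

# Backbone heavy atoms excluded from "sidechain" selections.
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


class PDBError(ValueError):
    """Raised for unparseable or empty PDB input."""


class SelectionError(KeyError):
    """Raised when an atom selection resolves to zero atoms."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray  # shape (3,), Angstrom
    element: str
    model_index: int  # 1-based

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: non-finite or malformed position")
        object.__setattr__(self, "position", pos)
        if self.model_index < 1:
            raise ValueError("model_index must be >= 1")


@dataclass
class Structure:
    atoms: list[AtomRecord] = field(default_factory=list)
    n_models: int = 1
    source_id: str = ""

    def model_atoms(self, model: int) -> list[AtomRecord]:
        if not 1 <= model <= self.n_models:
            raise IndexError(f"model {model} outside [1, {self.n_models}]")
        return [a for a in self.atoms if a.model_index == model]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class AtomSelection:
    """Selects atoms of one residue by name pattern.

    ``atom_name`` is either a literal atom name ("CA", "NZ"), the keyword
    "sidechain" (heavy atoms outside the backbone), the keyword "heavy"
    (all non-hydrogen atoms), or an explicit tuple of atom names.
    """

    residue_number: int
    atom_name: str | tuple[str, ...] = "CA"
    chain_id: str | None = None

    def matches(self, atom: AtomRecord) -> bool:
        if atom.residue_number != self.residue_number:
            return False
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if isinstance(self.atom_name, tuple):
            return atom.atom_name in self.atom_name
        if self.atom_name == "sidechain":
            return atom.element != "H" and atom.atom_name not in _BACKBONE
        if self.atom_name == "heavy":
            return atom.element != "H"
        return atom.atom_name == self.atom_name


def _infer_element(atom_name: str, element_field: str) -> str:
    if element_field:
        return element_field.strip().upper()
    name = atom_name.strip().lstrip("0123456789")
    if not name:
        return ""
    if name[0] == "H":
        return "H"
    return name[0].upper()


def parse_pdb(text: str, source_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    MODEL/ENDMDL blocks are counted; a file with no MODEL record is a
    single-model structure.  Altloc 'A' or blank is kept, all other
    alternate locations are dropped so each model holds one conformer.
    """
    atoms: list[AtomRecord] = []
    model_index = 0
    saw_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            saw_model = True
            model_index += 1
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        altloc = line[16:17]
        if altloc not in (" ", "", "A"):
            continue
        try:
            serial = int(line[6:11])
            atom_name = line[12:16].strip()
            residue_name = line[17:20].strip()
            chain_id = line[21:22]
            residue_number = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise PDBError(f"malformed ATOM record at line {lineno}: {exc}") from exc
        element = _infer_element(atom_name, line[76:78] if len(line) >= 78 else "")
        atoms.append(
            AtomRecord(
                serial=serial,
                atom_name=atom_name,
                residue_name=residue_name,
                residue_number=residue_number,
                chain_id=chain_id,
                position=np.array([x, y, z]),
                element=element,
                model_index=model_index if saw_model else 1,
            )
        )
    if not atoms:
        raise PDBError("no ATOM/HETATM records found")
    n_models = model_index if saw_model else 1
    return Structure(atoms=atoms, n_models=n_models, source_id=source_id)


def select_atoms(
    structure: Structure, selection: AtomSelection, model: int = 1
) -> list[np.ndarray]:
    """Resolve a selection to coordinates (file order) in one model."""
    hits = [a.position for a in structure.model_atoms(model) if selection.matches(a)]
    if not hits:
        raise SelectionError(
            f"selection residue {selection.residue_number} atom "
            f"{selection.atom_name!r} resolved to zero atoms in model {model}"
        )
    return hits


def selection_centroid(
    structure: Structure, selection: AtomSelection, model: int = 1
) -> np.ndarray:
    """Mean position of the selected atoms."""
    return np.mean(select_atoms(structure, selection, model), axis=0)


def _format_atom(a: AtomRecord) -> str:
    for c in a.position:
        if not -999.999 <= c <= 9999.999:
            raise PDBError(f"coordinate {c} overflows the PDB 8.3 field")
    name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
    return (
        f"ATOM  {a.serial:5d} {name:<4s} {a.residue_name:<3s} "
        f"{a.chain_id:1s}{a.residue_number:4d}    "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
    )


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure; round-trips coordinates to 3 decimals."""
    if not structure.atoms:
        raise PDBError("cannot write an empty structure")
    lines: list[str] = []
    multi = structure.n_models > 1
    for model in range(1, structure.n_models + 1):
        if multi:
            lines.append(f"MODEL     {model:4d}")
        lines.extend(_format_atom(a) for a in structure.model_atoms(model))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def structure_from_arrays(
    coords: np.ndarray,
    atom_names: Sequence[str],
    residue_numbers: Sequence[int],
    residue_names: Sequence[str] | None = None,
    chain_id: str = "A",
    source_id: str = "array",
) -> Structure:
    """Build a (possibly multi-model) Structure from coordinate arrays.

    ``coords`` is (n_atoms, 3) for a single model or (n_models, n_atoms, 3).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_models, n_atoms, _ = coords.shape
    if residue_names is None:
        residue_names = ["ALA"] * n_atoms
    atoms = []
    for m in range(n_models):
        for i in range(n_atoms):
            atoms.append(
                AtomRecord(
                    serial=i + 1,
                    atom_name=atom_names[i],
                    residue_name=residue_names[i],
                    residue_number=int(residue_numbers[i]),
                    chain_id=chain_id,
                    position=coords[m, i],
                    element=_infer_element(atom_names[i], ""),
                    model_index=m + 1,
                )
            )
    return Structure(atoms=atoms, n_models=n_models, source_id=source_id)
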