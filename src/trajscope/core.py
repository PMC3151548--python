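"""Core molecular containers: Atom, Structure, Trajectory, Selection.

Coordinates are in Angstrom throughout, masses in amu, B-factors in A^2.
Internal indices are 0-based; 1-based numbering appears only in user-facing
output (PDB serials, report tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrajscopeError

#: Standard atomic weights (amu) for the elements that occur in protein
#: structures and the hetero groups handled here.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "MG": 24.305, "FE": 55.845, "ZN": 65.38, "CA": 40.078,
    "NA": 22.990, "K": 39.098, "CL": 35.45, "SE": 78.971,
}


def guess_element(atom_name: str, resname: str = "") -> str:
    """Infer the element from a PDB atom name.

    Follows the PDB convention that the element occupies columns 13-14 of
    the name field; a leading digit (as in ``1HB``) is stripped.  Two-letter
    ions (``MG``, ``ZN`` ...) are recognised when the full stripped name
    matches.
    """
    name = atom_name.strip()
    while name and name[0].isdigit():
        name = name[1:]
    if not name:
        return "C"
    upper = name.upper()
    if upper in ATOMIC_MASSES and len(upper) > 1 and upper == resname.strip().upper():
        return upper
    if upper[:2] in ("MG", "FE", "ZN", "CL", "NA", "SE") and upper[:2] == upper:
        return upper[:2]
    return upper[0]


def mass_for(atom_name: str, resname: str = "") -> float:
    """Standard atomic weight for an atom named per PDB convention."""
    return ATOMIC_MASSES.get(guess_element(atom_name, resname), 12.011)


@dataclass
class Atom:
    """A single atom record.

    The B-factor column carries the experimental beta-factor used when
    correlating theoretical and experimental thermal fluctuations.
    """

    serial: int
    name: str
    resname: str
    resid: int
    segid: str
    coords: np.ndarray
    mass: float = 0.0
    bfactor: float = 0.0
    icode: str = ""
    chain: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise TrajscopeError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.mass <= 0.0:
            self.mass = mass_for(self.name, self.resname)

    @property
    def residue_key(self) -> tuple:
        """Residue identity: (segid, resid, insertion code)."""
        return (self.segid, self.resid, self.icode)


class Structure:
    """An ordered list of atoms with a residue index.

    Residue order follows file order; the residue key is
    ``(segid, resid, insertion-code)`` with the chain ID standing in for a
    blank segid.
    """

    def __init__(self, atoms: list[Atom]):
        self.atoms = list(atoms)
        self._build_residue_index()

    def _build_residue_index(self):
        self.residues: list[tuple] = []
        self.residue_atoms: dict[tuple, list[int]] = {}
        self.ca_index: dict[tuple, int] = {}
        for i, atom in enumerate(self.atoms):
            if not atom.segid and atom.chain:
                atom.segid = atom.chain
            key = atom.residue_key
            if key not in self.residue_atoms:
                self.residues.append(key)
                self.residue_atoms[key] = []
            self.residue_atoms[key].append(i)
            if atom.name.strip() == "CA" and key not in self.ca_index:
                self.ca_index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array (A)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def bfactors(self) -> np.ndarray:
        return np.array([a.bfactor for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TrajscopeError(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)")
        atoms = [
            Atom(a.serial, a.name, a.resname, a.resid, a.segid, c,
                 mass=a.mass, bfactor=a.bfactor, icode=a.icode, chain=a.chain)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms)


@dataclass
class Trajectory:
    """Stacked coordinate frames for a fixed atom set.

    ``coords`` is F x N x 3 in Angstrom; ``stride`` records the saving
    interval of the source simulation in frames.
    """

    coords: np.ndarray
    stride: int = 1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajscopeError("trajectory coords must be F x N x 3")
        if self.n_frames < 1:
            raise TrajscopeError("trajectory must hold at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass
class Selection:
    """A resolved atom selection: expression plus sorted unique 0-based indices."""

    expression: str
    indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        idx = list(self.indices)
        if any(idx[k] >= idx[k + 1] for k in range(len(idx) - 1)):
            raise TrajscopeError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)
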