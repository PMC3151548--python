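"""Fixed-column PDB reading and writing.

Handles ATOM/HETATM/MODEL/ENDMDL/TER/END records only.  Multi-model files
yield a companion Trajectory with one frame per MODEL.  The B-factor column
is retained on read and written back at format precision (2 decimals);
coordinates at 3 decimals.
"""

from __future__ import annotations

import numpy as np

from .core import Atom, Structure, Trajectory
from .errors import ParseError


def _parse_atom_line(line: str, lineno: int) -> Atom:
    line = line.rstrip("\n").ljust(80)
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # some writers overflow the serial column; tolerated
    name = line[12:16].strip()
    resname = line[17:21].strip()
    chain = line[21].strip()
    try:
        resid = int(line[22:26])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed residue number field: {line[22:26]!r}") from exc
    icode = line[26].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed coordinate field: {line[30:54]!r}") from exc
    try:
        bfactor = float(line[60:66]) if line[60:66].strip() else 0.0
    except ValueError:
        bfactor = 0.0
    segid = line[72:76].strip()
    return Atom(serial, name, resname, resid, segid or chain, (x, y, z),
                bfactor=bfactor, icode=icode, chain=chain)


def read_pdb(path) -> tuple[Structure, Trajectory | None]:
    """Read a PDB file.

    Returns the Structure built from the first model and, when the file
    holds several MODEL records with identical atom sets, a Trajectory with
    one frame per model (frame 0 duplicates the Structure coordinates).
    """
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
            elif rec == "MODEL":
                if current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec == "END":
                break
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    structure = Structure(models[0])
    trajectory = None
    if in_model and len(models) > 1:
        n = len(models[0])
        for k, m in enumerate(models):
            if len(m) != n:
                raise ParseError(
                    f"{path}: model {k + 1} has {len(m)} atoms, model 1 has {n}")
        coords = np.array([[a.coords for a in m] for m in models])
        trajectory = Trajectory(coords)
    return structure, trajectory


def _format_atom_line(atom: Atom, serial: int) -> str:
    name = atom.name
    # standard PDB name justification: element in columns 13-14
    if len(name) < 4 and name[:2].upper() not in ("MG", "FE", "ZN", "CL", "NA"):
        name = " " + name
    name = name.ljust(4)[:4]
    resname = atom.resname.ljust(4)[:4]
    chain = (atom.chain or atom.segid[:1] or "A")[:1]
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:5d} {name} {resname.rstrip().ljust(4)[:4]}{chain}"
        f"{atom.resid:4d}{atom.icode or ' ':1}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{atom.bfactor:6.2f}"
        f"      {atom.segid.ljust(4)[:4]}\n"
    )


def write_pdb(path, structure: Structure, trajectory: Trajectory | None = None,
              bfactors: np.ndarray | None = None) -> None:
    """Write a Structure (optionally multi-model from a Trajectory) to PDB.

    ``bfactors`` overrides the per-atom B-factor column, e.g. to export a
    perturbation-response profile for colouring in a molecular viewer.
    """
    if bfactors is not None and len(bfactors) != structure.n_atoms:
        raise ParseError("bfactor override length != atom count")
    frames = trajectory.coords if trajectory is not None else structure.coords[None]
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            for i, atom in enumerate(structure.atoms):
                a = atom
                if bfactors is not None or not np.array_equal(frame[i], atom.coords):
                    a = Atom(atom.serial, atom.name, atom.resname, atom.resid,
                             atom.segid, frame[i], mass=atom.mass,
                             bfactor=float(bfactors[i]) if bfactors is not None else atom.bfactor,
                             icode=atom.icode, chain=atom.chain)
                fh.write(_format_atom_line(a, i + 1))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
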