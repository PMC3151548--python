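"""CHARMM/X-PLOR binary DCD trajectory reading and writing.

Reading and writing are delegated to MDAnalysis (libdcd), which transparently
handles both little- and big-endian files.  A lightweight header sniff runs
before any read to reject truncated files (frame-size mismatch) and
fixed-atom DCDs, which this reader does not support.
"""

from __future__ import annotations

import os
import struct

import numpy as np

from .core import Trajectory
from .errors import FormatError, UnsupportedFeatureError

_HEADER_BLOCK = 84


def sniff_dcd_header(path) -> dict:
    """Parse the DCD header without reading any frame.

    Returns a dict with ``endian`` ('<' or '>'), ``n_frames``, ``n_atoms``,
    ``n_fixed``, ``has_cell`` and ``header_bytes``.
    """
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(96)
        if len(head) < 96:
            raise FormatError(f"{path}: file too short to hold a DCD header")
        if struct.unpack("<i", head[:4])[0] == _HEADER_BLOCK:
            endian = "<"
        elif struct.unpack(">i", head[:4])[0] == _HEADER_BLOCK:
            endian = ">"
        else:
            raise FormatError(f"{path}: not a DCD file (bad leading record size)")
        if head[4:8] != b"CORD":
            raise FormatError(f"{path}: not a DCD file (missing CORD magic)")
        icntrl = struct.unpack(endian + "20i", head[8:88])
        n_frames = icntrl[0]
        n_fixed = icntrl[8]
        charmm_version = icntrl[19]
        has_cell = bool(charmm_version and icntrl[10])
        # title record
        fh.seek(92)
        (title_len,) = struct.unpack(endian + "i", fh.read(4))
        fh.seek(title_len + 4, os.SEEK_CUR)
        marker, n_atoms, marker2 = struct.unpack(endian + "3i", fh.read(12))
        if marker != 4 or marker2 != 4:
            raise FormatError(f"{path}: malformed atom-count record")
        header_bytes = fh.tell()
    frame_bytes = (56 if has_cell else 0) + 3 * (8 + 4 * n_atoms)
    expected = header_bytes + n_frames * frame_bytes
    if n_fixed > 0:
        raise UnsupportedFeatureError(
            f"{path}: fixed-atom DCDs ({n_fixed} fixed atoms) are not supported")
    if size != expected:
        raise FormatError(
            f"{path}: frame-size mismatch: header promises {n_frames} frames "
            f"({expected} bytes) but the file holds {size} bytes")
    return {
        "endian": endian, "n_frames": n_frames, "n_atoms": n_atoms,
        "n_fixed": n_fixed, "has_cell": has_cell, "header_bytes": header_bytes,
    }


def read_dcd(path, stride_metadata: int = 1) -> Trajectory:
    """Read a DCD trajectory into an F x N x 3 coordinate array (A)."""
    sniff_dcd_header(path)
    from MDAnalysis.coordinates.DCD import DCDReader

    reader = DCDReader(str(path))
    try:
        coords = np.array([ts.positions.copy() for ts in reader], dtype=float)
    finally:
        reader.close()
    return Trajectory(coords, stride=stride_metadata)


def write_dcd(path, trajectory: Trajectory) -> None:
    """Write a Trajectory to a little-endian CHARMM DCD (float32 precision)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDWriter

    u = mda.Universe.empty(trajectory.n_atoms, trajectory=True)
    u.load_new(trajectory.coords.astype(np.float32), order="fac")
    with DCDWriter(str(path), trajectory.n_atoms) as writer:
        for _ in u.trajectory:
            writer.write(u.atoms)
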