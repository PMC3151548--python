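"""Deterministic, seeded generators for every synthetic test input.

Three generators cover the toolkit's input types: a chemically naive but
format-valid toy polypeptide (for network and selection tests, with
hand-countable side-chain contacts), a Gaussian trajectory with a known
3N x 3N covariance (for correlation tests), and a Markov microstate
timeseries with block (well) structure and a known transition matrix (for
the free-energy modules).  Each generator returns a machine-readable
ground-truth record beside the data; the same seed reproduces the same
fixture bit for bit.
"""

from __future__ import annotations

import json

import numpy as np

from .core import Atom, Structure, Trajectory
from .errors import TrajscopeError
from .fel import MicrostateTrajectory

# residue names cycled through toy structures; all have known normalization
# factors and a real side chain (no glycine)
_TOY_RESNAMES = ["ALA", "SER", "VAL", "THR", "LEU", "ASP", "LYS", "PHE"]


def write_ground_truth(path, record: dict) -> None:
    """Serialize a generator's ground-truth record as JSON."""

    def convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"not serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(record, fh, default=convert, indent=1)


_SIDE_NAMES = ["CB", "CG", "CD", "CE"]


def gen_toy_structure(n_res: int, geometry: str = "zigzag", seed: int = 0,
                      contact_scale: float = 1.0,
                      n_side_atoms: int = 2) -> tuple[Structure, dict]:
    """Toy polypeptide with CA plus side-chain pseudo-atoms per residue.

    ``zigzag`` alternates the backbone in a 3-D zig-zag with the canonical
    3.8 A alpha-carbon spacing; ``helix`` winds a compact idealized helix (2.3 A
    radius, 1.0 A rise, 100 degrees per residue) so that residues one turn
    apart come into side-chain contact.  Each residue carries
    ``n_side_atoms`` pseudo-atoms (CB, CG, ...) stacked ~1.4 A apart,
    tilted toward the chain axis; ``contact_scale`` widens (>1) or tightens
    (<1) the geometry to control which contacts form.  The ground-truth
    record lists every inter-residue side-chain atom-pair contact at 4.5 A
    and the per-pair counts n_ij, so interaction strengths are
    hand-countable.
    """
    if n_res < 2:
        raise TrajscopeError("toy structure needs at least 2 residues")
    if not 1 <= n_side_atoms <= len(_SIDE_NAMES):
        raise TrajscopeError(f"n_side_atoms must be in [1, {len(_SIDE_NAMES)}]")
    rng = np.random.default_rng(seed)
    ca = np.zeros((n_res, 3))
    if geometry == "zigzag":
        step = 3.8 * contact_scale
        for i in range(1, n_res):
            direction = np.array([1.0, 0.6 * (-1) ** i, 0.3 * (-1) ** (i // 2)])
            direction /= np.linalg.norm(direction)
            ca[i] = ca[i - 1] + step * direction
    elif geometry == "helix":
        radius, rise, turn = 2.3 * contact_scale, 1.0 * contact_scale, np.deg2rad(100)
        for i in range(n_res):
            ca[i] = (radius * np.cos(i * turn), radius * np.sin(i * turn), i * rise)
    else:
        raise TrajscopeError(f"unknown geometry {geometry!r}")
    axis = ca.mean(axis=0)
    atoms = []
    serial = 1
    side = np.empty((n_res, n_side_atoms, 3))
    for i in range(n_res):
        resname = _TOY_RESNAMES[i % len(_TOY_RESNAMES)]
        inward = axis - ca[i]
        if geometry == "helix":
            inward = np.array([axis[0], axis[1], ca[i, 2]]) - ca[i]
        norm = np.linalg.norm(inward)
        inward = inward / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        atoms.append(Atom(serial, "CA", resname, i + 1, "A", ca[i]))
        serial += 1
        for k in range(n_side_atoms):
            jitter = rng.normal(scale=0.05, size=3)
            side[i, k] = ca[i] + (1.4 * (k + 1)) * inward + jitter
            atoms.append(Atom(serial, _SIDE_NAMES[k], resname, i + 1, "A",
                              side[i, k]))
            serial += 1
    structure = Structure(atoms)
    contacts = []
    pair_count = np.zeros((n_res, n_res), dtype=int)
    for i in range(n_res):
        for j in range(i + 1, n_res):
            for a in range(n_side_atoms):
                for b in range(n_side_atoms):
                    d = float(np.linalg.norm(side[i, a] - side[j, b]))
                    if d <= 4.5:
                        contacts.append({"i": i + 1, "j": j + 1,
                                         "atom_i": _SIDE_NAMES[a],
                                         "atom_j": _SIDE_NAMES[b],
                                         "distance": d})
                        pair_count[i, j] += 1
                        pair_count[j, i] += 1
    truth = {
        "kind": "toy_structure", "seed": seed, "n_res": n_res,
        "geometry": geometry, "contact_cutoff": 4.5,
        "side_chain_contacts": contacts, "pair_counts": pair_count,
        "ca_coords": ca, "side_coords": side.reshape(n_res * n_side_atoms, 3),
    }
    return structure, truth


def gen_gaussian_traj(structure: Structure, covariance: np.ndarray,
                      n_frames: int, seed: int = 0) -> tuple[Trajectory, dict]:
    """Trajectory of frames drawn from N(structure coords, covariance).

    ``covariance`` is the full 3N x 3N positional covariance (A^2) and must
    be positive semidefinite.  The ground-truth record carries the
    covariance and the analytic DCC it implies, so sampled correlations can
    be checked against their population values.
    """
    n = structure.n_atoms
    cov = np.asarray(covariance, float)
    if cov.shape != (3 * n, 3 * n):
        raise TrajscopeError(f"covariance must be {3 * n} x {3 * n}")
    eigs = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if eigs.min() < -1e-10 * max(eigs.max(), 1.0):
        raise TrajscopeError("covariance is not positive semidefinite")
    rng = np.random.default_rng(seed)
    mean = structure.coords.reshape(-1)
    draws = rng.multivariate_normal(mean, cov, size=n_frames,
                                    method="eigh")
    coords = draws.reshape(n_frames, n, 3)
    # analytic DCC from the specified covariance
    traced = np.zeros((n, n))
    for a in range(3):
        traced += cov[a::3, a::3]
    diag = np.sqrt(np.clip(np.diag(traced), 1e-300, None))
    dcc = traced / np.outer(diag, diag)
    truth = {
        "kind": "gaussian_traj", "seed": seed, "n_frames": n_frames,
        "covariance": cov, "analytic_dcc": dcc,
    }
    return Trajectory(coords), truth


def gen_markov_traj(n_states: int, well_assignment, intra_p: float,
                    inter_p: float, n_steps: int, seed: int = 0,
                    start: int = 0) -> tuple[MicrostateTrajectory, dict]:
    """Microstate timeseries from an explicit block-structured Markov chain.

    ``well_assignment`` maps each state to a well id.  From any state, the
    probability mass splits into: ``intra_p`` shared uniformly over the
    *other* states of the same well, ``inter_p`` shared uniformly over all
    states of other wells, remainder on staying put.  ``inter_p`` therefore
    directly sets the barrier-crossing rate.  The transition matrix and the
    well labels are saved as ground truth.
    """
    wells = np.asarray(well_assignment, dtype=int)
    if wells.shape != (n_states,):
        raise TrajscopeError("well_assignment must give one well per state")
    if intra_p < 0 or inter_p < 0 or intra_p + inter_p > 1:
        raise TrajscopeError(
            "intra_p and inter_p must be nonnegative with sum <= 1 "
            "(rows must sum to 1)")
    T = np.zeros((n_states, n_states))
    for s in range(n_states):
        same = np.where((wells == wells[s]) & (np.arange(n_states) != s))[0]
        other = np.where(wells != wells[s])[0]
        stay = 1.0 - (intra_p if same.size else 0.0) - (inter_p if other.size else 0.0)
        T[s, s] = stay
        if same.size:
            T[s, same] = intra_p / same.size
        if other.size:
            T[s, other] = inter_p / other.size
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise TrajscopeError("transition probabilities do not sum to 1")
    rng = np.random.default_rng(seed)
    labels = np.empty(n_steps, dtype=int)
    state = start
    cdf = np.cumsum(T, axis=1)
    u = rng.random(n_steps)
    for t in range(n_steps):
        labels[t] = state
        state = int(np.searchsorted(cdf[state], u[t], side="right"))
        state = min(state, n_states - 1)
    truth = {
        "kind": "markov_traj", "seed": seed, "n_steps": n_steps,
        "transition_matrix": T, "wells": wells,
        "intra_p": intra_p, "inter_p": inter_p,
    }
    return MicrostateTrajectory.from_labels(labels), truth
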