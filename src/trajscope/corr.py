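"""Motion cross-correlation along a trajectory: DCC and LMI.

DCC (dynamic cross-correlation) is the normalized covariance of the
displacement vectors of two nodes,

    DCC_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

in [-1, 1]; it is blind to correlated motions along perpendicular
directions.  LMI (linear mutual information) is the mutual information of
the two positions under a Gaussian model,

    I_ij = 1/2 (ln det C_i + ln det C_j - ln det C_ij),

with C_i, C_j the 3x3 marginal and C_ij the 6x6 pair covariance; it detects
perpendicular correlations.  I is mapped onto [0, 1] through the Gaussian
correlation r = sqrt(1 - exp(-2 I / 3)) (dimension 3), which gives 0 for
independence and 1 for identical variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Selection, Structure, Trajectory
from .errors import TrajscopeError


@dataclass
class FluctuationSet:
    """Mean-subtracted per-node displacement timeseries (F x N x 3, A)."""

    deviations: np.ndarray
    node_labels: list
    group_by: str                # "atom" | "residue"
    mass_weighted: bool = False

    @property
    def n_frames(self) -> int:
        return self.deviations.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.deviations.shape[1]


@dataclass
class CorrelationMatrix:
    method: str                  # "DCC" | "LMI"
    values: np.ndarray
    node_labels: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def superpose_frames(coords: np.ndarray) -> np.ndarray:
    """Least-squares fit of every frame onto frame 0 (optional preprocessing)."""
    from scipy.spatial.transform import Rotation

    ref = coords[0] - coords[0].mean(axis=0)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        frame = coords[f] - coords[f].mean(axis=0)
        rot, _ = Rotation.align_vectors(ref, frame)
        out[f] = rot.apply(frame)
    return out


def build_fluctuations(traj: Trajectory, structure: Structure | None = None,
                       selection: Selection | None = None,
                       group_by: str = "atom", mass_weighted: bool = False,
                       fit: bool = False) -> FluctuationSet:
    """Extract per-node displacement timeseries from a trajectory.

    ``group_by='residue'`` collapses each residue's atoms to their
    (optionally mass-weighted) centroid per frame.  Deviations are taken
    about the trajectory mean, so they average to zero by construction.
    No superposition is applied unless ``fit`` is set.
    """
    if traj.n_frames < 2:
        raise TrajscopeError("need at least 2 frames to measure fluctuations")
    if selection is not None:
        idx = list(selection.indices)
        if not idx:
            raise TrajscopeError("empty selection")
    else:
        idx = list(range(traj.n_atoms))
    coords = traj.coords[:, idx, :]
    if fit:
        coords = superpose_frames(coords)
    if group_by == "atom":
        series = coords
        labels = idx if structure is None else [
            structure.atoms[i].residue_key + (structure.atoms[i].name,) for i in idx]
    elif group_by == "residue":
        if structure is None:
            raise TrajscopeError("residue grouping requires a Structure")
        groups: dict[tuple, list[int]] = {}
        order = []
        for pos, i in enumerate(idx):
            key = structure.atoms[i].residue_key
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(pos)
        series = np.empty((traj.n_frames, len(order), 3))
        for g, key in enumerate(order):
            members = groups[key]
            if mass_weighted:
                w = np.array([structure.atoms[idx[p]].mass for p in members])
            else:
                w = np.ones(len(members))
            w = w / w.sum()
            series[:, g, :] = np.einsum("fma,m->fa", coords[:, members, :], w)
        labels = order
    else:
        raise TrajscopeError(f"unknown grouping {group_by!r}")
    deviations = series - series.mean(axis=0, keepdims=True)
    return FluctuationSet(deviations, list(labels), group_by, mass_weighted)


def dcc(fluct: FluctuationSet) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix (normalized displacement covariance)."""
    dev = fluct.deviations
    # <dr_i . dr_j> over frames, population (1/F) normalization
    inner = np.einsum("fia,fja->ij", dev, dev) / fluct.n_frames
    var = np.diag(inner)
    bad = np.where(var <= 0)[0]
    if bad.size:
        raise TrajscopeError(
            f"zero-variance node(s) {bad.tolist()}: DCC undefined")
    values = inner / np.sqrt(np.outer(var, var))
    return CorrelationMatrix("DCC", np.clip(values, -1.0, 1.0), fluct.node_labels)


def gaussian_mutual_information(cov_i: np.ndarray, cov_j: np.ndarray,
                                cov_pair: np.ndarray) -> float:
    """Closed-form mutual information of two jointly Gaussian 3-vectors.

    Returns +inf when the pair covariance is singular (deterministic
    dependence).
    """
    sign_i, ld_i = np.linalg.slogdet(cov_i)
    sign_j, ld_j = np.linalg.slogdet(cov_j)
    if sign_i <= 0 or sign_j <= 0:
        raise TrajscopeError(
            "singular marginal covariance: motion confined to a subspace; "
            "consider regularizing with a small diagonal jitter")
    sign_p, ld_p = np.linalg.slogdet(cov_pair)
    if sign_p <= 0:
        return float("inf")
    return max(0.5 * (ld_i + ld_j - ld_p), 0.0)


def lmi_from_information(info: float) -> float:
    """Map mutual information (nats) onto the [0, 1] correlation scale.

    Gaussian-channel normalization in dimension 3:
    r = sqrt(1 - exp(-2 I / 3)); 0 at independence, 1 at identity.
    """
    if np.isinf(info):
        return 1.0
    return float(np.sqrt(1.0 - np.exp(-2.0 * info / 3.0)))


def lmi(fluct: FluctuationSet) -> CorrelationMatrix:
    """Linear mutual information correlation matrix in [0, 1]."""
    if fluct.n_frames <= 6:
        raise TrajscopeError(
            "LMI needs more than 6 frames to estimate 6x6 pair covariances")
    dev = fluct.deviations
    f, n, _ = dev.shape
    flat = dev.reshape(f, 3 * n)
    cov = flat.T @ flat / f   # 3N x 3N population covariance
    values = np.eye(n)
    for i in range(n):
        ci = cov[3 * i:3 * i + 3, 3 * i:3 * i + 3]
        for j in range(i + 1, n):
            cj = cov[3 * j:3 * j + 3, 3 * j:3 * j + 3]
            pair = np.empty((6, 6))
            pair[:3, :3] = ci
            pair[3:, 3:] = cj
            pair[:3, 3:] = cov[3 * i:3 * i + 3, 3 * j:3 * j + 3]
            pair[3:, :3] = pair[:3, 3:].T
            r = lmi_from_information(gaussian_mutual_information(ci, cj, pair))
            values[i, j] = values[j, i] = r
    return CorrelationMatrix("LMI", values, fluct.node_labels)
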