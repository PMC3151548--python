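"""Elastic network models: Hessian normal modes, structural perturbation
method (SPM), theoretical beta-factors, involvement coefficients / cumulative
square overlap, and mode-based residue correlations.

The network is a coarse-grained harmonic model: selected atoms (classically
the alpha-carbons) are beads joined by Hookean springs,

    E = 1/2 * sum_ij k_ij (d_ij - d0_ij)^2,

where d0_ij is the equilibrium (input-structure) distance.  Two spring
models are provided:

* ``cutoff`` (linear cutoff): k = 1 for pairs within a distance cutoff
  (default 12 A), k = 10 for sequence-adjacent beads;
* ``kovacs``: every pair interacts with a force constant decaying with the
  inverse sixth power of distance, k(d) = C * (3.8 / d)**6 with
  C = 40 kcal/(mol A^2) by default, 3.8 A being the canonical
  alpha-carbon virtual-bond length.

The Hessian of E at the minimum is the standard anisotropic-network
super-element: for each spring (i, j) with unit direction u,
H[i,i] += k u u^T, H[i,j] -= k u u^T.  A connected, non-collinear network
has exactly six zero modes (rigid translations and rotations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core import Selection, Structure
from .errors import DisconnectedNetworkError, TrajscopeError

BOLTZMANN_KCAL = 0.0019872041  # kcal/(mol K)
CA_VIRTUAL_BOND = 3.8  # A, consecutive alpha-carbon distance
ZERO_MODE_RTOL = 1e-8  # |lambda| < rtol * lambda_max counts as rigid-body


@dataclass
class Spring:
    i: int
    j: int
    k: float
    d0: float


@dataclass
class ElasticNetwork:
    """Bead coordinates plus the spring list of an elastic network."""

    coords: np.ndarray           # N x 3 (A)
    masses: np.ndarray           # N (amu)
    springs: list[Spring]
    model: str                   # "cutoff" | "kovacs"
    cutoff: float | None = None
    constant: float | None = None
    labels: list[tuple] = field(default_factory=list)  # residue keys per bead

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]


@dataclass
class ModeSet:
    """Eigen-decomposition of the 3N x 3N Hessian.

    Eigenvalues ascend; eigenvectors are orthonormal columns.  The first
    ``n_zero`` modes are rigid-body (near-zero eigenvalue) and are excluded
    from all thermal and overlap sums.
    """

    eigenvalues: np.ndarray      # 3N, ascending
    eigenvectors: np.ndarray     # 3N x 3N, columns
    n_zero: int
    network: ElasticNetwork
    mass_weighted: bool = False

    @property
    def n_internal(self) -> int:
        return len(self.eigenvalues) - self.n_zero

    def internal_indices(self) -> np.ndarray:
        return np.arange(self.n_zero, len(self.eigenvalues))


@dataclass
class SpmResponse:
    mode_index: int
    magnitude: float
    response: np.ndarray         # per-bead delta-omega, >= 0


@dataclass
class BetaFactorReport:
    theoretical: np.ndarray      # A^2
    experimental: np.ndarray | None
    correlation: float | None
    n_modes: int
    temperature: float


@dataclass
class OverlapReport:
    involvement: np.ndarray      # I_m per internal mode
    cso: float
    displacement: np.ndarray     # flattened 3N displacement T - R
    threshold: float

    def significant(self) -> list[tuple[int, float]]:
        """(internal mode rank, I) pairs above the output threshold."""
        return [(m, float(v)) for m, v in enumerate(self.involvement)
                if v > self.threshold]


def build_network(structure: Structure, selection: Selection | None = None,
                  model: str = "cutoff", cutoff: float = 12.0,
                  constant: float = 40.0) -> ElasticNetwork:
    """Build an elastic network on the selected atoms (default: all CA).

    ``cutoff`` model: k = 10 for sequence-adjacent beads (consecutive resid
    within one segid), k = 1 for any other pair within the distance cutoff.
    ``kovacs`` model: every pair gets k = constant * (3.8/d)^6.
    """
    if selection is None:
        idx = sorted(structure.ca_index[key] for key in structure.residues
                     if key in structure.ca_index)
    else:
        idx = list(selection.indices)
    if len(idx) < 2:
        raise TrajscopeError("elastic network needs at least 2 nodes")
    atoms = [structure.atoms[i] for i in idx]
    coords = np.array([a.coords for a in atoms])
    masses = np.array([a.mass for a in atoms])
    labels = [a.residue_key for a in atoms]
    n = len(idx)
    diffs = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diffs ** 2).sum(-1))
    springs: list[Spring] = []
    if model == "cutoff":
        for i in range(n):
            for j in range(i + 1, n):
                adjacent = (atoms[i].segid == atoms[j].segid
                            and abs(atoms[i].resid - atoms[j].resid) == 1)
                if adjacent:
                    springs.append(Spring(i, j, 10.0, dist[i, j]))
                elif dist[i, j] <= cutoff:
                    springs.append(Spring(i, j, 1.0, dist[i, j]))
    elif model == "kovacs":
        for i in range(n):
            for j in range(i + 1, n):
                d = dist[i, j]
                if d <= 0:
                    raise TrajscopeError(f"coincident nodes {i}, {j}")
                springs.append(Spring(i, j, constant * (CA_VIRTUAL_BOND / d) ** 6, d))
    else:
        raise TrajscopeError(f"unknown ENM model {model!r}")
    if not springs:
        raise DisconnectedNetworkError(
            "disconnected network: no atom pair within the cutoff")
    return ElasticNetwork(coords, masses, springs, model,
                          cutoff=cutoff if model == "cutoff" else None,
                          constant=constant if model == "kovacs" else None,
                          labels=labels)


def assemble_hessian(network: ElasticNetwork) -> np.ndarray:
    """3N x 3N Hessian of the harmonic energy at the input geometry."""
    n = network.n_nodes
    H = np.zeros((3 * n, 3 * n))
    for s in network.springs:
        u = network.coords[s.j] - network.coords[s.i]
        d = np.linalg.norm(u)
        u = u / d
        block = s.k * np.outer(u, u)
        si, sj = 3 * s.i, 3 * s.j
        H[si:si + 3, si:si + 3] += block
        H[sj:sj + 3, sj:sj + 3] += block
        H[si:si + 3, sj:sj + 3] -= block
        H[sj:sj + 3, si:si + 3] -= block
    return H


def diagonalize(network: ElasticNetwork, mass_weighting: bool = False) -> ModeSet:
    """Diagonalize the Hessian; modes sorted by ascending eigenvalue.

    Exactly six near-zero modes (|lambda| < 1e-8 * lambda_max) are expected
    for a connected non-collinear network; more than six triggers a warning
    about internal disconnection or collinearity.
    """
    import warnings

    H = assemble_hessian(network)
    if mass_weighting:
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(network.masses), 3)
        H = H * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    evals, evecs = scipy.linalg.eigh(H)
    lam_max = float(np.max(np.abs(evals))) or 1.0
    n_zero = int(np.sum(np.abs(evals) < ZERO_MODE_RTOL * lam_max))
    if n_zero > 6:
        warnings.warn(
            f"{n_zero} near-zero modes: internally disconnected or collinear network",
            stacklevel=2)
    return ModeSet(evals, evecs, n_zero, network, mass_weighting)


def perturbation_hessian(network: ElasticNetwork, node: int,
                         magnitude: float = 0.1) -> np.ndarray:
    """Hessian of the energy perturbation for node ``node``.

    Every spring touching the node has its force constant increased by
    ``magnitude``; the returned matrix is the Hessian of that extra energy.
    """
    sub = ElasticNetwork(
        network.coords, network.masses,
        [Spring(s.i, s.j, magnitude, s.d0) for s in network.springs
         if s.i == node or s.j == node],
        network.model)
    return assemble_hessian(sub)


def spm(modeset: ModeSet, mode_index: int, magnitude: float = 0.1) -> SpmResponse:
    """Structural perturbation method response for one internal mode.

    For each bead i, all springs touching i are stiffened by ``magnitude``
    and the induced frequency shift of mode m is measured as
    delta-omega = v_m^T dH v_m >= 0, identifying the beads most critical to
    that mode.  ``mode_index`` counts internal modes from 0 (the lowest
    nonzero-frequency mode).
    """
    net = modeset.network
    if mode_index < 0 or mode_index >= modeset.n_internal:
        raise TrajscopeError(
            f"mode_index {mode_index} outside internal modes "
            f"[0, {modeset.n_internal}) — rigid-body modes cannot be perturbed")
    v = modeset.eigenvectors[:, modeset.n_zero + mode_index]
    response = np.zeros(net.n_nodes)
    # per-spring closed form of v^T dH v: k * ((v_i - v_j) . u)^2
    for s in net.springs:
        u = net.coords[s.j] - net.coords[s.i]
        u = u / np.linalg.norm(u)
        dv = v[3 * s.i:3 * s.i + 3] - v[3 * s.j:3 * s.j + 3]
        contrib = magnitude * float(np.dot(dv, u)) ** 2
        response[s.i] += contrib
        response[s.j] += contrib
    return SpmResponse(mode_index, magnitude, response)


def beta_factors(modeset: ModeSet, n_modes: int | None = None,
                 temperature: float = 300.0,
                 experimental: np.ndarray | None = None) -> BetaFactorReport:
    """Theoretical beta-factors from the lowest internal modes.

    B_n = (8 pi^2 / 3) * kT * sum_m |v_m at node n|^2 / lambda_m, in A^2
    with force constants in kcal/(mol A^2).  When experimental B-factors are
    supplied, the Pearson-style cross-correlation between the two profiles
    is reported.
    """
    n_internal = modeset.n_internal
    if n_modes is None:
        n_modes = n_internal
    if not 1 <= n_modes <= n_internal:
        raise TrajscopeError(f"n_modes must be in [1, {n_internal}]")
    n = modeset.network.n_nodes
    b = np.zeros(n)
    kT = BOLTZMANN_KCAL * temperature
    for m in range(modeset.n_zero, modeset.n_zero + n_modes):
        lam = modeset.eigenvalues[m]
        v = modeset.eigenvectors[:, m].reshape(n, 3)
        b += (v ** 2).sum(axis=1) / lam
    b *= (8.0 * np.pi ** 2 / 3.0) * kT
    corr = None
    if experimental is not None:
        experimental = np.asarray(experimental, dtype=float)
        if experimental.shape != (n,):
            raise TrajscopeError("experimental B-factor array length != node count")
        corr = float(np.corrcoef(b, experimental)[0, 1])
    return BetaFactorReport(b, experimental, corr, n_modes, temperature)


def beta_correlation(theoretical: np.ndarray, experimental: np.ndarray) -> float:
    """Cross-correlation of theoretical vs experimental beta-factors.

    Pearson form: centred dot product over the product of centred norms;
    invariant to scale and offset of either profile.
    """
    t = np.asarray(theoretical, float) - np.mean(theoretical)
    e = np.asarray(experimental, float) - np.mean(experimental)
    denom = np.sqrt((t ** 2).sum() * (e ** 2).sum())
    if denom == 0:
        raise TrajscopeError("zero-variance beta-factor profile")
    return float(np.dot(t, e) / denom)


def involvement(modeset: ModeSet, conformer_t: np.ndarray,
                conformer_r: np.ndarray, threshold: float = 0.2) -> OverlapReport:
    """Involvement coefficients of the modes in an observed displacement.

    I_m = |v_m . (T - R)| / |T - R| for each internal mode m, and the
    cumulative square overlap CSO = sum_m I_m^2 over all internal modes.
    A displacement orthogonal to the rigid-body space gives CSO = 1.
    """
    t = np.asarray(conformer_t, float).reshape(-1)
    r = np.asarray(conformer_r, float).reshape(-1)
    if t.shape != r.shape or t.size != 3 * modeset.network.n_nodes:
        raise TrajscopeError("conformers must match the network's node set")
    disp = t - r
    norm = np.linalg.norm(disp)
    if norm == 0:
        raise TrajscopeError("identical conformers: zero displacement vector")
    internal = modeset.eigenvectors[:, modeset.n_zero:]
    proj = internal.T @ disp / norm
    inv = np.abs(proj)
    return OverlapReport(inv, float(np.sum(proj ** 2)), disp, threshold)


def mode_correlation(modeset: ModeSet, n_modes: int | None = None) -> np.ndarray:
    """N x N residue cross-correlation from the mode covariance.

    The positional covariance is the pseudo-inverse of the Hessian restricted
    to the chosen internal modes, sum_m v_m v_m^T / lambda_m; the correlation
    is the traced 3x3 block covariance normalized by the block variances:
    C_ij = tr(Cov_ij) / sqrt(tr(Cov_ii) tr(Cov_jj)), in [-1, 1] with unit
    diagonal.
    """
    n_internal = modeset.n_internal
    if n_modes is None:
        n_modes = n_internal
    if n_modes < 1 or n_modes > n_internal:
        raise TrajscopeError(f"n_modes must be in [1, {n_internal}]")
    n = modeset.network.n_nodes
    sel = slice(modeset.n_zero, modeset.n_zero + n_modes)
    v = modeset.eigenvectors[:, sel]
    lam = modeset.eigenvalues[sel]
    cov = (v / lam) @ v.T
    traced = np.zeros((n, n))
    for a in range(3):
        traced += cov[a::3, a::3]
    diag = np.sqrt(np.diag(traced))
    corr = traced / np.outer(diag, diag)
    return np.clip(corr, -1.0, 1.0)
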