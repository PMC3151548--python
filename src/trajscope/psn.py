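"""Protein structure networks (PSN).

Residues (and selected hetero groups) are nodes; two nodes are joined by an
edge when their interaction strength

    I_ij = 100 * n_ij / sqrt(N_i * N_j)   [percent]

reaches a threshold I_min, where n_ij counts side-chain atom pairs within a
distance cutoff (4.5 A default) and N_i, N_j are per-node normalization
factors accounting for node size and contact propensity.  Sequence
neighbours j = i +/- n (n = 2 default) within one chain are excluded, since
their contacts reflect covalent adjacency.

"Side chain" means every heavy atom except the backbone N, CA, C, O (OXT);
glycine therefore has no side-chain atoms and cannot form edges.  Hetero
nodes (GTP, GDP, Mg2+, retinal...) contribute all their heavy atoms.
Hydrogens are excluded from the pair counts by default (switchable).

Hubs are nodes with at least ``hub_cutoff`` (default 4) edges; node
clusterization is the connected-component partition of the edge set, and
I_critic is the I_min at which the largest cluster halves relative to
I_min = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import Selection, Structure
from .errors import TrajscopeError

#: Per-residue normalization factors for the 20 amino acids (contact-count
#: statistics over protein structure datasets).
AMINO_ACID_NF = {
    "ALA": 55.7551, "ARG": 93.7891, "ASN": 73.4097, "ASP": 75.1507,
    "CYS": 54.9528, "GLN": 78.1301, "GLU": 78.8288, "GLY": 47.3129,
    "HIS": 83.7357, "ILE": 67.9452, "LEU": 72.2517, "LYS": 69.6096,
    "MET": 69.2569, "PHE": 93.3082, "PRO": 51.3310, "SER": 61.3946,
    "THR": 63.7075, "TRP": 106.7030, "TYR": 100.7190, "VAL": 62.3673,
}

#: Normalization factors for hetero nodes, from contact statistics over
#: curated structure datasets (rhodopsins for retinal; G proteins for the
#: nucleotides; GTPases for the magnesium ion, whose NF depends on the
#: bound-nucleotide state).
RETINAL_NF = 170.13
GDP_NF = 220.19
GTP_NF = 274.78
MG_NF_GDP_STATE = 14.65
MG_NF_GTP_STATE = 22.01

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
STANDARD_RESIDUES = set(AMINO_ACID_NF)


def default_nf_table(mg_state: str = "GTP") -> dict[str, float]:
    """Normalization-factor table: 20 amino acids plus known hetero nodes.

    ``mg_state`` selects the Mg2+ factor for GDP- or GTP-bound GTPases.
    """
    table = dict(AMINO_ACID_NF)
    table["RET"] = RETINAL_NF
    table["GDP"] = GDP_NF
    table["GTP"] = GTP_NF
    table["MG"] = MG_NF_GTP_STATE if mg_state.upper() == "GTP" else MG_NF_GDP_STATE
    return table


@dataclass
class PSNGraph:
    """One frame's residue interaction network.

    ``nodes`` are residue keys in structure order; ``edges`` maps node-index
    pairs (i < j) to (I_ij percent, n_ij atom-pair count).
    """

    nodes: list[tuple]
    node_names: list[str]
    edges: dict[tuple[int, int], tuple[float, int]]
    i_min: float
    cutoff: float
    n_exclusion: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for (i, j) in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for (i, j), (strength, n_pairs) in self.edges.items():
            g.add_edge(i, j, weight=strength, n_pairs=n_pairs)
        return g


@dataclass
class HubSet:
    degrees: np.ndarray
    hub_flags: np.ndarray
    hub_interaction: np.ndarray   # I_i percent per node
    hub_cutoff: int
    strict: bool

    def hub_indices(self) -> list[int]:
        return [int(i) for i in np.where(self.hub_flags)[0]]


@dataclass
class ClusterSet:
    assignment: np.ndarray        # cluster id per node, numbered by smallest member
    sizes: list[int]

    @property
    def largest_size(self) -> int:
        return max(self.sizes) if self.sizes else 0


@dataclass
class EnsembleStats:
    edge_frequency: dict[tuple[int, int], float]
    hub_frequency: dict[int, float]
    stable_edges: list[tuple[int, int]]
    stable_hubs: list[int]
    hub_correlation_pairs: list[tuple[int, int, float]]
    stability: float
    n_frames: int


def _node_groups(structure: Structure, selection: Selection | None,
                 include_hydrogens: bool):
    """Residue keys, names and member-atom indices (side-chain rule applied)."""
    idx = selection.indices if selection is not None else range(structure.n_atoms)
    idx = list(idx)
    if not idx:
        raise TrajscopeError("empty selection")
    keys, names, members = [], [], {}
    for i in idx:
        a = structure.atoms[i]
        key = a.residue_key
        if key not in members:
            members[key] = []
            keys.append(key)
            names.append(a.resname)
        name = a.name.strip()
        is_standard = a.resname.strip().upper() in STANDARD_RESIDUES
        if is_standard and name in BACKBONE_NAMES:
            continue
        if not include_hydrogens and name.lstrip("0123456789").startswith("H"):
            continue
        members[key].append(i)
    return keys, names, members


def _resolve_nf(name: str, nf_table: dict[str, float]) -> float:
    key = name.strip().upper()
    if key not in nf_table:
        raise TrajscopeError(
            f"no normalization factor for node type {key!r}: supply one via "
            f"the nf_table argument or a name,NF CSV (--nf-file)")
    return nf_table[key]


def pair_counts(structure: Structure, coords: np.ndarray | None = None,
                selection: Selection | None = None, cutoff: float = 4.5,
                include_hydrogens: bool = False):
    """Count side-chain atom pairs within the cutoff for every node pair.

    Returns (residue keys, residue names, symmetric count matrix).
    """
    keys, names, members = _node_groups(structure, selection, include_hydrogens)
    if coords is None:
        coords = structure.coords
    atom_idx, group_of = [], []
    for g, key in enumerate(keys):
        for i in members[key]:
            atom_idx.append(i)
            group_of.append(g)
    n = len(keys)
    counts = np.zeros((n, n), dtype=int)
    if atom_idx:
        pts = coords[np.array(atom_idx)]
        tree = cKDTree(pts)
        group_of = np.array(group_of)
        for a, b in tree.query_pairs(cutoff):
            gi, gj = group_of[a], group_of[b]
            if gi != gj:
                counts[gi, gj] += 1
                counts[gj, gi] += 1
    return keys, names, counts


def interaction_strength(structure: Structure, node_i: tuple, node_j: tuple,
                         coords: np.ndarray | None = None, cutoff: float = 4.5,
                         nf_table: dict[str, float] | None = None,
                         include_hydrogens: bool = False) -> float:
    """Interaction strength I_ij (percent) between two residue keys."""
    if nf_table is None:
        nf_table = default_nf_table()
    keys, names, counts = pair_counts(structure, coords, None, cutoff,
                                      include_hydrogens)
    try:
        i = keys.index(node_i)
        j = keys.index(node_j)
    except ValueError as exc:
        raise TrajscopeError(f"residue key not in structure: {exc}") from exc
    ni = _resolve_nf(names[i], nf_table)
    nj = _resolve_nf(names[j], nf_table)
    return 100.0 * counts[i, j] / np.sqrt(ni * nj)


def _excluded(keys, i, j, n_exclusion: int) -> bool:
    segi, ri, _ = keys[i]
    segj, rj, _ = keys[j]
    return segi == segj and abs(ri - rj) <= n_exclusion


def interaction_matrix(structure: Structure, coords: np.ndarray | None = None,
                       selection: Selection | None = None, cutoff: float = 4.5,
                       n_exclusion: int = 2,
                       nf_table: dict[str, float] | None = None,
                       include_hydrogens: bool = False):
    """Full I_ij matrix (percent) with sequence neighbours zeroed out."""
    if nf_table is None:
        nf_table = default_nf_table()
    keys, names, counts = pair_counts(structure, coords, selection, cutoff,
                                      include_hydrogens)
    nf = np.array([_resolve_nf(nm, nf_table) for nm in names])
    strengths = 100.0 * counts / np.sqrt(np.outer(nf, nf))
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if _excluded(keys, i, j, n_exclusion):
                strengths[i, j] = strengths[j, i] = 0.0
                counts[i, j] = counts[j, i] = 0
    return keys, names, strengths, counts


def build_psn(structure: Structure, coords: np.ndarray | None = None,
              selection: Selection | None = None, i_min: float = 0.0,
              cutoff: float = 4.5, n_exclusion: int = 2,
              nf_table: dict[str, float] | None = None,
              include_hydrogens: bool = False) -> PSNGraph:
    """Build one frame's PSN: edges where I_ij >= i_min (non-excluded pairs)."""
    if i_min < 0:
        raise TrajscopeError("i_min must be >= 0")
    keys, names, strengths, counts = interaction_matrix(
        structure, coords, selection, cutoff, n_exclusion, nf_table,
        include_hydrogens)
    edges = {}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if counts[i, j] >= 1 and strengths[i, j] >= i_min:
                edges[(i, j)] = (float(strengths[i, j]), int(counts[i, j]))
    return PSNGraph(keys, names, edges, i_min, cutoff, n_exclusion)


def find_hubs(graph: PSNGraph, hub_cutoff: int = 4, strict: bool = False,
              nf_table: dict[str, float] | None = None) -> HubSet:
    """Identify hubs and their interaction percentage I_i.

    A node is a hub when its degree is >= hub_cutoff (inclusive default) or
    > hub_cutoff with ``strict``.  I_i = 100 * sum_j n_ij / N_i over the
    node's edges.
    """
    if nf_table is None:
        nf_table = default_nf_table()
    deg = graph.degree()
    flags = deg > hub_cutoff if strict else deg >= hub_cutoff
    pair_sum = np.zeros(graph.n_nodes)
    for (i, j), (_, n_pairs) in graph.edges.items():
        pair_sum[i] += n_pairs
        pair_sum[j] += n_pairs
    nf = np.array([_resolve_nf(nm, nf_table) for nm in graph.node_names])
    return HubSet(deg, flags, 100.0 * pair_sum / nf, hub_cutoff, strict)


def clusterize(graph: PSNGraph) -> ClusterSet:
    """Connected-component node clusterization.

    Clusters are numbered deterministically by their smallest member node;
    isolated nodes form singleton clusters.
    """
    import networkx as nx

    comps = sorted((sorted(c) for c in nx.connected_components(graph.to_networkx())),
                   key=lambda c: c[0])
    assignment = np.empty(graph.n_nodes, dtype=int)
    sizes = []
    for cid, comp in enumerate(comps):
        for node in comp:
            assignment[node] = cid
        sizes.append(len(comp))
    return ClusterSet(assignment, sizes)


def largest_cluster_curve(structure: Structure, frames: np.ndarray | None,
                          selection: Selection | None, imin_grid,
                          **psn_kwargs) -> np.ndarray:
    """Mean largest-cluster size at each I_min of the grid.

    ``frames`` is an F x N x 3 stack (or None for the structure's own
    coordinates).  The interaction matrix is computed once per frame and
    re-thresholded across the grid (monotone filtration).
    """
    imin_grid = np.asarray(list(imin_grid), dtype=float)
    frame_list = [None] if frames is None else list(frames)
    sizes = np.zeros((len(frame_list), len(imin_grid)))
    for f, coords in enumerate(frame_list):
        keys, names, strengths, counts = interaction_matrix(
            structure, coords, selection, **psn_kwargs)
        for g, imin in enumerate(imin_grid):
            edges = {}
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    if counts[i, j] >= 1 and strengths[i, j] >= imin:
                        edges[(i, j)] = (strengths[i, j], counts[i, j])
            graph = PSNGraph(keys, names, edges, imin, 4.5, 2)
            sizes[f, g] = clusterize(graph).largest_size
    return sizes.mean(axis=0)


def icritic_from_curve(imin_grid, largest_sizes) -> tuple[float | None, bool]:
    """I_critic from a largest-cluster-vs-I_min curve.

    I_critic is the I_min at which the largest cluster is half its size at
    I_min = 0, found by linear interpolation between the bracketing grid
    points.  Returns (value, reached); when the half size is never reached
    on the grid the value is None and ``reached`` is False (I_critic >
    max(grid)).
    """
    grid = np.asarray(list(imin_grid), dtype=float)
    sizes = np.asarray(list(largest_sizes), dtype=float)
    if grid[0] != 0.0:
        raise TrajscopeError("imin grid must include 0.0 as its first point")
    half = sizes[0] / 2.0
    for g in range(1, len(grid)):
        if sizes[g] <= half:
            s0, s1 = sizes[g - 1], sizes[g]
            if s1 == s0:
                return float(grid[g]), True
            frac = (s0 - half) / (s0 - s1)
            return float(grid[g - 1] + frac * (grid[g] - grid[g - 1])), True
    return None, False


def icritic(structure: Structure, frames: np.ndarray | None,
            selection: Selection | None, imin_grid, **psn_kwargs):
    """Largest-cluster curve over an I_min grid and the derived I_critic.

    Returns (grid array, mean largest-size array, I_critic or None, reached).
    """
    grid = np.asarray(list(imin_grid), dtype=float)
    sizes = largest_cluster_curve(structure, frames, selection, grid, **psn_kwargs)
    value, reached = icritic_from_curve(grid, sizes)
    return grid, sizes, value, reached


def ensemble_stats(structure: Structure, frames: np.ndarray,
                   selection: Selection | None = None, i_min: float = 0.0,
                   stability: float = 0.5, hub_cutoff: int = 4,
                   strict_hubs: bool = False,
                   hub_correlation_mode: str = "joint",
                   **psn_kwargs) -> EnsembleStats:
    """Per-edge and per-hub frame statistics over a trajectory.

    An edge or hub is stable when present in more than ``stability`` of the
    frames.  Hub correlation reports node pairs that are simultaneous hubs
    in more than ``stability`` of the frames (``joint`` mode; ``matching``
    mode instead counts frames where the two hub indicators agree).
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise TrajscopeError("need at least one frame")
    n_frames = frames.shape[0]
    edge_count: dict[tuple[int, int], int] = {}
    hub_indicator = []
    n_nodes = None
    for coords in frames:
        graph = build_psn(structure, coords, selection, i_min, **psn_kwargs)
        n_nodes = graph.n_nodes
        for e in graph.edges:
            edge_count[e] = edge_count.get(e, 0) + 1
        hub_indicator.append(find_hubs(graph, hub_cutoff, strict_hubs).hub_flags)
    hubs = np.array(hub_indicator)  # F x N bool
    edge_freq = {e: c / n_frames for e, c in edge_count.items()}
    hub_freq = {i: float(hubs[:, i].mean()) for i in range(n_nodes)
                if hubs[:, i].any()}
    stable_edges = sorted(e for e, f in edge_freq.items() if f > stability)
    stable_hubs = sorted(i for i, f in hub_freq.items() if f > stability)
    pairs = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if hub_correlation_mode == "joint":
                score = float((hubs[:, i] & hubs[:, j]).mean())
            elif hub_correlation_mode == "matching":
                score = float((hubs[:, i] == hubs[:, j]).mean())
            else:
                raise TrajscopeError(
                    f"unknown hub correlation mode {hub_correlation_mode!r}")
            if score > stability and (hubs[:, i].any() or hubs[:, j].any()):
                pairs.append((i, j, score))
    return EnsembleStats(edge_freq, hub_freq, stable_edges, stable_hubs,
                         pairs, stability, n_frames)
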