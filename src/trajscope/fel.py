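"""Free-energy-surface analysis on microstate timeseries.

A finely clustered trajectory — one integer microstate label per frame —
is turned into a transition network: nodes are microstates weighted by
their populations, directed links carry the transition counts sampled at a
chosen lag.  From the row-normalized transition matrix T, two kinetic
coordinates are solved analytically:

* the committor p_fold (probability of reaching a target microstate before
  a competing one), from the linear system p_i = sum_j T_ij p_j with
  boundary values 1 (target) and 0 (source);
* the mean first passage time, m = 1 + T m with m(target) = 0, in lag units.

The cut-based free energy profile (cFEP) ranks microstates by kinetic
proximity to a reference state, sweeps a cut through that ordering, and at
each cut reports the progress coordinate x = Z_A / Z (cumulative relative
partition function) against the barrier ordinate dG = -ln(Z_AB / Z) in kT,
where Z_AB is the transition flux crossing the cut.  Because every pathway
to the reference crosses every cut, the profile preserves barrier heights;
the profile maximum locates the minimum-flux (min-cut) interface.

Kinetic grouping analysis (KGA) instead groups microstates into basins by
empirical commitment probabilities: p_commit(i -> j) is the fraction of
visits to i from which the trajectory reaches j within a commitment time
tau_commit, and states with p_commit >= 0.5 fall in one basin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, TrajscopeError


@dataclass
class MicrostateTrajectory:
    """Frame-ordered microstate labels with dense internal relabeling."""

    labels: np.ndarray            # internal dense labels, 0..n_states-1
    original_labels: np.ndarray   # user labels per internal state
    interval: int = 1             # saving interval metadata (frames)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_states(self) -> int:
        return self.original_labels.shape[0]

    @property
    def populations(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_states)

    @classmethod
    def from_labels(cls, labels, interval: int = 1) -> "MicrostateTrajectory":
        labels = np.asarray(labels, dtype=int)
        if labels.ndim != 1 or labels.size == 0:
            raise TrajscopeError("label series must be a non-empty 1-D sequence")
        originals, dense = np.unique(labels, return_inverse=True)
        return cls(dense, originals, interval)

    @classmethod
    def from_file(cls, path, interval: int = 1) -> "MicrostateTrajectory":
        """Read one integer label per line (the cluster module's output)."""
        labels = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                try:
                    labels.append(int(line))
                except ValueError as exc:
                    raise TrajscopeError(
                        f"{path}: line {lineno}: not an integer label") from exc
        return cls.from_labels(labels, interval)

    def internal(self, original_label) -> int:
        idx = np.searchsorted(self.original_labels, original_label)
        if idx >= self.n_states or self.original_labels[idx] != original_label:
            raise TrajscopeError(f"unknown microstate label {original_label}")
        return int(idx)


@dataclass
class TransitionNetwork:
    counts: np.ndarray            # directed transition counts at the lag
    weights: np.ndarray           # state visit counts
    lag: int
    transition_matrix: np.ndarray = field(init=False)

    def __post_init__(self):
        rows = self.counts.sum(axis=1, keepdims=True)
        T = np.zeros_like(self.counts, dtype=float)
        np.divide(self.counts, rows, out=T, where=rows > 0)
        self.transition_matrix = T

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass
class KineticCoordinate:
    kind: str                     # "pfold" | "mfpt"
    values: np.ndarray
    boundary: dict


@dataclass
class FepProfile:
    x: np.ndarray                 # Z_A / Z, non-decreasing
    dg: np.ndarray                # -ln(Z_AB / Z), kT
    order: np.ndarray             # state indices sorted by kinetic proximity
    cut_flux: np.ndarray          # Z_AB per cut
    coordinate_kind: str

    def barrier(self) -> tuple[float, float]:
        """(x, dG) of the profile maximum over interior cuts."""
        i = int(np.argmax(self.dg))
        return float(self.x[i]), float(self.dg[i])


@dataclass
class BasinPartition:
    basin_of: np.ndarray          # basin id per state, -1 = unassigned
    tau_commit: int
    heavy_states: np.ndarray
    p_commit_heavy: np.ndarray
    representatives: list[int]


def build_network(mtraj: MicrostateTrajectory, lag: int = 1,
                  symmetrize: bool = False) -> TransitionNetwork:
    """Count transitions (s_t, s_{t+lag}) into a transition network."""
    if lag < 1:
        raise TrajscopeError("lag must be >= 1")
    if mtraj.n_frames <= lag:
        raise TrajscopeError("trajectory shorter than the lag")
    n = mtraj.n_states
    if n < 2:
        raise DegenerateInputError("degenerate network: a single microstate")
    counts = np.zeros((n, n))
    np.add.at(counts, (mtraj.labels[:-lag], mtraj.labels[lag:]), 1.0)
    if symmetrize:
        counts = 0.5 * (counts + counts.T)
    return TransitionNetwork(counts, mtraj.populations.astype(float), lag)


def _reachable_to(T: np.ndarray, target: int) -> np.ndarray:
    """States from which ``target`` is reachable along positive-probability links."""
    n = T.shape[0]
    reach = np.zeros(n, dtype=bool)
    reach[target] = True
    frontier = [target]
    incoming = [np.where(T[:, j] > 0)[0] for j in range(n)]
    while frontier:
        j = frontier.pop()
        for i in incoming[j]:
            if not reach[i]:
                reach[i] = True
                frontier.append(int(i))
    return reach


def pfold(network: TransitionNetwork, folded: int, unfolded: int) -> KineticCoordinate:
    """Analytic committor to ``folded`` before ``unfolded``.

    Solves the harmonic system p_i = sum_j T_ij p_j for interior states with
    p(folded) = 1, p(unfolded) = 0.
    """
    T = network.transition_matrix
    n = network.n_states
    if folded == unfolded:
        raise TrajscopeError("folded and unfolded nodes must differ")
    for b in (folded, unfolded):
        if not 0 <= b < n:
            raise TrajscopeError(f"boundary node {b} not in network")
        if not _reachable_to(T, b).all():
            raise TrajscopeError(
                f"boundary node {b} unreachable from part of the network")
    interior = np.array([i for i in range(n) if i not in (folded, unfolded)])
    p = np.zeros(n)
    p[folded] = 1.0
    if interior.size:
        A = np.eye(interior.size) - T[np.ix_(interior, interior)]
        b_vec = T[interior, folded]
        p[interior] = np.linalg.solve(A, b_vec)
    p = np.clip(p, 0.0, 1.0)
    return KineticCoordinate("pfold", p, {"folded": folded, "unfolded": unfolded})


def mfpt(network: TransitionNetwork, target: int) -> KineticCoordinate:
    """Analytic mean first passage time to ``target``, in lag units.

    States from which the target is unreachable are flagged infinite.
    """
    T = network.transition_matrix
    n = network.n_states
    if not 0 <= target < n:
        raise TrajscopeError(f"target node {target} not in network")
    reach = _reachable_to(T, target)
    m = np.full(n, np.inf)
    m[target] = 0.0
    interior = np.array([i for i in range(n) if i != target and reach[i]])
    if interior.size:
        A = np.eye(interior.size) - T[np.ix_(interior, interior)]
        m[interior] = np.linalg.solve(A, np.ones(interior.size))
    return KineticCoordinate("mfpt", m, {"target": target})


def cfep(network: TransitionNetwork, coordinate: KineticCoordinate) -> FepProfile:
    """Cut-based free energy profile along a kinetic coordinate.

    States are ordered by kinetic proximity to the reference (descending
    p_fold or ascending mfpt); cuts fall between consecutive distinct
    coordinate values, ties broken by state weight then id.  Each cut
    yields x = Z_A / Z (Z from the state weights) and dG = -ln(Z_AB / Z_T)
    with Z_AB the transition count crossing the cut (both directions) and
    Z_T the total sampled transition count; the choice of Z_T fixes only the
    additive constant of the profile.
    """
    values = np.asarray(coordinate.values, float)
    n = network.n_states
    if values.shape != (n,):
        raise TrajscopeError("coordinate does not cover all network nodes")
    proximity = values if coordinate.kind == "pfold" else -values
    w = network.weights
    # nearer-to-reference first; ties by weight (heavier first) then id
    order = np.lexsort((np.arange(n), -w, -proximity))
    Z = w.sum()
    counts = network.counts
    in_a = np.zeros(n, dtype=bool)
    xs, dgs, fluxes = [], [], []
    for pos in range(n - 1):
        s = order[pos]
        in_a[s] = True
        if proximity[order[pos]] == proximity[order[pos + 1]]:
            continue  # cuts only between distinct coordinate values
        z_a = w[in_a].sum()
        cross = counts[np.ix_(in_a, ~in_a)].sum() + counts[np.ix_(~in_a, in_a)].sum()
        xs.append(z_a / Z)
        fluxes.append(cross)
        total = counts.sum()
        dgs.append(-np.log(cross / total) if cross > 0 else np.inf)
    return FepProfile(np.array(xs), np.array(dgs), order, np.array(fluxes),
                      coordinate.kind)


def _next_occurrence(labels: np.ndarray, n_states: int) -> np.ndarray:
    """next[j, t]: smallest t' >= t with labels[t'] == j (F if never)."""
    f = labels.shape[0]
    nxt = np.full((n_states, f + 1), f, dtype=np.int64)
    for t in range(f - 1, -1, -1):
        nxt[:, t] = nxt[:, t + 1]
        nxt[labels[t], t] = t
    return nxt


def commitment_matrix(mtraj: MicrostateTrajectory, subset=None,
                      tau_commit: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Empirical commitment probabilities between microstates.

    p_commit(i -> j) is the fraction of occurrences of i (sliding starts,
    overlapping windows, start frames t with t + tau inside the trajectory)
    from which j is visited within ``tau_commit`` frames; the start frame
    itself counts, so p(i -> i) = 1.  Returns (subset state ids, matrix).
    """
    if tau_commit >= mtraj.n_frames:
        raise TrajscopeError("tau_commit must be smaller than the frame count")
    if tau_commit < 1:
        raise TrajscopeError("tau_commit must be >= 1")
    if subset is None:
        subset = np.arange(mtraj.n_states)
    subset = np.asarray(subset, dtype=int)
    labels = mtraj.labels
    f = mtraj.n_frames
    nxt = _next_occurrence(labels, mtraj.n_states)
    p = np.zeros((subset.size, subset.size))
    max_start = f - 1 - tau_commit
    for a, i in enumerate(subset):
        starts = np.where(labels[:max_start + 1] == i)[0]
        if starts.size == 0:
            continue
        for b, j in enumerate(subset):
            reached = nxt[j, starts] <= starts + tau_commit
            p[a, b] = reached.mean()
    return subset, p


def kga(mtraj: MicrostateTrajectory, tau_commit: int, n_heavy: int | None = None,
        mutual: bool = False) -> BasinPartition:
    """Kinetic grouping analysis: partition microstates into basins.

    The ``n_heavy`` most populated microstates are grouped by the transitive
    closure of the relation p_commit >= 0.5 (by default the relation holds
    when max(p_ij, p_ji) >= 0.5; ``mutual`` requires both directions).  In
    the post-processing step every remaining microstate is assigned to the
    basin it commits to with probability >= 0.5 within ``tau_commit``, and
    stays unassigned otherwise.
    """
    import warnings

    import networkx as nx

    n = mtraj.n_states
    if n_heavy is None:
        n_heavy = n
    if n_heavy > n:
        warnings.warn(f"n_heavy={n_heavy} exceeds the {n} states; clamped",
                      stacklevel=2)
        n_heavy = n
    pops = mtraj.populations
    heavy = np.sort(np.lexsort((np.arange(n), -pops))[:n_heavy])
    _, p = commitment_matrix(mtraj, heavy, tau_commit)
    g = nx.Graph()
    g.add_nodes_from(range(heavy.size))
    for a in range(heavy.size):
        for b in range(a + 1, heavy.size):
            linked = (min(p[a, b], p[b, a]) >= 0.5 if mutual
                      else max(p[a, b], p[b, a]) >= 0.5)
            if linked:
                g.add_edge(a, b)
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: c[0])
    basin_of = np.full(n, -1, dtype=int)
    representatives = []
    for basin_id, comp in enumerate(comps):
        members = heavy[comp]
        for s in members:
            basin_of[s] = basin_id
        representatives.append(int(members[np.argmax(pops[members])]))
    # post-processing: commit the light states to the isolated basins
    light = [s for s in range(n) if basin_of[s] < 0]
    if light and comps:
        labels = mtraj.labels
        f = mtraj.n_frames
        nxt = _next_occurrence(labels, n)
        max_start = f - 1 - tau_commit
        basin_next = []
        for comp in comps:
            members = heavy[comp]
            basin_next.append(np.min(nxt[members], axis=0))
        for s in light:
            starts = np.where(labels[:max_start + 1] == s)[0]
            if starts.size == 0:
                continue
            probs = [ (bn[starts] <= starts + tau_commit).mean()
                      for bn in basin_next ]
            best = int(np.argmax(probs))
            if probs[best] >= 0.5:
                basin_of[s] = best
    return BasinPartition(basin_of, tau_commit, heavy, p, representatives)


def commit_to_representative(mtraj: MicrostateTrajectory, representative: int,
                             tau_commit: int) -> np.ndarray:
    """Single-basin mode: p_commit of every state to one representative."""
    subset, p = commitment_matrix(mtraj, None, tau_commit)
    return p[:, representative]


def fpt_distribution(mtraj: MicrostateTrajectory, target: int,
                     start_state: int | None = None):
    """Empirical first-passage-time distribution to a target microstate.

    Starts are the occurrences of ``start_state`` (default: the target
    itself, measuring first-return times) that are followed by a later
    visit of the target; the FPT is the number of frames until that visit.
    Returns (sorted unique FPTs, counts).  The log-log plot of this
    histogram typically separates intra- from inter-basin timescales and
    guides the choice of tau_commit.
    """
    labels = mtraj.labels
    if not (labels == target).any():
        raise TrajscopeError(f"target state {target} never visited")
    if start_state is None:
        start_state = target
    f = mtraj.n_frames
    nxt = _next_occurrence(labels, mtraj.n_states)
    starts = np.where(labels[:-1] == start_state)[0]
    fpts = nxt[target, starts + 1] - starts
    fpts = fpts[starts + fpts <= f - 1]  # drop starts never reaching the target
    values, counts = np.unique(fpts, return_counts=True)
    return values.astype(int), counts
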