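"""Conformational clustering of trajectory frames.

Frame-to-frame distance is either RMSD (optionally after optimal
superposition, the default) or DRMS, the root-mean-square difference of the
two frames' intramolecular distance matrices (superposition-free by
construction).  Three algorithms are provided:

* ``leader``: single sequential pass; a frame joins an existing cluster
  whose center lies within the threshold, else founds a new cluster.  The
  comparison modality is ``nearest`` (all centers, closest wins — default),
  ``first-fit`` (first center within threshold), or ``backward`` (scan the
  clusters of frames n-1, n-2, ... and stop at the first hit — fast on
  time-correlated, non-Markovian frame sequences).  The outcome depends on
  frame order by design.
* ``qt``: quality-threshold-like; each candidate cluster collects all
  remaining frames within the threshold of its reference frame (the
  threshold is the cluster *radius*), the largest candidate is extracted,
  and the procedure repeats.  Ties break toward the lower reference index.
* ``hierarchical``: average-linkage agglomerative merging until the
  inter-cluster distance exceeds the threshold.

A two-pass scheme clusters a frame subset first, then sweeps all frames,
assigning each to the nearest center within the threshold; frames beyond
every center found new clusters that later frames can join.  The distance
matrix can be persisted (plain-text header + binary upper triangle) and
reused across thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .errors import TrajscopeError

_DMAT_MAGIC = "#trajscope-dmat v1"


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # per-frame cluster id; -1 = isolated
    centers: list[int]            # center frame index per cluster
    algorithm: str
    threshold: float
    metric: str
    modality: str | None = None
    passes: int = 1
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def sizes(self) -> list[int]:
        return [int(np.sum(self.labels == c)) for c in range(self.n_clusters)]


def frame_distance(frame_a: np.ndarray, frame_b: np.ndarray,
                   metric: str = "rmsd", superpose: bool = True) -> float:
    """Distance (A) between two N x 3 coordinate frames."""
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise TrajscopeError("frames must be equal-size N x 3 selections")
    if metric == "rmsd":
        if superpose:
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            _, rssd = Rotation.align_vectors(ac, bc)
            return float(rssd / np.sqrt(a.shape[0]))
        return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
    if metric == "drms":
        da = pdist(a)
        db = pdist(b)
        return float(np.sqrt(((da - db) ** 2).mean()))
    raise TrajscopeError(f"unknown metric {metric!r}")


def distance_matrix(frames: np.ndarray, metric: str = "rmsd",
                    superpose: bool = True) -> np.ndarray:
    """Full symmetric frame-frame distance matrix."""
    frames = np.asarray(frames, float)
    f = frames.shape[0]
    mat = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            mat[i, j] = mat[j, i] = frame_distance(frames[i], frames[j],
                                                   metric, superpose)
    return mat


def leader(frames: np.ndarray, threshold: float, modality: str = "nearest",
           metric: str = "rmsd", superpose: bool = True) -> ClusterAssignment:
    """Sequential leader-like clustering (order-dependent by design)."""
    if threshold < 0:
        raise TrajscopeError("threshold must be >= 0")
    if modality not in ("nearest", "first-fit", "backward"):
        raise TrajscopeError(f"unknown leader modality {modality!r}")
    frames = np.asarray(frames, float)
    f = frames.shape[0]
    labels = np.full(f, -1, dtype=int)
    centers: list[int] = []
    for n in range(f):
        assigned = -1
        if centers:
            if modality == "nearest":
                dists = [frame_distance(frames[n], frames[c], metric, superpose)
                         for c in centers]
                best = int(np.argmin(dists))
                if dists[best] <= threshold:
                    assigned = best
            elif modality == "first-fit":
                for cid, c in enumerate(centers):
                    if frame_distance(frames[n], frames[c], metric,
                                      superpose) <= threshold:
                        assigned = cid
                        break
            else:  # backward: clusters of frames n-1, n-2, ... then the rest
                seen = []
                for prev in range(n - 1, -1, -1):
                    cid = int(labels[prev])
                    if cid not in seen:
                        seen.append(cid)
                for cid in seen:
                    if frame_distance(frames[n], frames[centers[cid]], metric,
                                      superpose) <= threshold:
                        assigned = cid
                        break
        if assigned < 0:
            centers.append(n)
            assigned = len(centers) - 1
        labels[n] = assigned
    return ClusterAssignment(labels, centers, "leader", threshold, metric,
                             modality=modality)


def qt_like(dmat: np.ndarray, threshold: float) -> ClusterAssignment:
    """QT-like clustering on a precomputed distance matrix.

    Iteratively extracts the largest candidate cluster — all remaining
    frames within ``threshold`` of a reference frame — so every member lies
    within the cluster radius of its center.  Equal-size candidates break
    toward the lower reference frame index.
    """
    dmat = np.asarray(dmat, float)
    f = dmat.shape[0]
    labels = np.full(f, -1, dtype=int)
    centers: list[int] = []
    remaining = np.ones(f, dtype=bool)
    while remaining.any():
        best_center, best_members = -1, None
        for i in np.where(remaining)[0]:
            members = np.where(remaining & (dmat[i] <= threshold))[0]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = int(i), members
        cid = len(centers)
        centers.append(best_center)
        labels[best_members] = cid
        remaining[best_members] = False
    return ClusterAssignment(labels, centers, "qt", threshold, "precomputed")


def hierarchical(dmat: np.ndarray, threshold: float) -> ClusterAssignment:
    """Average-linkage agglomerative clustering of a distance matrix.

    Merging stops when the (average-linkage) inter-cluster distance exceeds
    the threshold.  The result does not depend on frame order; cluster ids
    are renumbered by smallest member frame and the center is the medoid
    (minimum summed intra-cluster distance, lower index on ties).
    """
    dmat = np.asarray(dmat, float)
    if dmat.ndim != 2 or dmat.shape[0] != dmat.shape[1] or \
            not np.allclose(dmat, dmat.T, atol=1e-12):
        raise TrajscopeError("distance matrix must be square and symmetric")
    f = dmat.shape[0]
    if f == 1:
        return ClusterAssignment(np.zeros(1, dtype=int), [0], "hierarchical",
                                 threshold, "precomputed")
    link = linkage(squareform(dmat, checks=False), method="average")
    raw = fcluster(link, t=threshold, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    ordered = sorted(clusters.values(), key=lambda mem: mem[0])
    labels = np.empty(f, dtype=int)
    centers = []
    for cid, members in enumerate(ordered):
        for m in members:
            labels[m] = cid
        sub = dmat[np.ix_(members, members)]
        centers.append(members[int(np.argmin(sub.sum(axis=1)))])
    return ClusterAssignment(labels, centers, "hierarchical", threshold,
                             "precomputed")


def two_pass(frames: np.ndarray, subset_stride: int, threshold: float,
             algorithm: str = "qt", metric: str = "rmsd",
             superpose: bool = True, modality: str = "nearest") -> ClusterAssignment:
    """Two-pass clustering: cluster a frame subset, then sweep all frames.

    Pass 2 assigns each frame to the nearest pass-1 center within the
    threshold; a frame beyond every center becomes a new cluster center that
    later frames can join (isolated-frames-as-new-centers rule).
    """
    frames = np.asarray(frames, float)
    f = frames.shape[0]
    if subset_stride >= f:
        raise TrajscopeError(f"stride {subset_stride} >= frame count {f}")
    if subset_stride < 1:
        raise TrajscopeError("stride must be >= 1")
    subset = list(range(0, f, subset_stride))
    sub_frames = frames[subset]
    if algorithm == "leader":
        first = leader(sub_frames, threshold, modality, metric, superpose)
    elif algorithm == "qt":
        first = qt_like(distance_matrix(sub_frames, metric, superpose), threshold)
    elif algorithm == "hierarchical":
        first = hierarchical(distance_matrix(sub_frames, metric, superpose),
                             threshold)
    else:
        raise TrajscopeError(f"unknown algorithm {algorithm!r}")
    centers = [subset[c] for c in first.centers]
    labels = np.full(f, -1, dtype=int)
    for n in range(f):
        dists = [frame_distance(frames[n], frames[c], metric, superpose)
                 for c in centers]
        best = int(np.argmin(dists))
        if dists[best] <= threshold:
            labels[n] = best
        else:
            centers.append(n)
            labels[n] = len(centers) - 1
    return ClusterAssignment(labels, centers, algorithm, threshold, metric,
                             modality=modality if algorithm == "leader" else None,
                             passes=2, params={"stride": subset_stride})


def save_distance_matrix(path, dmat: np.ndarray, metric: str,
                         selection: str = "", superpose: bool = True) -> None:
    """Persist a distance matrix: text header plus binary upper triangle."""
    dmat = np.asarray(dmat, float)
    condensed = squareform(dmat, checks=False).astype("<f8")
    header = (f"{_DMAT_MAGIC}\n#metric={metric}\n#selection={selection}\n"
              f"#superpose={superpose}\n#n_frames={dmat.shape[0]}\n#end\n")
    with open(path, "wb") as fh:
        fh.write(header.encode())
        fh.write(condensed.tobytes())


def load_distance_matrix(path, expect_metric: str | None = None,
                         expect_selection: str | None = None,
                         expect_superpose: bool | None = None) -> np.ndarray:
    """Load a persisted distance matrix, refusing silent parameter misuse.

    When ``expect_*`` values are given they are checked against the stored
    header; a mismatch is an error rather than a silent reinterpretation.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    end = data.find(b"#end\n")
    if end < 0 or not data.startswith(_DMAT_MAGIC.encode()):
        raise TrajscopeError(f"{path}: not a trajscope distance-matrix file")
    meta = {}
    for line in data[:end].decode().splitlines()[1:]:
        key, _, value = line.lstrip("#").partition("=")
        meta[key] = value
    if expect_metric is not None and meta.get("metric") != expect_metric:
        raise TrajscopeError(
            f"distance matrix was computed with metric {meta.get('metric')!r}, "
            f"not {expect_metric!r}")
    if expect_selection is not None and meta.get("selection") != expect_selection:
        raise TrajscopeError("distance matrix was computed on a different selection")
    if expect_superpose is not None and meta.get("superpose") != str(expect_superpose):
        raise TrajscopeError("distance matrix superposition flag mismatch")
    n = int(meta["n_frames"])
    condensed = np.frombuffer(data[end + 5:], dtype="<f8")
    if condensed.size != n * (n - 1) // 2:
        raise TrajscopeError(f"{path}: payload size does not match n_frames={n}")
    return squareform(condensed)
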