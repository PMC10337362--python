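"""Template-based trajectory features: DTW, key-point extraction, distances.

The screening idea: every healthy-control drawing of a given test block
should resemble the "standard answer" for that block.  A reference
trajectory (template) is picked from healthy controls as the subset member
with the smallest summed dynamic-time-warping distance (DTWD) to its peers.
Every trajectory — template included — is then compressed into an ordered
sequence of *key points*: k-means cluster centers of its pen-down points
(codebook size 40 by default), cleaned by a temporal-restructuring pass that
removes points lying outside the time span bracketed by the neighboring
clusters' mean times, and re-averaged.  Three distances between a
trajectory's key points and the template's quantify abnormality: DTWD over
the key-point sequences, and the index-paired mean Euclidean distance with
or without relative weights (a cluster's share of the trajectory's pen-down
samples).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.ndimage import gaussian_filter1d

from ._dtw import dtw_full_cost, dtw_window
from .core import Trajectory, block_key_str

DEFAULT_CODEBOOK_SIZE = 40
DEFAULT_SIGMA = 0.1
DEFAULT_SUBSET_SIZE = 10
DEFAULT_RADIUS = 1


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

def _as_xy(seq) -> np.ndarray:
    a = np.asarray(seq, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] == 0:
        raise ValueError("expected a nonempty (n, 2) point sequence")
    return a


def dtw_distance(a, b) -> float:
    """Exact DTW distance: minimal summed Euclidean local cost over all
    monotone alignment paths (unconstrained, no path-length normalization)."""
    a = _as_xy(a)
    b = _as_xy(b)
    return float(dtw_full_cost(
        np.ascontiguousarray(a[:, 0]), np.ascontiguousarray(a[:, 1]),
        np.ascontiguousarray(b[:, 0]), np.ascontiguousarray(b[:, 1]),
    ))


def _reduce_by_half(a: np.ndarray) -> np.ndarray:
    n2 = len(a) // 2
    return 0.5 * (a[: 2 * n2 : 2] + a[1 : 2 * n2 : 2])


def _expanded_window(path_i, path_j, radius, n, m):
    """Project a coarse alignment path to the next finer level, dilate it by
    ``radius`` (in coarse cells), and return per-row column bounds."""
    lo = np.full(n, m, dtype=np.int64)
    hi = np.full(n, -1, dtype=np.int64)
    for ci, cj in zip(path_i, path_j):
        for a in range(ci - radius, ci + radius + 1):
            for b in range(cj - radius, cj + radius + 1):
                # coarse cell (a, b) covers fine rows 2a..2a+1, cols 2b..2b+1
                j0 = max(0, 2 * b)
                j1 = min(m - 1, 2 * b + 1)
                if j1 < j0:
                    continue
                for i in (2 * a, 2 * a + 1):
                    if 0 <= i < n:
                        if j0 < lo[i]:
                            lo[i] = j0
                        if j1 > hi[i]:
                            hi[i] = j1
    # guarantee full coverage and monotone staircase shape
    for i in range(n):
        if hi[i] < lo[i]:  # uncovered row: bridge from neighbors
            lo[i] = lo[i - 1] if i > 0 else 0
            hi[i] = hi[i - 1] if i > 0 else m - 1
    lo[0] = 0
    hi[n - 1] = m - 1
    return lo, hi


def _fastdtw(ax, ay, bx, by, radius):
    n, m = len(ax), len(bx)
    min_size = radius + 2
    if n <= min_size or m <= min_size:
        lo = np.zeros(n, dtype=np.int64)
        hi = np.full(n, m - 1, dtype=np.int64)
        return dtw_window(ax, ay, bx, by, lo, hi)
    _, pi, pj = _fastdtw(
        _reduce_by_half(ax), _reduce_by_half(ay),
        _reduce_by_half(bx), _reduce_by_half(by), radius,
    )
    lo, hi = _expanded_window(pi, pj, radius, n, m)
    return dtw_window(ax, ay, bx, by, lo, hi)


def fast_dtw_distance(a, b, radius: int = DEFAULT_RADIUS) -> float:
    """Multilevel coarse-to-fine DTW approximation.

    The sequences are recursively halved, aligned at the coarsest level, and
    the alignment is refined through the levels inside a corridor of width
    controlled by ``radius``.  Exact whenever ``radius >= max(len(a),
    len(b))`` (the corridor then covers the whole matrix).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    a = _as_xy(a)
    b = _as_xy(b)
    cost, _, _ = _fastdtw(
        np.ascontiguousarray(a[:, 0]), np.ascontiguousarray(a[:, 1]),
        np.ascontiguousarray(b[:, 0]), np.ascontiguousarray(b[:, 1]),
        int(radius),
    )
    return float(cost)


def pairwise_dtwd(seqs, method: str = "fast", radius: int = DEFAULT_RADIUS) -> np.ndarray:
    """Symmetric matrix of pairwise DTW distances (zero diagonal)."""
    if method not in ("exact", "fast"):
        raise ValueError("method must be 'exact' or 'fast'")
    seqs = [_as_xy(s) for s in seqs]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    k = len(seqs)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if method == "exact":
                d = dtw_distance(seqs[i], seqs[j])
            else:
                d = fast_dtw_distance(seqs[i], seqs[j], radius=radius)
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# template selection
# ---------------------------------------------------------------------------

def trajectory_points(traj: Trajectory) -> np.ndarray:
    """Pen-down (x, y) points of a trajectory, in temporal order."""
    mask = traj.pen_down
    return np.column_stack([traj.x[mask], traj.y[mask]])


def select_template(
    hc_trajs: list[Trajectory],
    subset_size: int = DEFAULT_SUBSET_SIZE,
    seed: int = 0,
    method: str = "fast",
    radius: int = DEFAULT_RADIUS,
    _dtwd_cache: dict | None = None,
) -> Trajectory:
    """Pick the reference trajectory from a healthy-control pool.

    A random subset of ``subset_size`` trajectories (without replacement,
    capped at the pool size) is drawn; the member minimizing the sum of its
    DTW distances to the rest of the subset is the template.  The pool is
    ordered by subject id before sampling so the choice is invariant to the
    caller's ordering; ties go to the lowest subject id.
    """
    if not hc_trajs:
        raise ValueError("empty healthy-control pool")
    pool = sorted(hc_trajs, key=lambda tr: tr.subject_id)
    if len(pool) == 1:
        return pool[0]
    rng = np.random.default_rng(seed)
    size = min(subset_size, len(pool))
    idx = rng.choice(len(pool), size=size, replace=False)
    subset = [pool[i] for i in sorted(idx)]
    if len(subset) == 1:
        return subset[0]

    pts = [trajectory_points(tr) for tr in subset]
    k = len(subset)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            key = None
            if _dtwd_cache is not None:
                key = tuple(sorted((subset[i].subject_id, subset[j].subject_id)))
            if key is not None and key in _dtwd_cache:
                d = _dtwd_cache[key]
            else:
                if method == "exact":
                    d = dtw_distance(pts[i], pts[j])
                else:
                    d = fast_dtw_distance(pts[i], pts[j], radius=radius)
                if key is not None:
                    _dtwd_cache[key] = d
            D[i, j] = D[j, i] = d
    row_sums = D.sum(axis=1)
    best = row_sums.min()
    candidates = [subset[i] for i in np.flatnonzero(row_sums == best)]
    return min(candidates, key=lambda tr: tr.subject_id)


# ---------------------------------------------------------------------------
# smoothing and vector quantization
# ---------------------------------------------------------------------------

def gaussian_smooth(traj: Trajectory, sigma: float = DEFAULT_SIGMA) -> Trajectory:
    """Gaussian-filter x and y independently over sample index.

    ``sigma`` is in sample-index units (reflect boundary); pressure and time
    are untouched; ``sigma == 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return traj
    return traj.replace(
        x=gaussian_filter1d(traj.x, sigma, mode="reflect"),
        y=gaussian_filter1d(traj.y, sigma, mode="reflect"),
    )


@dataclass
class RawCluster:
    """A k-means cluster of pen-down points, with member timestamps."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray

    @property
    def mean_t(self) -> float:
        return float(self.t.mean())

    @property
    def center(self) -> tuple[float, float]:
        return (float(self.x.mean()), float(self.y.mean()))

    @property
    def n_points(self) -> int:
        return len(self.t)


def vq_cluster(points: np.ndarray, t: np.ndarray, k: int = DEFAULT_CODEBOOK_SIZE,
               seed: int = 0) -> list[RawCluster]:
    """k-means vector quantization of pen-down points.

    Clustering is spatial only — timestamps ride along but never enter the
    distance.  Seeded ++-style initialization; if a cluster comes back empty
    the run restarts with a shifted seed (up to 10 times), after which empty
    clusters are dropped.  The effective codebook size is capped at the
    number of distinct points.
    """
    points = _as_xy(points)
    t = np.asarray(t, dtype=float)
    if len(points) != len(t):
        raise ValueError("points and timestamps must align")
    n_distinct = len(np.unique(points, axis=0))
    k_eff = min(k, n_distinct)
    if k_eff < 1:
        raise ValueError("need at least one pen-down point")
    labels = None
    for attempt in range(10):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, lab = kmeans2(points, k_eff, minit="++",
                             seed=np.random.default_rng(seed + attempt))
        counts = np.bincount(lab, minlength=k_eff)
        labels = lab
        if counts.min() > 0:
            break
    clusters = []
    for c in range(k_eff):
        mask = labels == c
        if not mask.any():
            continue  # empty after max restarts: drop
        clusters.append(RawCluster(points[mask, 0], points[mask, 1], t[mask]))
    return clusters


# ---------------------------------------------------------------------------
# temporal restructuring and key points
# ---------------------------------------------------------------------------

@dataclass
class KeyPointSequence:
    """Temporally ordered key points of one trajectory.

    Parallel arrays: center coordinates, mean member time, member count and
    relative weight (member count over the trajectory's pen-down total).
    ``mean_t`` is strictly increasing.
    """

    cx: np.ndarray
    cy: np.ndarray
    mean_t: np.ndarray
    n_points: np.ndarray
    weight: np.ndarray
    subject_id: str = ""
    part: str = ""
    block: int = 0
    codebook_size: int = DEFAULT_CODEBOOK_SIZE

    def __len__(self) -> int:
        return len(self.cx)

    def centers(self) -> np.ndarray:
        return np.column_stack([self.cx, self.cy])


def temporal_restructure(clusters: list[RawCluster], total_points: int | None = None,
                         **meta) -> KeyPointSequence:
    """Clean spatial clusters into a temporally consistent key-point sequence.

    Clusters are ordered by their original mean timestamps.  In one pass,
    each cluster sheds member points earlier than the previous cluster's
    mean time or later than the next cluster's mean time (neighbor means
    taken *before* any removal); emptied clusters are dropped and centers
    and mean times are recomputed from the survivors.  A final stable sort
    by recomputed mean time — merging clusters whose mean times coincide
    exactly — guarantees strictly increasing mean times.
    """
    if not clusters:
        raise ValueError("no clusters to restructure")
    order = np.argsort([c.mean_t for c in clusters], kind="stable")
    ordered = [clusters[i] for i in order]
    means = [c.mean_t for c in ordered]
    survivors: list[RawCluster] = []
    for i, c in enumerate(ordered):
        lo = means[i - 1] if i > 0 else -np.inf
        hi = means[i + 1] if i + 1 < len(ordered) else np.inf
        keep = (c.t >= lo) & (c.t <= hi)
        if keep.any():
            survivors.append(RawCluster(c.x[keep], c.y[keep], c.t[keep]))
    if not survivors:
        raise ValueError("temporal restructuring emptied every cluster")
    # order by recomputed mean time; merge exact ties to keep it strict
    survivors.sort(key=lambda c: c.mean_t)
    merged: list[RawCluster] = [survivors[0]]
    for c in survivors[1:]:
        if c.mean_t == merged[-1].mean_t:
            p = merged[-1]
            merged[-1] = RawCluster(
                np.concatenate([p.x, c.x]),
                np.concatenate([p.y, c.y]),
                np.concatenate([p.t, c.t]),
            )
        else:
            merged.append(c)
    n_points = np.array([c.n_points for c in merged])
    if total_points is None:
        total_points = sum(c.n_points for c in clusters)
    return KeyPointSequence(
        cx=np.array([c.center[0] for c in merged]),
        cy=np.array([c.center[1] for c in merged]),
        mean_t=np.array([c.mean_t for c in merged]),
        n_points=n_points,
        weight=n_points / float(total_points),
        **meta,
    )


def extract_keypoints(traj: Trajectory, k: int = DEFAULT_CODEBOOK_SIZE,
                      sigma: float = DEFAULT_SIGMA, seed: int = 0) -> KeyPointSequence:
    """Smooth, quantize and restructure one trajectory into key points."""
    sm = gaussian_smooth(traj, sigma)
    mask = sm.pen_down
    points = np.column_stack([sm.x[mask], sm.y[mask]])
    clusters = vq_cluster(points, sm.t[mask], k=k, seed=seed)
    return temporal_restructure(
        clusters, total_points=len(points),
        subject_id=traj.subject_id, part=traj.part, block=traj.block,
        codebook_size=k,
    )


@dataclass
class TemplateFeatures:
    """Distances of one trajectory's key points from the template's."""

    dtwd: float
    vq_unweighted: float
    vq_weighted: float


def template_features(ref: KeyPointSequence, traj_kp: KeyPointSequence) -> TemplateFeatures:
    """Compare a trajectory's key points with the reference's.

    DTWD aligns the two center sequences; the VQ distances pair key points
    by temporal rank up to the shorter length, averaging Euclidean center
    distances without weights and with the trajectory's relative weights
    (renormalized over the paired prefix).
    """
    if len(ref) == 0 or len(traj_kp) == 0:
        raise ValueError("empty key-point sequence")
    rc = ref.centers()
    tc = traj_kp.centers()
    m = min(len(ref), len(traj_kp))
    d = np.linalg.norm(rc[:m] - tc[:m], axis=1)
    w = traj_kp.weight[:m]
    return TemplateFeatures(
        dtwd=dtw_distance(rc, tc),
        vq_unweighted=float(d.mean()),
        vq_weighted=float((w * d).sum() / w.sum()),
    )


# ---------------------------------------------------------------------------
# template archive
# ---------------------------------------------------------------------------

@dataclass
class TemplateSet:
    """Per-(part, block) reference key points plus their provenance."""

    keypoints: dict[tuple[str, int], KeyPointSequence] = field(default_factory=dict)
    seed: int = 0
    codebook_size: int = DEFAULT_CODEBOOK_SIZE
    sigma: float = DEFAULT_SIGMA


def save_templates(templates: TemplateSet, path: str | Path) -> None:
    doc = {
        "seed": templates.seed,
        "codebook_size": templates.codebook_size,
        "sigma": templates.sigma,
        "blocks": {},
    }
    for (part, block), kp in templates.keypoints.items():
        doc["blocks"][block_key_str(part, block)] = {
            "reference_subject_id": kp.subject_id,
            "part": part,
            "block": block,
            "codebook_size": kp.codebook_size,
            "keypoints": [
                {
                    "idx": i,
                    "cx": float(kp.cx[i]),
                    "cy": float(kp.cy[i]),
                    "mean_t": float(kp.mean_t[i]),
                    "n_points": int(kp.n_points[i]),
                    "weight": float(kp.weight[i]),
                }
                for i in range(len(kp))
            ],
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_templates(path: str | Path) -> TemplateSet:
    with open(path) as fh:
        doc = json.load(fh)
    ts = TemplateSet(seed=doc["seed"], codebook_size=doc["codebook_size"],
                     sigma=doc["sigma"])
    for entry in doc["blocks"].values():
        rows = entry["keypoints"]
        kp = KeyPointSequence(
            cx=np.array([r["cx"] for r in rows]),
            cy=np.array([r["cy"] for r in rows]),
            mean_t=np.array([r["mean_t"] for r in rows]),
            n_points=np.array([r["n_points"] for r in rows]),
            weight=np.array([r["weight"] for r in rows]),
            subject_id=entry["reference_subject_id"],
            part=entry["part"],
            block=entry["block"],
            codebook_size=entry["codebook_size"],
        )
        ts.keypoints[(entry["part"], entry["block"])] = kp
    return ts
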