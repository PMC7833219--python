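"""Perceptron construction, domain partitioning, pGSI and pSRI.

The SpO2 complexity track is turned into a binary perceptron: segment m is
labelled γ_m = +1 (relative normoxemia) when its Hurst exponent exceeds the
track's own mean E[H(SpO2)], −1 (relative hypoxemia) otherwise. Both labels
are *relative to the subject's own complexity mean* — no clinical
hypoxemia threshold is involved.

The labelled per-segment points (H(HRV)_m, H(SF)_m) are then used to
partition the effective domain

    Ω = [min H(HRV), max H(HRV)] × [min H(SF), max H(SF)]

into convex positive subdomains Ω+_j and negative subdomains Ω−_i whose
union covers Ω. The partition pipeline: per-class agglomerative clustering
under three dissimilarities (Bray-Curtis, Chebyshev, normalized squared
Euclidean) with the Calinski-Harabasz criterion choosing the cluster count
per run and the run with the fewest clusters winning; convexification of
each cluster; thin separation layers shrinking overlapping opposite-class
hulls; and a Delaunay triangulation of a regular mesh over Ω whose
triangles are classified by nearest hull, so areas are sums of triangle
areas and the covering property holds exactly.

From the partition:

* pGSI  τ = meas(∪Ω+) / meas(Ω) ∈ [0, 1] — the predictive Geometric
  Stress Index, with τ = 1/2 the neutrality baseline;
* pSRI  θ = mean distance of positive-labelled points inside ∪Ω+ to the
  nearest negative-subdomain boundary — the predictive Stress Resistance
  Index (larger = the subject's normoxemic complexity states sit farther
  from the hypoxemia boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import ConvexHull, Delaunay
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import calinski_harabasz_score

from .complexity import ComplexityTrack
from .io import DataError

__all__ = [
    "PerceptronTrack",
    "GeometryConfig",
    "DomainPartition",
    "build_perceptron",
    "partition_domain",
    "compute_pgsi",
    "compute_psri",
    "StressIndexResult",
]


@dataclass
class PerceptronTrack:
    """Binary labels γ_m ∈ {−1, +1} derived from the SpO2 complexity track.

    ``threshold`` is E[H(SpO2)] over the valid segments; ``excluded`` lists
    the indices of flagged (undefined-complexity) segments, which carry no
    label.
    """

    labels: np.ndarray
    threshold: float
    source: ComplexityTrack | None = None
    excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("perceptron labels must be exactly -1 or +1")


def build_perceptron(hz: ComplexityTrack) -> PerceptronTrack:
    """γ_m = sign(H(SpO2)_m − E[H(SpO2)]), with sign(0) → +1.

    Exact ties with the mean are labelled +1 (normoxemia); they are
    measure-zero for real data, and a constant track — every segment tied —
    is flagged degenerate with a warning.
    """
    valid = hz.valid
    if valid.sum() < 2:
        raise DataError("perceptron needs >= 2 valid segments")
    thr = hz.mean()
    vals = hz.values[valid]
    labels = np.where(vals >= thr, 1, -1).astype(int)
    degenerate = bool(np.all(vals == vals[0]))
    if degenerate:
        warnings.warn(
            "constant SpO2 complexity track: all perceptron labels tie to +1",
            RuntimeWarning,
            stacklevel=2,
        )
    return PerceptronTrack(
        labels=labels,
        threshold=thr,
        source=hz,
        excluded=np.flatnonzero(~valid),
        degenerate=degenerate,
    )


@dataclass
class GeometryConfig:
    """Options of the domain-partition pipeline.

    epsilon : float or None
        Total separation-layer width; None → 1% of the diagonal of Ω
        (halved and applied to each class).
    mesh : int
        Mesh points per axis for the Delaunay triangulation of Ω
        (default 60, i.e. a 60 × 60 point grid).
    max_clusters : int
        Upper bound on the per-class cluster count scanned.
    ch_accept_factor : float
        A split into >= 2 clusters is accepted only when its
        Calinski-Harabasz score exceeds ``ch_accept_factor * n_points``;
        otherwise the class stays one cluster. The variance-ratio score is
        undefined for a single cluster, and empirically scales like
        ~0.6-1.1·n for an unsplittable Gaussian cloud versus >10·n for
        genuinely separated blobs, so a factor of 3 cleanly separates the
        regimes without a free absolute threshold.
    classifier : {"hull", "logistic"}
        How mesh triangles are classified: nearest convex hull (the
        geometric path, default) or a 2-D logistic-regression decision
        boundary fit to the labelled points (cross-check path).
    """

    epsilon: float | None = None
    mesh: int = 60
    max_clusters: int = 6
    ch_accept_factor: float = 3.0
    classifier: Literal["hull", "logistic"] = "hull"

    def __post_init__(self) -> None:
        if self.mesh < 10:
            raise ValueError("mesh must be >= 10")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class DomainPartition:
    """The partitioned effective domain Ω with triangulated class areas."""

    bounds: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    positive_polygons: list
    negative_polygons: list
    mesh_points: np.ndarray
    simplices: np.ndarray
    triangle_classes: np.ndarray  # +1/-1 per triangle
    area_positive: float
    area_negative: float
    meta: dict = field(default_factory=dict)

    @property
    def meas_omega(self) -> float:
        xmin, xmax, ymin, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.bounds
        pts = np.atleast_2d(pts)
        return (
            (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
            & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
        )

    def classify(self, pts: np.ndarray) -> np.ndarray:
        """Class (+1/-1) of arbitrary points by the partition's own rule."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if not self.negative_polygons:
            return np.ones(len(pts), dtype=int)
        if not self.positive_polygons:
            return -np.ones(len(pts), dtype=int)
        if self.meta.get("classifier") == "logistic" and "_logistic" in self.meta:
            pred = self.meta["_logistic"].predict(pts)
            return pred.astype(int)
        dpos = _distance_to_union(pts, self.positive_polygons)
        dneg = _distance_to_union(pts, self.negative_polygons)
        return np.where(dpos <= dneg, 1, -1).astype(int)

    def to_json_dict(self) -> dict:
        def poly_coords(g):
            if g.geom_type == "Polygon":
                return list(map(list, np.asarray(g.exterior.coords)))
            return list(map(list, np.asarray(g.coords)))

        return {
            "bounds": list(self.bounds),
            "positive_polygons": [poly_coords(p) for p in self.positive_polygons],
            "negative_polygons": [poly_coords(p) for p in self.negative_polygons],
            "area_positive": self.area_positive,
            "area_negative": self.area_negative,
            "meas_omega": self.meas_omega,
            "meta": {k: v for k, v in self.meta.items() if not k.startswith("_")},
        }


def _normalized_sqeuclidean(pts: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance after per-coordinate standardization."""
    sd = pts.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return pdist(pts / sd, "sqeuclidean")


def _cluster_one_class(pts: np.ndarray, cfg: GeometryConfig) -> list[np.ndarray]:
    """Cluster one label class; returns a list of index arrays.

    Three agglomerative (complete-linkage) runs under Bray-Curtis,
    Chebyshev and normalized squared Euclidean dissimilarities; the
    Calinski-Harabasz criterion picks the cluster count within each run and
    the run with the fewest clusters wins. Ties with a single cluster are
    resolved by the acceptance factor (see GeometryConfig).
    """
    n = len(pts)
    if n <= 3:
        return [np.arange(n)]
    metrics = {
        "braycurtis": lambda p: pdist(p, "braycurtis"),
        "chebyshev": lambda p: pdist(p, "chebyshev"),
        "normalized-sqeuclidean": _normalized_sqeuclidean,
    }
    results: list[tuple[int, str, np.ndarray]] = []
    for name, dist in metrics.items():
        d = dist(pts)
        if not np.all(np.isfinite(d)):
            continue
        D = squareform(d)
        best_k, best_ch, best_lab = 1, -np.inf, np.zeros(n, dtype=int)
        for k in range(2, min(cfg.max_clusters, n - 1) + 1):
            model = AgglomerativeClustering(
                n_clusters=k, metric="precomputed", linkage="complete"
            )
            lab = model.fit_predict(D)
            if len(np.unique(lab)) < 2:
                continue
            ch = calinski_harabasz_score(pts, lab)
            if ch > best_ch:
                best_k, best_ch, best_lab = k, ch, lab
        if best_k > 1 and best_ch < cfg.ch_accept_factor * n:
            best_k, best_lab = 1, np.zeros(n, dtype=int)
        results.append((best_k, name, best_lab))
    if not results:
        return [np.arange(n)]
    results.sort(key=lambda r: (r[0], list(metrics).index(r[1])))
    _, _, lab = results[0]
    return [np.flatnonzero(lab == c) for c in np.unique(lab)]


def _hull_geometry(pts: np.ndarray):
    """Convex hull of a point set as a shapely geometry (may be degenerate)."""
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            return Polygon(pts[hull.vertices])
        except Exception:  # collinear points
            pass
    return MultiPoint([tuple(p) for p in pts]).convex_hull


def _distance_to_union(pts: np.ndarray, geoms: list) -> np.ndarray:
    union = unary_union(geoms)
    return np.array([union.distance(Point(p)) for p in pts])


def _apply_separation_layers(
    pos: list, neg: list, eps: float, max_iter: int = 25
) -> tuple[list, list, int]:
    """Shrink overlapping opposite-class hulls inward by eps/2 per side.

    Repeated until no opposite-class polygon pair overlaps with positive
    area or the iteration cap is reached (heavily intermixed data cannot be
    fully separated by convex shrinking; the residual overlap is tolerated,
    mirroring the partition's tolerance for intermixed points).
    A polygon is never shrunk to emptiness: the last non-empty shape wins.
    """
    pos, neg = list(pos), list(neg)
    iters = 0
    for _ in range(max_iter):
        overlapping_pos: set[int] = set()
        overlapping_neg: set[int] = set()
        for i, p in enumerate(pos):
            for j, q in enumerate(neg):
                if (
                    p.geom_type == "Polygon"
                    and q.geom_type == "Polygon"
                    and p.intersection(q).area > 1e-12
                ):
                    overlapping_pos.add(i)
                    overlapping_neg.add(j)
        if not overlapping_pos:
            break
        iters += 1
        for i in overlapping_pos:
            shrunk = pos[i].buffer(-eps / 2.0, join_style="mitre")
            if not shrunk.is_empty and shrunk.geom_type == "Polygon":
                pos[i] = shrunk
        for j in overlapping_neg:
            shrunk = neg[j].buffer(-eps / 2.0, join_style="mitre")
            if not shrunk.is_empty and shrunk.geom_type == "Polygon":
                neg[j] = shrunk
    return pos, neg, iters


def partition_domain(
    points: np.ndarray,
    labels: PerceptronTrack | np.ndarray,
    config: GeometryConfig | None = None,
) -> DomainPartition:
    """Partition the effective domain Ω into positive/negative subdomains.

    Parameters
    ----------
    points : (n, 2) array
        Per-segment (H(HRV), H(SF)) coordinates.
    labels : PerceptronTrack or array of ±1
        Segment labels aligned with ``points``.
    config : GeometryConfig
        Pipeline options.

    Returns a :class:`DomainPartition` whose triangle classes cover Ω
    exactly, so the two class areas always sum to meas(Ω).
    """
    cfg = config or GeometryConfig()
    pts = np.asarray(points, dtype=float)
    lab = labels.labels if isinstance(labels, PerceptronTrack) else np.asarray(labels)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(lab) != len(pts):
        raise ValueError("labels must align with points")
    ok = np.all(np.isfinite(pts), axis=1)
    pts, lab = pts[ok], lab[ok]
    if len(pts) < 4:
        raise DataError("need >= 4 points with defined complexity")
    xmin, xmax = pts[:, 0].min(), pts[:, 0].max()
    ymin, ymax = pts[:, 1].min(), pts[:, 1].max()
    if (xmax - xmin) * (ymax - ymin) <= 0:
        raise DataError("degenerate effective domain (zero area)")
    bounds = (float(xmin), float(xmax), float(ymin), float(ymax))
    diag = float(np.hypot(xmax - xmin, ymax - ymin))
    eps = cfg.epsilon if cfg.epsilon is not None else 0.01 * diag

    hulls: dict[int, list] = {1: [], -1: []}
    cluster_counts: dict[int, int] = {1: 0, -1: 0}
    for cls in (1, -1):
        cpts = pts[lab == cls]
        if len(cpts) == 0:
            continue
        clusters = _cluster_one_class(cpts, cfg)
        cluster_counts[cls] = len(clusters)
        for idx in clusters:
            hulls[cls].append(_hull_geometry(cpts[idx]))

    pos, neg, sep_iters = _apply_separation_layers(hulls[1], hulls[-1], eps)

    # regular mesh over Ω, Delaunay-triangulated; classify triangle centroids
    gx = np.linspace(xmin, xmax, cfg.mesh)
    gy = np.linspace(ymin, ymax, cfg.mesh)
    mesh = np.column_stack([np.repeat(gx, cfg.mesh), np.tile(gy, cfg.mesh)])
    tri = Delaunay(mesh)
    centroids = mesh[tri.simplices].mean(axis=1)

    logit = None
    if len(pos) == 0:
        tri_cls = -np.ones(len(tri.simplices), dtype=int)
    elif len(neg) == 0:
        tri_cls = np.ones(len(tri.simplices), dtype=int)
    elif cfg.classifier == "logistic":
        logit = LogisticRegression().fit(pts, lab)
        tri_cls = logit.predict(centroids).astype(int)
    else:
        dpos = _distance_to_union(centroids, pos)
        dneg = _distance_to_union(centroids, neg)
        tri_cls = np.where(dpos <= dneg, 1, -1).astype(int)

    verts = mesh[tri.simplices]
    tri_areas = 0.5 * np.abs(
        (verts[:, 1, 0] - verts[:, 0, 0]) * (verts[:, 2, 1] - verts[:, 0, 1])
        - (verts[:, 2, 0] - verts[:, 0, 0]) * (verts[:, 1, 1] - verts[:, 0, 1])
    )
    area_pos = float(tri_areas[tri_cls == 1].sum())
    area_neg = float(tri_areas[tri_cls == -1].sum())

    meta = {
        "epsilon": eps,
        "mesh": cfg.mesh,
        "classifier": cfg.classifier,
        "clusters_positive": cluster_counts[1],
        "clusters_negative": cluster_counts[-1],
        "separation_iterations": sep_iters,
        "n_points": int(len(pts)),
    }
    if logit is not None:
        meta["_logistic"] = logit
    return DomainPartition(
        bounds=bounds,
        positive_polygons=pos,
        negative_polygons=neg,
        mesh_points=mesh,
        simplices=tri.simplices,
        triangle_classes=tri_cls,
        area_positive=area_pos,
        area_negative=area_neg,
        meta=meta,
    )


def compute_pgsi(partition: DomainPartition) -> float:
    """pGSI τ = meas(∪Ω+) / meas(Ω) ∈ [0, 1].

    Exactly 1.0 when no negative subdomain exists and exactly 0.0 when no
    positive one does; otherwise the triangulated positive-area fraction.
    """
    if not partition.negative_polygons:
        return 1.0
    if not partition.positive_polygons:
        return 0.0
    total = partition.area_positive + partition.area_negative
    return float(min(1.0, max(0.0, partition.area_positive / total)))


@dataclass
class StressIndexResult:
    """pGSI τ, pSRI θ and the bookkeeping behind them."""

    tau: float
    theta: float
    m_plus: int
    distances: np.ndarray
    theta_flag: str | None = None  # None | "no-negative-boundary" | "undefined"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if np.isfinite(self.theta) and self.theta < 0:
            raise ValueError("theta must be >= 0")


def compute_psri(
    points: np.ndarray,
    labels: PerceptronTrack | np.ndarray,
    partition: DomainPartition,
) -> StressIndexResult:
    """pSRI θ: mean distance of positive points inside ∪Ω+ to ∪∂Ω−.

    m+ counts the positive-labelled points lying in a positive subdomain;
    θ is the mean Euclidean distance from those points to the nearest point
    of any negative-subdomain boundary. With no negative subdomain, θ is
    computed against ∂Ω and flagged; with m+ = 0, θ is NaN and flagged.
    """
    pts = np.asarray(points, dtype=float)
    lab = labels.labels if isinstance(labels, PerceptronTrack) else np.asarray(labels)
    ok = np.all(np.isfinite(pts), axis=1)
    pts, lab = pts[ok], lab[ok]
    pos_pts = pts[lab == 1]
    if len(pos_pts) and partition.positive_polygons:
        union_pos = unary_union(partition.positive_polygons)
        tol = 1e-12 * max(1.0, partition.meas_omega)
        inside = np.array([union_pos.distance(Point(p)) <= tol for p in pos_pts])
        pos_in = pos_pts[inside]
    else:
        pos_in = pos_pts[:0]
    m_plus = int(len(pos_in))
    if m_plus == 0:
        return StressIndexResult(
            tau=compute_pgsi(partition),
            theta=float("nan"),
            m_plus=0,
            distances=np.array([]),
            theta_flag="undefined",
        )
    flag = None
    if partition.negative_polygons:
        target = unary_union(
            [
                g.exterior if g.geom_type == "Polygon" else g
                for g in partition.negative_polygons
            ]
        )
    else:
        xmin, xmax, ymin, ymax = partition.bounds
        target = Polygon(
            [(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)]
        ).exterior
        flag = "no-negative-boundary"
    d = np.array([target.distance(Point(p)) for p in pos_in])
    return StressIndexResult(
        tau=compute_pgsi(partition),
        theta=float(d.mean()),
        m_plus=m_plus,
        distances=d,
        theta_flag=flag,
    )
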