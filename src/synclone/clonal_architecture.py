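"""Clonal architecture inference from paired mutant-allele-frequency clouds.

Each somatic SNV gives a point (MAF in adenoma, MAF in carcinoma).  Density
clustering (DBSCAN, Euclidean metric on the unit square) separates mutation
clusters from outliers; clusters below 1% of the points are discarded as
outliers.  Cluster centers are compared against the expected positions of the
four mutation classes — clonal at (rho_A/2, rho_C/2), lesion-specific on the
axes, and the stepwise-intermediate class (subclonal in adenoma, clonal in
carcinoma) whose presence is the signature of stepwise evolution.  The final
verdict is *parallel* when clonal and lesion-specific clusters coexist with no
intermediate cluster, *stepwise* when an intermediate cluster is found, and
*indeterminate* otherwise (in particular for mutation-poor cases).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .variant_io import SomaticVariant

AUTOSOMES = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
)


class ClusterLabel(str, enum.Enum):
    CLONAL = "clonal"
    ADENOMA_SPECIFIC = "adenoma_specific"
    CARCINOMA_SPECIFIC = "carcinoma_specific"
    STEPWISE_INTERMEDIATE = "stepwise_intermediate"
    UNLABELED = "unlabeled"


class Verdict(str, enum.Enum):
    PARALLEL = "parallel"
    STEPWISE = "stepwise"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class MafPoint:
    variant_id: str
    maf_adenoma: float
    maf_carcinoma: float

    def __post_init__(self) -> None:
        for v in (self.maf_adenoma, self.maf_carcinoma):
            if not 0.0 <= v <= 1.0:
                raise ValueError("MAF coordinates must lie in [0, 1]")


@dataclass
class MutationCluster:
    member_ids: list
    center: tuple  # (median maf_adenoma, median maf_carcinoma)
    label: ClusterLabel = ClusterLabel.UNLABELED

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClonalArchitecture:
    clusters: list
    outlier_ids: list
    verdict: Verdict
    purity_estimates: Optional[tuple] = None  # (rho_adenoma, rho_carcinoma)
    n_points: int = 0

    def summary(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "n_points": self.n_points,
            "n_outliers": len(self.outlier_ids),
            "purity_estimates": self.purity_estimates,
            "clusters": [
                {
                    "label": c.label.value,
                    "size": c.size,
                    "center": [round(c.center[0], 4), round(c.center[1], 4)],
                }
                for c in self.clusters
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def select_clustering_input(
    variants: Sequence[SomaticVariant],
    segments: Optional[Sequence] = None,
) -> list:
    """MAF points for clustering: autosomal SNVs, optionally copy-neutral only.

    When a segmentation (list of CopySegment) is supplied, variants are kept
    only if they fall inside a segment called neutral — mirroring the use of
    copy-number-neutral mutations so MAF needs no copy-number correction.
    Without a segmentation all autosomal SNVs are used.
    """
    neutral: dict = {}
    if segments is not None:
        for seg in segments:
            if seg.call == "neutral":
                neutral.setdefault(seg.chrom, []).append((seg.start, seg.end))

    points = []
    for v in variants:
        if v.kind != "SNV" or v.chrom not in AUTOSOMES:
            continue
        if segments is not None:
            pos0 = v.pos - 1
            intervals = neutral.get(v.chrom, [])
            if not any(lo <= pos0 < hi for lo, hi in intervals):
                continue
        points.append(MafPoint(v.id, v.maf("adenoma"), v.maf("carcinoma")))
    return points


def dbscan_cluster(points: Sequence[MafPoint], eps: float = 0.01, min_pts: int = 5):
    """DBSCAN on the MAF unit square; returns ``(clusters, outlier_ids)``.

    Standard semantics: a core point has at least ``min_pts`` neighbours
    within ``eps`` (the point itself included); clusters are maximal
    density-connected sets of core points plus their border points; border
    points reachable from several clusters join the first cluster (in input
    order of core seeds) that reaches them.  The default ``eps`` corresponds
    to a reachability distance of 1% in MAF units.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    if len(points) == 0:
        return [], []
    xy = np.array([[p.maf_adenoma, p.maf_carcinoma] for p in points])
    labels = DBSCAN(eps=eps, min_samples=min_pts, metric="euclidean").fit_predict(xy)

    clusters = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        member_ids = [points[i].variant_id for i in idx]
        center = (float(np.median(xy[idx, 0])), float(np.median(xy[idx, 1])))
        clusters.append(MutationCluster(member_ids=member_ids, center=center))
    outliers = [points[i].variant_id for i in np.flatnonzero(labels == -1)]
    return clusters, outliers


def filter_small_clusters(
    clusters: Sequence[MutationCluster], total_n: int, min_frac: float = 0.01
):
    """Drop clusters holding < ``min_frac`` of all points; members become outliers."""
    if not 0.0 <= min_frac < 1.0:
        raise ValueError("min_frac must be in [0, 1)")
    retained, extra_outliers = [], []
    for c in clusters:
        if c.size >= min_frac * total_n:
            retained.append(c)
        else:
            extra_outliers.extend(c.member_ids)
    return retained, extra_outliers


def estimate_purity(clonal_cluster: MutationCluster) -> tuple:
    """Per-lesion purity from the clonal cluster: rho = 2 * median MAF, clipped to [0,1].

    For copy-neutral heterozygous clonal mutations the expected MAF is rho/2,
    so doubling the cluster's median MAF recovers the tumor cell content.
    """
    if clonal_cluster.label is not ClusterLabel.CLONAL:
        raise ValueError("purity is estimated from a cluster labeled clonal")
    return tuple(float(np.clip(2.0 * m, 0.0, 1.0)) for m in clonal_cluster.center)


def estimate_purity_neighborhood(
    points: Sequence[MafPoint], center: tuple, radius: float = 0.1
) -> tuple:
    """Purity from the clonal neighborhood: 2 * median MAF of nearby points.

    DBSCAN at a 1% reachability distance can shave the tails of a
    binomially-dispersed clonal cloud into small fragments; the coordinate-wise
    median over *all* points within ``radius`` of the clonal cluster's center
    pools those fragments back and is robust to the shaving.  ``radius``
    should stay well below the separation between mutation classes.
    """
    xy = np.array([[p.maf_adenoma, p.maf_carcinoma] for p in points])
    med = np.asarray(center, dtype=float)
    for _ in range(2):  # re-center once: the anchor may sit on the cloud's edge
        near = np.max(np.abs(xy - med), axis=1) <= radius
        if not near.any():
            break
        med = np.median(xy[near], axis=0)
    return tuple(float(np.clip(2.0 * m, 0.0, 1.0)) for m in med)


def _categorize(center_maf: float, rho: float, absent_max: float, clonal_min_frac: float) -> str:
    if center_maf < absent_max:
        return "absent"
    if center_maf >= clonal_min_frac * rho / 2.0:
        return "clonal"
    return "subclonal"


def label_clusters(
    clusters: Sequence[MutationCluster],
    rho_adenoma: float,
    rho_carcinoma: float,
    absent_max: float = 0.05,
    clonal_min_frac: float = 0.6,
) -> list:
    """Label clusters against the expected class positions (in place).

    Per lesion a center coordinate is *absent* below ``absent_max``, *clonal*
    at or above ``clonal_min_frac`` of the clonal reference rho/2, else
    *subclonal*.  (clonal, clonal) -> clonal; presence in exactly one lesion
    -> lesion-specific; (subclonal in adenoma, clonal in carcinoma) -> the
    stepwise-intermediate class; every other combination stays unlabeled.
    """
    for rho in (rho_adenoma, rho_carcinoma):
        if not 0.0 < rho <= 1.0:
            raise ValueError("purities must lie in (0, 1]")
    for c in clusters:
        cat_a = _categorize(c.center[0], rho_adenoma, absent_max, clonal_min_frac)
        cat_c = _categorize(c.center[1], rho_carcinoma, absent_max, clonal_min_frac)
        if cat_a == "clonal" and cat_c == "clonal":
            c.label = ClusterLabel.CLONAL
        elif cat_a == "subclonal" and cat_c == "clonal":
            c.label = ClusterLabel.STEPWISE_INTERMEDIATE
        elif cat_a in ("clonal", "subclonal") and cat_c == "absent":
            c.label = ClusterLabel.ADENOMA_SPECIFIC
        elif cat_a == "absent" and cat_c in ("clonal", "subclonal"):
            c.label = ClusterLabel.CARCINOMA_SPECIFIC
        else:
            c.label = ClusterLabel.UNLABELED
    return list(clusters)


def infer_evolution(clusters: Sequence[MutationCluster]) -> Verdict:
    """Parallel/stepwise verdict from the labeled, size-filtered clusters.

    Stepwise as soon as an intermediate (subclonal-in-adenoma,
    clonal-in-carcinoma) cluster survives filtering; parallel when a clonal
    cluster coexists with at least one lesion-specific cluster and no
    intermediate one; otherwise indeterminate.
    """
    labels = {c.label for c in clusters}
    if ClusterLabel.STEPWISE_INTERMEDIATE in labels:
        return Verdict.STEPWISE
    has_clonal = ClusterLabel.CLONAL in labels
    has_specific = bool(
        labels & {ClusterLabel.ADENOMA_SPECIFIC, ClusterLabel.CARCINOMA_SPECIFIC}
    )
    if has_clonal and has_specific:
        return Verdict.PARALLEL
    return Verdict.INDETERMINATE


def analyze_maf_points(
    points: Sequence[MafPoint],
    eps: float = 0.01,
    min_pts: int = 5,
    min_frac: float = 0.01,
    min_points: int = 50,
    purities: Optional[tuple] = None,
    absent_max: float = 0.05,
    clonal_min_frac: float = 0.6,
) -> ClonalArchitecture:
    """Full clustering pipeline: DBSCAN, size filter, purity, labels, verdict.

    With fewer than ``min_points`` input points (the mutation-poor,
    microsatellite-stable situation) no architecture is attempted and the
    verdict is indeterminate.  When ``purities`` is not supplied it is
    estimated from the tentative clonal cluster — the retained cluster whose
    smaller center coordinate is largest.
    """
    if len(points) < min_points:
        return ClonalArchitecture(
            clusters=[],
            outlier_ids=[p.variant_id for p in points],
            verdict=Verdict.INDETERMINATE,
            purity_estimates=None,
            n_points=len(points),
        )
    clusters, outliers = dbscan_cluster(points, eps=eps, min_pts=min_pts)
    clusters, extra = filter_small_clusters(clusters, len(points), min_frac=min_frac)
    outliers = outliers + extra

    if not clusters:
        return ClonalArchitecture([], outliers, Verdict.INDETERMINATE, None, len(points))

    if purities is None:
        # Anchor on the cluster present in both lesions (no coordinate in the
        # absent band) with the highest minimum MAF coordinate: that separates
        # the clonal cluster — or a fragment of it — from any
        # stepwise-intermediate cluster, and the neighborhood median then
        # re-centers the estimate on the full clonal cloud.
        candidates = [c for c in clusters if min(c.center) >= absent_max]
        if not candidates:
            return ClonalArchitecture(clusters, outliers, Verdict.INDETERMINATE,
                                      None, len(points))
        anchor = max(candidates, key=lambda c: min(c.center))
        purities = estimate_purity_neighborhood(points, anchor.center)
    rho_a, rho_c = purities
    label_clusters(clusters, rho_a, rho_c, absent_max=absent_max,
                   clonal_min_frac=clonal_min_frac)
    verdict = infer_evolution(clusters)
    return ClonalArchitecture(clusters, outliers, verdict, (rho_a, rho_c), len(points))


def analyze_lesion_pair(
    variants: Sequence[SomaticVariant],
    segments: Optional[Sequence] = None,
    **kwargs,
) -> ClonalArchitecture:
    """Convenience wrapper: variant selection then :func:`analyze_maf_points`."""
    return analyze_maf_points(select_clustering_input(variants, segments), **kwargs)


def write_assignments_tsv(architecture: ClonalArchitecture, path) -> None:
    """Cluster assignment table (variant_id, cluster_id, label)."""
    import pandas as pd

    rows = []
    for i, c in enumerate(architecture.clusters):
        rows.extend(
            {"variant_id": vid, "cluster_id": i, "label": c.label.value}
            for vid in c.member_ids
        )
    rows.extend(
        {"variant_id": vid, "cluster_id": -1, "label": "outlier"}
        for vid in architecture.outlier_ids
    )
    pd.DataFrame(rows, columns=["variant_id", "cluster_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def plot_maf_scatter(points: Sequence[MafPoint], architecture: ClonalArchitecture, path) -> None:
    """Basic MAF scatter colored by cluster label (adenoma x, carcinoma y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        ClusterLabel.CLONAL: "black",
        ClusterLabel.ADENOMA_SPECIFIC: "green",
        ClusterLabel.CARCINOMA_SPECIFIC: "red",
        ClusterLabel.STEPWISE_INTERMEDIATE: "orange",
        ClusterLabel.UNLABELED: "blue",
    }
    by_id = {p.variant_id: p for p in points}
    fig, ax = plt.subplots(figsize=(5, 5))
    for c in architecture.clusters:
        xy = np.array([[by_id[v].maf_adenoma, by_id[v].maf_carcinoma] for v in c.member_ids])
        ax.scatter(xy[:, 0], xy[:, 1], s=6, color=colors[c.label], label=c.label.value)
    if architecture.outlier_ids:
        xy = np.array(
            [[by_id[v].maf_adenoma, by_id[v].maf_carcinoma] for v in architecture.outlier_ids]
        )
        ax.scatter(xy[:, 0], xy[:, 1], s=6, color="gray", label="outlier")
    ax.set_xlabel("MAF adenoma")
    ax.set_ylabel("MAF carcinoma")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120)
    plt.close(fig)
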