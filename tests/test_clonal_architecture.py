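import numpy as np
import pytest

from synclone.bruteforce import dbscan_reference
from synclone.clonal_architecture import (
    ClusterLabel,
    MafPoint,
    MutationCluster,
    Verdict,
    analyze_lesion_pair,
    analyze_maf_points,
    dbscan_cluster,
    estimate_purity,
    filter_small_clusters,
    infer_evolution,
    label_clusters,
    select_clustering_input,
)
from synclone.copy_number import CopySegment
from synclone.synthetic_data import SimulationConfig, simulate_lesion_pair

from conftest import make_variant


def random_instance(rng):
    """A mixture of tight blobs and uniform noise on the unit square."""
    n = int(rng.integers(5, 201))
    n_blobs = int(rng.integers(1, 5))
    parts = [
        np.clip(
            rng.uniform(0, 1, 2) + rng.normal(0, 0.004, size=(n // n_blobs, 2)), 0, 1
        )
        for _ in range(n_blobs)
    ]
    n_noise = n - sum(len(p) for p in parts)
    parts.append(rng.uniform(0, 1, size=(n_noise, 2)))
    return np.vstack(parts)


def labels_from_clusters(points, clusters, outliers):
    got = {}
    for k, c in enumerate(clusters):
        for vid in c.member_ids:
            got[vid] = k
    for vid in outliers:
        got[vid] = -1
    return np.array([got[p.variant_id] for p in points])


class TestSelectInput:
    def test_sex_chromosome_excluded(self):
        vx = make_variant(vid="x", chrom="chrX", adenoma=(40, 20), carcinoma=(40, 20))
        v1 = make_variant(vid="a", chrom="chr1", adenoma=(40, 20), carcinoma=(40, 20))
        points = select_clustering_input([vx, v1])
        assert [p.variant_id for p in points] == ["a"]

    def test_indels_excluded(self):
        vi = make_variant(vid="i", ref="A", alt="AT", adenoma=(40, 20))
        assert select_clustering_input([vi]) == []

    def test_copy_number_gain_region_excluded(self):
        v_gain = make_variant(vid="g", chrom="chr1", pos=500, adenoma=(40, 20))
        v_neut = make_variant(vid="n", chrom="chr1", pos=5000, adenoma=(40, 20))
        segments = [
            CopySegment("chr1", 0, 1000, 0.8, 10, call="gain"),
            CopySegment("chr1", 1000, 10000, 0.0, 90, call="neutral"),
        ]
        points = select_clustering_input([v_gain, v_neut], segments)
        assert [p.variant_id for p in points] == ["n"]

    def test_no_segmentation_keeps_all_autosomal_snvs(self):
        variants = [make_variant(vid=f"v{i}", chrom=f"chr{1 + i % 22}") for i in range(10)]
        assert len(select_clustering_input(variants)) == 10


class TestDbscan:
    def test_tight_blob_is_one_cluster(self):
        rng = np.random.default_rng(0)
        xy = 0.35 + rng.uniform(-0.001, 0.001, size=(10, 2))
        points = [MafPoint(f"v{i}", *xy[i]) for i in range(10)]
        clusters, outliers = dbscan_cluster(points, eps=0.01, min_pts=4)
        assert len(clusters) == 1 and not outliers
        assert clusters[0].size == 10

    def test_isolated_point_is_outlier(self):
        rng = np.random.default_rng(0)
        xy = 0.35 + rng.uniform(-0.001, 0.001, size=(10, 2))
        points = [MafPoint(f"v{i}", *xy[i]) for i in range(10)]
        points.append(MafPoint("far", 0.9, 0.1))
        clusters, outliers = dbscan_cluster(points, eps=0.01, min_pts=4)
        assert outliers == ["far"]
        assert len(clusters) == 1

    def test_empty_input(self):
        assert dbscan_cluster([]) == ([], [])

    def test_matches_density_reachability_oracle(self):
        # 30 random instances here; the full 100-instance sweep runs in the
        # acceptance suite
        rng = np.random.default_rng(1234)
        for _ in range(30):
            xy = random_instance(rng)
            eps = float(rng.uniform(0.005, 0.02))
            min_pts = int(rng.integers(2, 8))
            points = [MafPoint(f"v{i:04d}", *xy[i]) for i in range(len(xy))]
            clusters, outliers = dbscan_cluster(points, eps=eps, min_pts=min_pts)
            got = labels_from_clusters(points, clusters, outliers)
            ref = dbscan_reference(xy, eps, min_pts)
            assert np.array_equal(got, ref)

    def test_partition_invariant(self):
        rng = np.random.default_rng(7)
        xy = random_instance(rng)
        points = [MafPoint(f"v{i:04d}", *xy[i]) for i in range(len(xy))]
        clusters, outliers = dbscan_cluster(points)
        ids = [vid for c in clusters for vid in c.member_ids] + list(outliers)
        assert sorted(ids) == sorted(p.variant_id for p in points)


class TestFilterSmallClusters:
    def _cluster(self, n):
        return MutationCluster([f"v{i}" for i in range(n)], (0.3, 0.3))

    def test_sub_percent_cluster_dropped(self):
        retained, moved = filter_small_clusters([self._cluster(9)], total_n=1000)
        assert retained == [] and len(moved) == 9

    def test_exact_one_percent_retained(self):
        retained, moved = filter_small_clusters([self._cluster(10)], total_n=1000)
        assert len(retained) == 1 and moved == []

    def test_zero_min_frac_keeps_everything(self):
        retained, moved = filter_small_clusters(
            [self._cluster(1), self._cluster(2)], total_n=1000, min_frac=0.0
        )
        assert len(retained) == 2 and moved == []


class TestPurityAndLabels:
    def test_purity_doubles_median_maf(self):
        c = MutationCluster(["a"], (0.375, 0.36), label=ClusterLabel.CLONAL)
        assert estimate_purity(c) == pytest.approx((0.75, 0.72))

    def test_purity_clipped_at_one(self):
        c = MutationCluster(["a"], (0.6, 0.3), label=ClusterLabel.CLONAL)
        assert estimate_purity(c)[0] == 1.0

    def test_unlabeled_cluster_rejected(self):
        with pytest.raises(ValueError):
            estimate_purity(MutationCluster(["a"], (0.3, 0.3)))

    @pytest.mark.parametrize(
        "center,expected",
        [
            ((0.37, 0.36), ClusterLabel.CLONAL),
            ((0.12, 0.37), ClusterLabel.STEPWISE_INTERMEDIATE),
            ((0.36, 0.02), ClusterLabel.ADENOMA_SPECIFIC),
            ((0.02, 0.36), ClusterLabel.CARCINOMA_SPECIFIC),
            ((0.02, 0.02), ClusterLabel.UNLABELED),
            ((0.12, 0.12), ClusterLabel.UNLABELED),
        ],
    )
    def test_expected_class_positions(self, center, expected):
        c = MutationCluster(["a"], center)
        label_clusters([c], 0.75, 0.75)
        assert c.label is expected

    def test_purity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_clusters([], 0.0, 0.75)


class TestVerdict:
    def _with_labels(self, labels):
        return [MutationCluster(["x"], (0.3, 0.3), label=lab) for lab in labels]

    def test_three_class_architecture_is_parallel(self):
        clusters = self._with_labels(
            [ClusterLabel.CLONAL, ClusterLabel.ADENOMA_SPECIFIC,
             ClusterLabel.CARCINOMA_SPECIFIC]
        )
        assert infer_evolution(clusters) is Verdict.PARALLEL

    def test_intermediate_cluster_means_stepwise(self):
        clusters = self._with_labels(
            [ClusterLabel.CLONAL, ClusterLabel.CARCINOMA_SPECIFIC,
             ClusterLabel.STEPWISE_INTERMEDIATE]
        )
        assert infer_evolution(clusters) is Verdict.STEPWISE

    def test_clonal_only_is_indeterminate(self):
        assert infer_evolution(self._with_labels([ClusterLabel.CLONAL])) is (
            Verdict.INDETERMINATE
        )


class TestPipeline:
    def test_mutation_poor_case_is_indeterminate(self):
        sim = simulate_lesion_pair(
            SimulationConfig(n_clonal=10, n_adenoma_specific=5,
                             n_carcinoma_specific=5, seed=0)
        )
        arch = analyze_lesion_pair(sim.variants)
        assert arch.verdict is Verdict.INDETERMINATE

    def test_parallel_recovery_single_run(self):
        sim = simulate_lesion_pair(SimulationConfig(model="parallel", seed=123))
        arch = analyze_lesion_pair(sim.variants)
        assert arch.verdict is Verdict.PARALLEL
        labels = {c.label for c in arch.clusters}
        assert ClusterLabel.STEPWISE_INTERMEDIATE not in labels
        assert arch.purity_estimates == pytest.approx((0.75, 0.75), abs=0.05)

    def test_stepwise_recovery_single_run(self):
        sim = simulate_lesion_pair(
            SimulationConfig(model="stepwise", n_clonal=200, n_adenoma_specific=200,
                             n_carcinoma_specific=200, n_stepwise_intermediate=200,
                             seed=321)
        )
        arch = analyze_lesion_pair(sim.variants)
        assert arch.verdict is Verdict.STEPWISE

    def test_members_and_outliers_partition_points(self):
        sim = simulate_lesion_pair(SimulationConfig(seed=99))
        points = select_clustering_input(sim.variants)
        arch = analyze_maf_points(points)
        ids = [vid for c in arch.clusters for vid in c.member_ids] + list(arch.outlier_ids)
        assert sorted(ids) == sorted(p.variant_id for p in points)

    def test_verdict_stable_under_input_reordering(self):
        sim = simulate_lesion_pair(SimulationConfig(seed=17))
        points = select_clustering_input(sim.variants)
        arch = analyze_maf_points(points)
        rng = np.random.default_rng(0)
        shuffled = [points[i] for i in rng.permutation(len(points))]
        arch2 = analyze_maf_points(shuffled)
        assert arch.verdict is arch2.verdict
        assert len(arch.clusters) == len(arch2.clusters)
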