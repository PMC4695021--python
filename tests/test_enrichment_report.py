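import json

import numpy as np
import pytest

from synclone.bruteforce import fisher_reference
from synclone.clonal_architecture import analyze_lesion_pair
from synclone.enrichment_report import (
    build_trunk_branch_tree,
    class_enrichment,
    fisher_exact_2x2,
    make_report,
    truncating_recurrence,
    write_report,
)
from synclone.synthetic_data import SimulationConfig, simulate_lesion_pair
from synclone.variant_io import RegionalClass, classify_all, summarize_abundance

from conftest import make_variant


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        # margins (3,3)/(3,3): observed p = 1/20 per extreme diagonal, both
        # diagonals extreme -> 2/20
        assert fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 16, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(fisher_reference(t), rel=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestClassEnrichment:
    def _cohort(self):
        variants = []
        classes = {}
        for i in range(4):  # gene G: 4 clonal nonsilent mutations
            v = make_variant(vid=f"g{i}", gene="G", consequence="missense")
            variants.append(v)
            classes[v.id] = RegionalClass.CLONAL
        for i in range(10):  # background: 10 clonal elsewhere
            v = make_variant(vid=f"bc{i}", gene=f"B{i}", consequence="missense")
            variants.append(v)
            classes[v.id] = RegionalClass.CLONAL
        for i in range(30):  # background: 30 lesion-specific elsewhere
            v = make_variant(vid=f"bl{i}", gene=f"C{i}", consequence="nonsense")
            variants.append(v)
            classes[v.id] = (
                RegionalClass.ADENOMA_SPECIFIC if i % 2 else RegionalClass.CARCINOMA_SPECIFIC
            )
        return variants, classes

    def test_clonal_specific_gene_table_and_p(self):
        variants, classes = self._cohort()
        results = class_enrichment(variants, classes)
        top = next(r for r in results if r.gene == "G" and r.direction == "clonal")
        assert top.table == ((4, 0), (10, 30))
        assert top.p == pytest.approx(fisher_exact_2x2([[4, 0], [10, 30]]))
        assert top.p == pytest.approx(fisher_reference([[4, 0], [10, 30]]))

    def test_single_mutation_gene_is_not_enriched(self):
        v = make_variant(vid="solo", gene="S", consequence="missense")
        other = [make_variant(vid=f"o{i}", gene="O", consequence="missense") for i in range(6)]
        classes = {"solo": RegionalClass.CLONAL}
        classes.update({f"o{i}": RegionalClass.CLONAL for i in range(3)})
        classes.update({f"o{i}": RegionalClass.ADENOMA_SPECIFIC for i in range(3, 6)})
        results = class_enrichment([v] + other, classes)
        solo = [r for r in results if r.gene == "S"]
        assert all(r.p > 0.4 for r in solo)

    def test_direction_swap_symmetry(self):
        variants, classes = self._cohort()
        swapped = {
            vid: (
                RegionalClass.ADENOMA_SPECIFIC
                if cls is RegionalClass.CLONAL
                else RegionalClass.CLONAL
            )
            for vid, cls in classes.items()
        }
        p_orig = {
            (r.gene, r.direction): r.p for r in class_enrichment(variants, classes)
        }
        p_swap = {
            (r.gene, r.direction): r.p for r in class_enrichment(variants, swapped)
        }
        assert p_orig[("G", "clonal")] == pytest.approx(p_swap[("G", "adenoma_specific")])

    def test_silent_mutations_ignored(self):
        v = make_variant(vid="s", gene="G", consequence="silent")
        assert class_enrichment([v], {"s": RegionalClass.CLONAL}) == []


class TestTruncatingRecurrence:
    def test_three_clonal_frameshifts_reported(self):
        variants = [
            make_variant(vid=f"v{i}", gene="ACVR2A", consequence="frameshift")
            for i in range(3)
        ]
        classes = {v.id: RegionalClass.CLONAL for v in variants}
        out = truncating_recurrence(variants, classes)
        assert out["clonal"] == ["ACVR2A"]

    def test_missense_does_not_count(self):
        variants = [
            make_variant(vid=f"t{i}", gene="X", consequence="nonsense") for i in range(2)
        ] + [
            make_variant(vid=f"m{i}", gene="X", consequence="missense") for i in range(5)
        ]
        classes = {v.id: RegionalClass.CLONAL for v in variants}
        out = truncating_recurrence(variants, classes)
        assert out["clonal"] == []

    def test_min_events_one_reports_every_truncated_gene(self):
        v = make_variant(vid="v", gene="TP53", consequence="nonsense")
        out = truncating_recurrence([v], {"v": RegionalClass.CARCINOMA_SPECIFIC},
                                    min_events=1)
        assert out["carcinoma_specific"] == ["TP53"]


class TestTrunkBranchTree:
    def _classified(self, n_clonal, n_aden, n_carc):
        variants, classes = [], {}
        specs = (
            [("clonal", RegionalClass.CLONAL)] * n_clonal
            + [("aden", RegionalClass.ADENOMA_SPECIFIC)] * n_aden
            + [("carc", RegionalClass.CARCINOMA_SPECIFIC)] * n_carc
        )
        for i, (tag, cls) in enumerate(specs):
            v = make_variant(vid=f"{tag}{i}", gene="APC" if i == 0 else "")
            variants.append(v)
            classes[v.id] = cls
        return variants, classes

    def test_newick_serialization(self):
        variants, classes = self._classified(120, 40, 60)
        tree = build_trunk_branch_tree(variants, classes, driver_genes={"APC"})
        assert tree.newick() == "((Adenoma:40,Carcinoma:60)LCA:120)Normal;"
        assert tree.annotations["clonal"] == [("APC", "missense")]

    def test_zero_length_branches_still_emitted(self):
        variants, classes = self._classified(5, 0, 0)
        tree = build_trunk_branch_tree(variants, classes)
        assert tree.newick() == "((Adenoma:0,Carcinoma:0)LCA:5)Normal;"

    def test_counts_conserve_abundance_totals(self):
        sim = simulate_lesion_pair(SimulationConfig(seed=8))
        classes = classify_all(sim.variants)
        table = summarize_abundance(sim.variants, classes)
        tree = build_trunk_branch_tree(sim.variants, classes)
        assert tree.trunk_count == int(table.loc["clonal"].sum())
        assert tree.adenoma_branch_count == int(table.loc["adenoma_specific"].sum())
        assert tree.carcinoma_branch_count == int(table.loc["carcinoma_specific"].sum())

    def test_shared_copy_number_event_goes_to_trunk(self):
        from synclone.copy_number import CopySegment

        variants, classes = self._classified(1, 1, 1)
        seg_a = [CopySegment("chr8", 0, 100, 0.6, 10, call="gain")]
        seg_c = [
            CopySegment("chr8", 50, 150, 0.7, 10, call="gain"),
            CopySegment("chr5", 0, 100, -0.6, 10, call="loss"),
        ]
        tree = build_trunk_branch_tree(variants, classes, segments_adenoma=seg_a,
                                       segments_carcinoma=seg_c)
        assert tree.segments["clonal"] == ["chr8:0-100:gain"]
        assert tree.segments["carcinoma_specific"] == ["chr5:0-100:loss"]


class TestReport:
    def test_end_to_end_synthetic_case(self, tmp_path):
        sim = simulate_lesion_pair(SimulationConfig(seed=6))
        classes = classify_all(sim.variants)
        arch = analyze_lesion_pair(sim.variants)
        table = summarize_abundance(sim.variants, classes)
        tree = build_trunk_branch_tree(sim.variants, classes)
        report = make_report(abundance=table, architecture=arch, tree=tree)
        assert report["clonal_architecture"]["verdict"] == "parallel"
        labels = [c["label"] for c in report["clonal_architecture"]["clusters"]]
        assert {"clonal", "adenoma_specific", "carcinoma_specific"} <= set(labels)
        path = tmp_path / "report.json"
        write_report(report, path)
        assert json.loads(path.read_text())["tree"]["trunk"] == tree.trunk_count

    def test_empty_report_skeleton(self):
        report = make_report()
        assert set(report["missing_stages"]) == {
            "abundance", "clonal_architecture", "msi", "copy_number",
            "enrichment", "tree",
        }

    def test_deterministic_rerun(self):
        def build():
            sim = simulate_lesion_pair(SimulationConfig(seed=13))
            classes = classify_all(sim.variants)
            return make_report(
                abundance=summarize_abundance(sim.variants, classes),
                architecture=analyze_lesion_pair(sim.variants),
                tree=build_trunk_branch_tree(sim.variants, classes),
            )

        assert json.dumps(build(), sort_keys=True) == json.dumps(build(), sort_keys=True)
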