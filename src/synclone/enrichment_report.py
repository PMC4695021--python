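"""Class-specific gene enrichment, trunk-branch trees, and the case report.

Genes are tested for preferential accumulation of nonsilent mutations in one
regional class (clonal, adenoma-specific, or carcinoma-specific) with a
two-sided Fisher's exact test on the pooled 2x2 table (mutations in the gene
vs all other genes) x (in-class vs other classes); p-values are reported raw.
For hypermutated, microsatellite-unstable genomes a recurrence rule is used
instead: genes with at least three truncating (nonsense/frameshift) events in
a class.  The per-case evolutionary summary is a trunk-branch tree whose edge
lengths are the regional mutation counts, serialized as Newick.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .variant_io import NONSILENT, TRUNCATING, RegionalClass, SomaticVariant

_DIRECTIONS = ("clonal", "adenoma_specific", "carcinoma_specific")


@dataclass
class EnrichmentResult:
    gene: str
    direction: str
    table: tuple  # ((in_gene_in_class, in_gene_other), (other_in_class, other_other))
    p: float


@dataclass
class TrunkBranchTree:
    """Two-lesion phylogeny: shared trunk plus adenoma and carcinoma branches."""

    trunk_count: int
    adenoma_branch_count: int
    carcinoma_branch_count: int
    annotations: dict = field(default_factory=dict)  # class -> [(gene, consequence)]
    segments: dict = field(default_factory=dict)  # class -> [copy-number event labels]

    def newick(self) -> str:
        return (
            f"((Adenoma:{self.adenoma_branch_count},"
            f"Carcinoma:{self.carcinoma_branch_count})"
            f"LCA:{self.trunk_count})Normal;"
        )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed table's
    (up to a 1 + 1e-7 relative tolerance).
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    return float(fisher_exact(arr, alternative="two-sided")[1])


def class_enrichment(
    variants: Sequence[SomaticVariant],
    classes: Mapping[str, RegionalClass],
    min_mutations: int = 1,
) -> list:
    """Per-gene, per-direction Fisher tests of nonsilent mutation counts.

    Only nonsilent mutations (missense, nonsense, frameshift, splice) in the
    three regional classes enter the table; genes with fewer than
    ``min_mutations`` such mutations are skipped.  Results are sorted by
    ascending p; no multiple-testing correction is applied (raw p-values are
    reported).
    """
    events = []  # (gene, class value)
    for v in variants:
        if not v.gene or v.consequence not in NONSILENT:
            continue
        cls = classes[v.id]
        if cls is RegionalClass.ABSENT:
            continue
        events.append((v.gene, cls.value))
    results = []
    genes = sorted({g for g, _ in events})
    for gene in genes:
        in_gene = [c for g, c in events if g == gene]
        if len(in_gene) < min_mutations:
            continue
        other = [c for g, c in events if g != gene]
        for direction in _DIRECTIONS:
            a = sum(c == direction for c in in_gene)
            b = len(in_gene) - a
            c_ = sum(c == direction for c in other)
            d = len(other) - c_
            tbl = ((a, b), (c_, d))
            results.append(
                EnrichmentResult(gene=gene, direction=direction, table=tbl,
                                 p=fisher_exact_2x2(tbl))
            )
    results.sort(key=lambda r: (r.p, r.gene, r.direction))
    return results


def truncating_recurrence(
    variants: Sequence[SomaticVariant],
    classes: Mapping[str, RegionalClass],
    min_events: int = 3,
) -> dict:
    """Genes with >= ``min_events`` truncating events per regional class.

    Truncating means nonsense or frameshift (MSI-derived frameshifts
    included).  Returns ``{class value: [genes]}`` for the three regional
    classes.
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    counts: dict = {}
    for v in variants:
        if not v.gene or v.consequence not in TRUNCATING:
            continue
        cls = classes[v.id]
        if cls is RegionalClass.ABSENT:
            continue
        counts[(cls.value, v.gene)] = counts.get((cls.value, v.gene), 0) + 1
    out = {d: [] for d in _DIRECTIONS}
    for (cls, gene), n in sorted(counts.items()):
        if n >= min_events:
            out[cls].append(gene)
    return out


def build_trunk_branch_tree(
    variants: Sequence[SomaticVariant],
    classes: Mapping[str, RegionalClass],
    driver_genes: Optional[Iterable] = None,
    segments_adenoma: Optional[Sequence] = None,
    segments_carcinoma: Optional[Sequence] = None,
) -> TrunkBranchTree:
    """Assemble the trunk-branch tree for one adenoma-carcinoma pair.

    Edge lengths are the clonal / adenoma-specific / carcinoma-specific
    variant counts (matching the abundance summary exactly).  Nonsilent
    mutations in ``driver_genes`` are annotated on their class's edge.
    Copy-number events (non-neutral segments) are placed on the clonal edge
    when the same call overlaps in both lesions, else on the lesion's edge.
    """
    driver_set = set(driver_genes or ())
    tallies = {d: 0 for d in _DIRECTIONS}
    annotations = {d: [] for d in _DIRECTIONS}
    for v in variants:
        cls = classes[v.id]
        if cls is RegionalClass.ABSENT:
            continue
        tallies[cls.value] += 1
        if v.gene in driver_set and v.consequence in NONSILENT:
            annotations[cls.value].append((v.gene, v.consequence))

    seg_labels = {d: [] for d in _DIRECTIONS}
    if segments_adenoma or segments_carcinoma:
        a_events = [s for s in (segments_adenoma or []) if s.call != "neutral"]
        c_events = [s for s in (segments_carcinoma or []) if s.call != "neutral"]

        def overlaps(s1, s2) -> bool:
            return s1.chrom == s2.chrom and s1.call == s2.call and \
                s1.start < s2.end and s2.start < s1.end

        for s in a_events:
            shared = any(overlaps(s, t) for t in c_events)
            key = "clonal" if shared else "adenoma_specific"
            seg_labels[key].append(f"{s.chrom}:{s.start}-{s.end}:{s.call}")
        for s in c_events:
            if not any(overlaps(s, t) for t in a_events):
                seg_labels["carcinoma_specific"].append(
                    f"{s.chrom}:{s.start}-{s.end}:{s.call}"
                )

    return TrunkBranchTree(
        trunk_count=tallies["clonal"],
        adenoma_branch_count=tallies["adenoma_specific"],
        carcinoma_branch_count=tallies["carcinoma_specific"],
        annotations=annotations,
        segments=seg_labels,
    )


def make_report(
    abundance=None,
    architecture=None,
    msi_calls=None,
    segments=None,
    enrichment=None,
    tree=None,
    timestamp: str = "",
) -> dict:
    """Bundle stage outputs into one JSON-serializable report dictionary.

    Any subset of stages may be present; missing stages are listed under
    ``missing_stages``.  The report is deterministic apart from the optional
    ``timestamp`` field the caller may supply.
    """
    report: dict = {"timestamp": timestamp, "missing_stages": []}

    if abundance is not None:
        report["abundance"] = {
            cls: {kind: int(abundance.loc[cls, kind]) for kind in abundance.columns}
            for cls in abundance.index
        }
    else:
        report["missing_stages"].append("abundance")

    if architecture is not None:
        report["clonal_architecture"] = architecture.summary()
    else:
        report["missing_stages"].append("clonal_architecture")

    if msi_calls is not None:
        n_msi = sum(c.is_msi for c in msi_calls)
        n_overlap = sum(c.is_msi and c.overlaps_indel for c in msi_calls)
        report["msi"] = {
            "n_loci_tested": len(msi_calls),
            "n_msi_events": int(n_msi),
            "n_overlapping_indels": int(n_overlap),
            "n_retained": int(n_msi - n_overlap),
        }
    else:
        report["missing_stages"].append("msi")

    if segments is not None:
        report["copy_number"] = [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "mean_log2": round(s.mean_log2, 4),
                "n_bins": s.n_bins,
                "call": s.call,
            }
            for s in segments
        ]
    else:
        report["missing_stages"].append("copy_number")

    if enrichment is not None:
        report["enrichment"] = [
            {"gene": r.gene, "direction": r.direction, "p": round(r.p, 6)}
            for r in enrichment
        ]
    else:
        report["missing_stages"].append("enrichment")

    if tree is not None:
        report["tree"] = {
            "newick": tree.newick(),
            "trunk": tree.trunk_count,
            "adenoma_branch": tree.adenoma_branch_count,
            "carcinoma_branch": tree.carcinoma_branch_count,
            "annotations": tree.annotations,
            "segments": tree.segments,
        }
    else:
        report["missing_stages"].append("tree")

    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
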