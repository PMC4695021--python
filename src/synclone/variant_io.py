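"""Somatic variant tables for paired-lesion (adenoma / carcinoma / normal) exomes.

A :class:`SomaticVariant` is the atom of the pipeline: one somatic event with
per-sample allele depths.  This module reads and writes variant tables (minimal
VCF v4.2 and a flat TSV dialect), computes mutant allele frequencies (MAF),
assigns regional classes (clonal / adenoma-specific / carcinoma-specific) from
per-lesion presence, and summarizes abundance and substitution spectra.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

#: canonical sample names, in column order
SAMPLES = ("adenoma", "carcinoma", "normal")
LESIONS = ("adenoma", "carcinoma")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six pyrimidine-context substitution categories
SPECTRUM_CATEGORIES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

NONSILENT = frozenset({"missense", "nonsense", "frameshift", "splice"})
TRUNCATING = frozenset({"nonsense", "frameshift"})
CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "silent", "splice", "other"})


class RegionalClass(str, enum.Enum):
    """Regional clonality class of a variant across the two synchronous lesions."""

    CLONAL = "clonal"
    ADENOMA_SPECIFIC = "adenoma_specific"
    CARCINOMA_SPECIFIC = "carcinoma_specific"
    ABSENT = "absent"


@dataclass
class SomaticVariant:
    """One somatic event with per-sample (ref_count, alt_count) depths.

    ``kind`` is derived from the alleles: an SNV iff both alleles are single
    bases.  ``depths`` maps each sample in :data:`SAMPLES` to a pair of
    non-negative integer read counts.
    """

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"
    depths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"variant {self.id}: unknown consequence {self.consequence!r}")
        for sample, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"variant {self.id}: negative depth in {sample}")

    @property
    def kind(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    def maf(self, sample: str) -> float:
        r, a = self.depths[sample]
        return compute_maf(r, a)

    def total_depth(self, sample: str) -> int:
        r, a = self.depths[sample]
        return r + a


def compute_maf(ref_count: int, alt_count: int) -> float:
    """Mutant allele frequency alt/(ref+alt); 0.0 for a no-coverage site."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total == 0:
        return 0.0
    return alt_count / total


def has_coverage(ref_count: int, alt_count: int) -> bool:
    """False for the degenerate (0, 0) depth pair whose MAF is reported as 0."""
    return (ref_count + alt_count) > 0


def classify_regional(
    variant: SomaticVariant, min_alt_reads: int = 4, min_maf: float = 0.05
) -> RegionalClass:
    """Assign a regional class from per-lesion presence.

    A variant is *present* in a lesion when its alt read count reaches
    ``min_alt_reads`` and its MAF reaches ``min_maf``.  Present in both
    lesions -> clonal; in one -> lesion-specific; in neither -> absent.
    """
    if min_alt_reads < 0 or min_maf < 0:
        raise ValueError("thresholds must be non-negative")

    def present(sample: str) -> bool:
        _, a = variant.depths[sample]
        return a >= min_alt_reads and variant.maf(sample) >= min_maf

    in_a, in_c = present("adenoma"), present("carcinoma")
    if in_a and in_c:
        return RegionalClass.CLONAL
    if in_a:
        return RegionalClass.ADENOMA_SPECIFIC
    if in_c:
        return RegionalClass.CARCINOMA_SPECIFIC
    return RegionalClass.ABSENT


def classify_all(
    variants: Iterable[SomaticVariant], min_alt_reads: int = 4, min_maf: float = 0.05
) -> dict:
    """Classify every variant; returns ``{variant_id: RegionalClass}``."""
    return {v.id: classify_regional(v, min_alt_reads, min_maf) for v in variants}


def filter_high_confidence_indels(
    variants: Sequence[SomaticVariant], min_maf: float = 0.40, min_depth: int = 50
) -> list:
    """Keep indels supported by MAF > 40% or coverage > 50X in a lesion.

    SNVs pass through untouched.  An indel is retained when, in at least one
    lesion, its MAF exceeds ``min_maf`` or its total depth exceeds
    ``min_depth``.
    """
    kept = []
    for v in variants:
        if v.kind == "SNV":
            kept.append(v)
            continue
        maf_ok = any(v.maf(s) > min_maf for s in LESIONS)
        depth_ok = any(v.total_depth(s) > min_depth for s in LESIONS)
        if maf_ok or depth_ok:
            kept.append(v)
    return kept


def summarize_abundance(
    variants: Sequence[SomaticVariant], classes: Mapping[str, RegionalClass]
) -> pd.DataFrame:
    """Count variants per (regional class, kind); counts partition the input."""
    rows = []
    for v in variants:
        if v.id not in classes:
            raise ValueError(f"variant {v.id} is unclassified")
        rows.append((classes[v.id].value, v.kind))
    index = [c.value for c in RegionalClass]
    table = pd.DataFrame(0, index=index, columns=["SNV", "indel"], dtype=int)
    for cls, kind in rows:
        table.loc[cls, kind] += 1
    assert int(table.to_numpy().sum()) == len(variants)
    return table


def mutation_spectrum(variants: Sequence[SomaticVariant]) -> dict:
    """Six-category substitution spectrum with purine references complemented.

    G>A is counted as C>T etc., so a sequence and its reverse complement give
    identical spectra.
    """
    counts = {c: 0 for c in SPECTRUM_CATEGORIES}
    for v in variants:
        if v.kind != "SNV":
            raise ValueError(f"mutation_spectrum accepts SNVs only; {v.id} is an indel")
        ref, alt = v.ref.upper(), v.alt.upper()
        if ref in "GA":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    return counts


# ---------------------------------------------------------------------------
# I/O: minimal VCF v4.2 and flat TSV
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "gene", "consequence"] + [
    f"{field}_{sample}" for sample in SAMPLES for field in ("ref", "alt")
]


def write_variants(variants: Sequence[SomaticVariant], path, format: str = "vcf") -> None:
    if format == "vcf":
        _write_vcf(variants, path)
    elif format == "tsv":
        _write_tsv(variants, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_variants(path, format: str = "vcf") -> list:
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _vcf_header(contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQ", 1, "String", "Functional consequence")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for sample in SAMPLES:
        header.add_sample(sample)
    return header


def _write_vcf(variants: Sequence[SomaticVariant], path) -> None:
    contigs = list(dict.fromkeys(v.chrom for v in variants)) or ["chr1"]
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                id=v.id,
            )
            rec.info["GENE"] = v.gene or "."
            rec.info["CSQ"] = v.consequence
            for sample in SAMPLES:
                r, a = v.depths[sample]
                rec.samples[sample]["AD"] = (r, a)
            out.write(rec)


def _read_vcf(path) -> list:
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        missing = [s for s in SAMPLES if s not in list(vcf.header.samples)]
        if missing:
            raise ValueError(f"VCF is missing required sample columns: {missing}")
        for i, rec in enumerate(vcf):
            if len(rec.alts or ()) != 1:
                raise ValueError(f"record {i + 1} ({rec.chrom}:{rec.pos}): exactly one ALT required")
            gene = rec.info.get("GENE", ".")
            depths = {}
            for sample in SAMPLES:
                ad = rec.samples[sample].get("AD")
                if ad is None or len(ad) < 2:
                    raise ValueError(f"record {i + 1}: sample {sample} lacks AD")
                depths[sample] = (int(ad[0]), int(ad[1]))
            variants.append(
                SomaticVariant(
                    id=rec.id or f"var{i + 1}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene="" if gene == "." else gene,
                    consequence=rec.info.get("CSQ", "other"),
                    depths=depths,
                )
            )
    return variants


def _write_tsv(variants: Sequence[SomaticVariant], path) -> None:
    rows = []
    for v in variants:
        row = {
            "id": v.id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence,
        }
        for sample in SAMPLES:
            row[f"ref_{sample}"], row[f"alt_{sample}"] = v.depths[sample]
        rows.append(row)
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str}, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TSV {path} is missing required columns: {missing}")
    variants = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            depths = {
                sample: (int(getattr(row, f"ref_{sample}")), int(getattr(row, f"alt_{sample}")))
                for sample in SAMPLES
            }
            variants.append(
                SomaticVariant(
                    id=str(row.id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    gene=str(row.gene),
                    consequence=str(row.consequence),
                    depths=depths,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed record at line {lineno}: {exc}") from exc
    return variants


def write_truth(truth: Mapping[str, str], path) -> None:
    """Write a ground-truth class table as TSV (variant_id, true_class)."""
    pd.DataFrame(
        {"variant_id": list(truth), "true_class": list(truth.values())}
    ).to_csv(path, sep="\t", index=False)
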