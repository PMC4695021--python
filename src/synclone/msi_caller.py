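"""Microsatellite instability (MSI) calling from intraread repeat lengths.

The caller follows the read-length-distribution approach: microsatellite
tracts (1-4 bp units, 7-60 bp total) are located in the reference by a perfect
tandem-repeat scanner; every read spanning a tract with enough anchor sequence
contributes one observed tract length; per locus, the tumor and normal length
distributions are compared by a two-sample Kolmogorov-Smirnov test, with
Benjamini-Hochberg FDR control across loci.  Calls overlapping independently
called indels are flagged so the two event types are not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import kolmogorov
from statsmodels.stats.multitest import multipletests

MIN_TRACT = 7
MAX_TRACT = 60
MAX_UNIT = 4

_VALID_BASES = frozenset("ACGTN")


def _minimal_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True when the unit is not itself a repetition of a shorter unit."""
    n = len(unit)
    for q in range(1, n):
        if n % q == 0 and unit == unit[:q] * (n // q):
            return False
    return True


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A reference tandem-repeat tract (0-based, half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    unit: str
    locus_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.unit) <= MAX_UNIT:
            raise ValueError(f"unit length must be 1-{MAX_UNIT}, got {self.unit!r}")
        if not _is_primitive(self.unit):
            raise ValueError(f"unit {self.unit!r} is itself periodic")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not self.locus_id:
            object.__setattr__(self, "locus_id", f"{self.seq_id}:{self.start}-{self.end}")

    @property
    def tract_length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatLengthDistribution:
    """Observed tract lengths (one per spanning read) at a locus in a sample."""

    locus_id: str
    sample: str
    lengths: list

    def __post_init__(self) -> None:
        if any(x < 1 for x in self.lengths):
            raise ValueError("observed tract lengths must be >= 1")

    @property
    def n_reads(self) -> int:
        return len(self.lengths)


@dataclass
class MsiCall:
    """KS comparison of tumor vs normal repeat lengths at one locus."""

    locus_id: str
    comparison: str
    D: float
    p: float
    q: float = float("nan")
    is_msi: bool = False
    overlaps_indel: bool = False


# ---------------------------------------------------------------------------
# Reference scanning
# ---------------------------------------------------------------------------


def _maximal_period_runs(seq: np.ndarray, period: int):
    """Yield (start, end) of maximal tracts with the given period (0-based, half-open)."""
    n = seq.size
    if n <= period:
        return
    # a match at i commits positions i..i+period to the tract, so any N in
    # that window invalidates it (N breaks tracts)
    n_count = np.concatenate(([0], np.cumsum(seq == ord("N"))))
    has_n = (n_count[period + 1:] - n_count[: n - period]) > 0
    m = (seq[:-period] == seq[period:]) & ~has_n
    if not m.any():
        return
    padded = np.concatenate(([False], m, [False]))
    diffs = np.flatnonzero(padded[1:] != padded[:-1])
    for a, b in zip(diffs[::2], diffs[1::2]):
        yield int(a), int(b) + period  # run of matches [a, b) -> tract [a, b + period)


def find_microsatellites(
    sequence: str,
    seq_id: str = "seq",
    min_tract: int = MIN_TRACT,
    max_tract: int = MAX_TRACT,
) -> list:
    """Scan a reference sequence for perfect microsatellite tracts.

    Maximal perfect tandem tracts of 1-4 bp units with total length in
    ``[min_tract, max_tract]``; each tract is reported at its smallest period,
    with the unit given as the lexicographically minimal rotation.  Candidates
    that overlap are resolved in favour of the smallest unit, then the longest
    tract.  ``N`` breaks tracts; other non-ACGT symbols are rejected.
    """
    sequence = sequence.upper()
    if set(sequence) - _VALID_BASES:
        bad = sorted(set(sequence) - _VALID_BASES)
        raise ValueError(f"sequence contains non-ACGTN symbols: {bad}")
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)

    candidates = []
    for period in range(1, MAX_UNIT + 1):
        for a, b in _maximal_period_runs(seq, period):
            length = b - a
            if not min_tract <= length <= max_tract:
                continue
            tract = sequence[a:b]
            # skip tracts whose fundamental period is smaller: the smaller-
            # period scan reports a tract at least as long there
            if any(all(tract[i] == tract[i + q] for i in range(length - q))
                   for q in range(1, period)):
                continue
            unit = _minimal_rotation(sequence[a:a + period])
            candidates.append((period, -length, a, b, unit))

    candidates.sort()
    kept: list = []
    occupied: list = []  # (start, end) of accepted loci
    for period, neg_len, a, b, unit in candidates:
        if any(a < e and s < b for s, e in occupied):
            continue
        occupied.append((a, b))
        kept.append(MicrosatelliteLocus(seq_id=seq_id, start=a, end=b, unit=unit))
    kept.sort(key=lambda loc: loc.start)
    return kept


def scan_fasta(path) -> dict:
    """Scan every contig of a FASTA file; returns ``{seq_id: [loci]}``."""
    from pyfaidx import Fasta

    out = {}
    with Fasta(str(path)) as fasta:
        for name in fasta.keys():
            out[name] = find_microsatellites(str(fasta[name][:]), seq_id=name)
    return out


# ---------------------------------------------------------------------------
# Intraread repeat lengths
# ---------------------------------------------------------------------------


def extract_intraread_lengths(
    reads: Iterable,
    locus: MicrosatelliteLocus,
    min_flank: int = 5,
):
    """Collect per-sample observed tract lengths from spanning reads.

    ``reads`` yields ``(sample, sequence, mapped_start)`` records with
    ``mapped_start`` the 0-based reference position of the read's first base.
    Only reads spanning ``[start - min_flank, end + min_flank)`` contribute;
    the observed length is the maximal tract of the locus unit found in the
    read around the expected offset, so indels within the tract change the
    observation.  Returns ``(distributions, n_skipped)`` where
    ``distributions`` maps sample name to a
    :class:`RepeatLengthDistribution` and ``n_skipped`` counts non-spanning
    or non-informative reads per sample.
    """
    if min_flank < 1:
        raise ValueError("min_flank must be >= 1")
    period = len(locus.unit)
    per_sample: dict = {}
    skipped: dict = {}
    for sample, sequence, mapped_start in reads:
        sequence = sequence.upper()
        spans = (
            mapped_start <= locus.start - min_flank
            and mapped_start + len(sequence) >= locus.end + min_flank
        )
        if not spans:
            skipped[sample] = skipped.get(sample, 0) + 1
            continue
        offset = locus.start - mapped_start
        window_lo = offset - period
        window_hi = offset + locus.tract_length + period
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        best = 0
        for a, b in _maximal_period_runs(arr, period):
            if b <= window_lo or a >= window_hi:
                continue
            if _minimal_rotation(sequence[a:a + period]) != locus.unit:
                continue
            best = max(best, b - a)
        if best == 0:
            skipped[sample] = skipped.get(sample, 0) + 1
            continue
        per_sample.setdefault(sample, []).append(best)
    dists = {
        sample: RepeatLengthDistribution(locus.locus_id, sample, lengths)
        for sample, lengths in per_sample.items()
    }
    return dists, skipped


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Two-sample KS statistic and asymptotic p-value.

    D is the sup over all observed values of the empirical CDF difference
    (ties handled by evaluating both CDFs at every observed value); the
    p-value comes from the asymptotic Kolmogorov distribution at
    ``sqrt(ne) * D`` with effective size ``ne = |x||y| / (|x| + |y|)``,
    clipped to [0, 1].
    """
    x = np.asarray(sorted(x), dtype=float)
    y = np.asarray(sorted(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(x, grid, side="right") / x.size
    fy = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.max(np.abs(fx - fy)))
    ne = x.size * y.size / (x.size + y.size)
    p = float(np.clip(kolmogorov(np.sqrt(ne) * d), 0.0, 1.0))
    return d, p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_msi(
    tumor_lengths: Mapping[str, Sequence[int]],
    normal_lengths: Mapping[str, Sequence[int]],
    alpha: float = 0.05,
    min_reads: int = 10,
    comparison: str = "carcinoma_vs_normal",
):
    """Call MSI events per locus: KS test then BH-FDR across the comparison family.

    Loci with fewer than ``min_reads`` observations in either sample are
    skipped.  Returns ``(calls, skipped_ids)``; ``skipped_ids`` also reports
    loci present in only one of the two mappings.
    """
    shared = sorted(set(tumor_lengths) & set(normal_lengths))
    skipped = sorted((set(tumor_lengths) ^ set(normal_lengths)))
    retained = []
    for locus_id in shared:
        t, n = tumor_lengths[locus_id], normal_lengths[locus_id]
        if len(t) < min_reads or len(n) < min_reads:
            skipped.append(locus_id)
            continue
        retained.append(locus_id)
    calls = []
    for locus_id in retained:
        d, p = ks_two_sample(tumor_lengths[locus_id], normal_lengths[locus_id])
        calls.append(MsiCall(locus_id=locus_id, comparison=comparison, D=d, p=p))
    if calls:
        q = bh_fdr([c.p for c in calls])
        for call, qv in zip(calls, q):
            call.q = float(qv)
            call.is_msi = bool(qv < alpha)
    return calls, skipped


def group_distributions(dists: Iterable[RepeatLengthDistribution], sample: str) -> dict:
    """Pick one sample's distributions out of a mixed list: ``{locus_id: lengths}``."""
    return {d.locus_id: d.lengths for d in dists if d.sample == sample}


def reconcile_with_indels(
    calls: Sequence[MsiCall],
    loci: Mapping[str, MicrosatelliteLocus],
    indel_variants: Iterable,
) -> list:
    """Flag MSI calls whose locus overlaps an indel; return the non-overlapping calls.

    An indel occupies the reference interval ``[pos - 1, pos - 1 + |ref|)``
    (1-based VCF position converted to 0-based half-open).  The retained list
    is exactly the calls with ``overlaps_indel == False``, so
    ``len(retained) == len(calls) - n_overlapping`` always.
    """
    spans = []
    for v in indel_variants:
        if v.kind != "indel":
            continue
        spans.append((v.chrom, v.pos - 1, v.pos - 1 + len(v.ref)))
    retained = []
    for call in calls:
        locus = loci[call.locus_id]
        call.overlaps_indel = any(
            chrom == locus.seq_id and lo < locus.end and locus.start < hi
            for chrom, lo, hi in spans
        )
        if not call.overlaps_indel:
            retained.append(call)
    return retained


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_loci_bed(loci: Sequence[MicrosatelliteLocus], path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.seq_id}\t{loc.start}\t{loc.end}\t{loc.locus_id};{loc.unit}\n")


def write_calls_tsv(calls: Sequence[MsiCall], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "comparison": c.comparison,
                "D": c.D,
                "p": c.p,
                "q": c.q,
                "is_msi": c.is_msi,
                "overlaps_indel": c.overlaps_indel,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
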