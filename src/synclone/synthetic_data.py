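"""Synthetic paired-lesion data with recoverable ground truth.

Three generators, each deterministic under its seed:

* :func:`simulate_lesion_pair` — somatic SNV read counts for a synchronous
  adenoma/carcinoma pair under an explicit *parallel* or *stepwise* clone
  model.  A copy-neutral heterozygous variant carried by a fraction ``c`` of
  tumor cells in a lesion of purity ``rho`` has expected mutant allele
  frequency ``rho * c / 2``; per-lesion depth is Poisson, alt counts binomial.
* :func:`simulate_msi_observations` — per-locus microsatellite repeat-length
  reads with geometric PCR-stutter noise and, at unstable loci, a mixture
  shift of the tumor distribution.
* :func:`simulate_depth_profile` — piecewise-constant tumor/normal depth
  profiles with optional smooth multiplicative GC bias.

Class -> cancer-cell-fraction map (adenoma, carcinoma): clonal (1, 1),
adenoma_specific (1, 0), carcinoma_specific (0, 1), and — only under the
stepwise model — stepwise_intermediate (f, 1), where ``f`` is the fraction of
adenoma tumor cells belonging to the carcinoma-fated subclone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .msi_caller import MicrosatelliteLocus, RepeatLengthDistribution
from .variant_io import SomaticVariant

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

TRUE_CLASSES = (
    "clonal",
    "adenoma_specific",
    "carcinoma_specific",
    "stepwise_intermediate",
    "outlier",
)

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Clone model and sampling parameters for a lesion-pair simulation.

    Defaults reflect the study conditions this pipeline is exercised under:
    microdissection purity ~0.75 in both lesions, exome-like mean depth 120,
    a few hundred somatic SNVs per regional class, and a small uniform
    outlier admixture.  ``stepwise_subclone_fraction`` is the cancer-cell
    fraction, within the adenoma, of the carcinoma-fated clone (stepwise
    model only).
    """

    model: str = "parallel"
    purity_adenoma: float = 0.75
    purity_carcinoma: float = 0.75
    n_clonal: int = 300
    n_adenoma_specific: int = 250
    n_carcinoma_specific: int = 250
    n_stepwise_intermediate: int = 200
    stepwise_subclone_fraction: float = 0.3
    mean_depth: float = 120.0
    outlier_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.model not in ("parallel", "stepwise"):
            raise ValueError(f"model must be 'parallel' or 'stepwise', got {self.model!r}")
        for name in ("purity_adenoma", "purity_carcinoma"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_clonal", "n_adenoma_specific", "n_carcinoma_specific",
                     "n_stepwise_intermediate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.model == "stepwise":
            f = self.stepwise_subclone_fraction
            if not 0.0 < f < 1.0:
                raise ValueError(f"stepwise_subclone_fraction must be in (0, 1), got {f}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")


@dataclass
class LesionPairSimulation:
    """Emitted variants plus the generating truth for every one of them."""

    variants: list
    truth: dict  # variant_id -> true class
    config: SimulationConfig

    def __post_init__(self) -> None:
        ids = [v.id for v in self.variants]
        if sorted(ids) != sorted(self.truth):
            raise ValueError("truth labels do not match emitted variant ids")


def _class_roster(config: SimulationConfig) -> list:
    roster = (
        ["clonal"] * config.n_clonal
        + ["adenoma_specific"] * config.n_adenoma_specific
        + ["carcinoma_specific"] * config.n_carcinoma_specific
    )
    if config.model == "stepwise":
        roster += ["stepwise_intermediate"] * config.n_stepwise_intermediate
    n_outliers = int(round(config.outlier_fraction * len(roster)))
    roster += ["outlier"] * n_outliers
    return roster


def expected_maf(true_class: str, config: SimulationConfig) -> tuple:
    """Expected (MAF_adenoma, MAF_carcinoma) for a non-outlier class."""
    f = config.stepwise_subclone_fraction
    ccf = {
        "clonal": (1.0, 1.0),
        "adenoma_specific": (1.0, 0.0),
        "carcinoma_specific": (0.0, 1.0),
        "stepwise_intermediate": (f, 1.0),
    }[true_class]
    return (
        config.purity_adenoma * ccf[0] / 2.0,
        config.purity_carcinoma * ccf[1] / 2.0,
    )


def simulate_lesion_pair(config: SimulationConfig) -> LesionPairSimulation:
    """Draw somatic SNV read counts for one adenoma/carcinoma pair.

    Per variant and lesion, depth ~ Poisson(mean_depth) and alt count ~
    Binomial(depth, expected MAF).  Outliers draw their MAF pair uniformly on
    the unit square.  The matched normal carries depth but zero alt reads.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    roster = _class_roster(config)

    variants: list = []
    truth: dict = {}
    for i, true_class in enumerate(roster):
        vid = f"v{i + 1:05d}"
        if true_class == "outlier":
            maf_a, maf_c = rng.uniform(0.0, 1.0, size=2)
        else:
            maf_a, maf_c = expected_maf(true_class, config)
        depths = {}
        for sample, maf in (("adenoma", maf_a), ("carcinoma", maf_c)):
            depth = int(rng.poisson(config.mean_depth))
            alt = int(rng.binomial(depth, maf)) if depth > 0 else 0
            depths[sample] = (depth - alt, alt)
        depths["normal"] = (int(rng.poisson(config.mean_depth)), 0)

        chrom = AUTOSOMES[int(rng.integers(len(AUTOSOMES)))]
        pos = int(rng.integers(1, 100_000_000))
        ref = _BASES[int(rng.integers(4))]
        alt_base = [b for b in _BASES if b != ref][int(rng.integers(3))]
        variants.append(
            SomaticVariant(
                id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt_base,
                gene=f"GENE{int(rng.integers(1, 500)):04d}",
                consequence="missense", depths=depths,
            )
        )
        truth[vid] = true_class

    return LesionPairSimulation(variants=variants, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Microsatellite repeat-length observations
# ---------------------------------------------------------------------------


@dataclass
class MsiSimulationConfig:
    """Parameters for the repeat-length noise model.

    ``stutter_prob`` is the per-unit slippage probability of the geometric
    stutter kernel (offset d drawn with weight ``stutter_prob**|d|``,
    truncated at |d| <= 3).  At unstable loci each tumor read is additionally
    shifted by ``msi_shift`` repeat units with probability 0.5, producing the
    bimodal tumor distribution characteristic of MSI.
    """

    n_null_loci: int = 180
    n_msi_loci: int = 20
    reads_per_locus: int = 50
    stutter_prob: float = 0.1
    msi_shift: int = -3
    seed: int = 0

    def validate(self) -> None:
        if self.n_null_loci <= 0 or self.n_msi_loci < 0:
            raise ValueError("locus counts must be positive")
        if self.reads_per_locus <= 0:
            raise ValueError("reads_per_locus must be positive")
        if not 0.0 <= self.stutter_prob < 1.0:
            raise ValueError("stutter_prob must be in [0, 1)")


def _stutter_offsets(rng: np.random.Generator, stutter_prob: float, n: int) -> np.ndarray:
    if stutter_prob == 0.0:
        return np.zeros(n, dtype=int)
    offsets = np.arange(-3, 4)
    weights = stutter_prob ** np.abs(offsets)
    weights = weights / weights.sum()
    return rng.choice(offsets, size=n, p=weights)


def simulate_msi_observations(config: MsiSimulationConfig):
    """Generate paired tumor/normal repeat-length distributions per locus.

    Returns ``(loci, distributions, truth)`` where ``distributions`` is a list
    of :class:`RepeatLengthDistribution` (samples ``normal`` and
    ``carcinoma``) and ``truth`` maps locus_id -> bool (True at MSI loci).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_null_loci + config.n_msi_loci
    msi_flags = np.zeros(n_total, dtype=bool)
    msi_flags[rng.choice(n_total, size=config.n_msi_loci, replace=False)] = True

    loci: list = []
    dists: list = []
    truth: dict = {}
    cursor = 100  # synthetic non-overlapping coordinates on one contig
    for i in range(n_total):
        tract = int(rng.integers(10, 31))
        unit = "A" if rng.random() < 0.5 else "C"
        locus_id = f"ms{i + 1:05d}"
        locus = MicrosatelliteLocus(
            seq_id="chr1", start=cursor, end=cursor + tract, unit=unit, locus_id=locus_id
        )
        cursor += tract + 50
        loci.append(locus)
        truth[locus_id] = bool(msi_flags[i])

        n = config.reads_per_locus
        normal = tract + _stutter_offsets(rng, config.stutter_prob, n)
        tumor = tract + _stutter_offsets(rng, config.stutter_prob, n)
        if msi_flags[i]:
            shifted = rng.random(n) < 0.5
            tumor = tumor + np.where(shifted, config.msi_shift, 0)
        normal = np.maximum(normal, 1)
        tumor = np.maximum(tumor, 1)
        dists.append(RepeatLengthDistribution(locus_id, "normal", [int(x) for x in normal]))
        dists.append(RepeatLengthDistribution(locus_id, "carcinoma", [int(x) for x in tumor]))

    return loci, dists, truth


# ---------------------------------------------------------------------------
# Binned depth profiles
# ---------------------------------------------------------------------------


def simulate_depth_profile(
    n_bins: int,
    breakpoints: Sequence[int],
    segment_log2: Sequence[float],
    noise_sd: float = 5.0,
    gc_effect: bool = False,
    seed: int = 0,
    base_depth: float = 100.0,
    bin_size: int = 10_000,
    gc_coeff: float = 4.0,
) -> pd.DataFrame:
    """Piecewise-constant tumor/normal depth profile as a DepthBin table.

    ``breakpoints`` are strictly increasing bin indices in (0, n_bins);
    ``segment_log2`` gives the true tumor/normal log2 ratio of each of the
    ``len(breakpoints) + 1`` segments.  Normal depth is constant plus Gaussian
    noise (sd in read-depth units); tumor depth is ``normal * 2**log2``.  When
    ``gc_effect`` is on, a smooth multiplicative bias ``2**(gc_coeff * (gc -
    mean gc))`` is applied identically to both samples; the per-bin GC value
    is recorded in the table so it can be corrected away downstream.
    """
    bp = list(breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    if bp and (bp[0] <= 0 or bp[-1] >= n_bins):
        raise ValueError("breakpoints must lie strictly inside (0, n_bins)")
    if len(segment_log2) != len(bp) + 1:
        raise ValueError("need one segment_log2 value per segment (len(breakpoints) + 1)")

    rng = np.random.default_rng(seed)
    edges = [0] + bp + [n_bins]
    log2_per_bin = np.empty(n_bins)
    for lo, hi, val in zip(edges[:-1], edges[1:], segment_log2):
        log2_per_bin[lo:hi] = val

    i = np.arange(n_bins)
    gc = 0.45 + 0.08 * np.sin(2.0 * np.pi * 2.0 * i / n_bins)
    bias = 2.0 ** (gc_coeff * (gc - gc.mean())) if gc_effect else np.ones(n_bins)

    normal = base_depth * bias + rng.normal(0.0, noise_sd, n_bins)
    tumor = base_depth * (2.0 ** log2_per_bin) * bias + rng.normal(0.0, noise_sd, n_bins)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": i * bin_size,
            "end": (i + 1) * bin_size,
            "gc": gc,
            "depth_tumor": np.maximum(tumor, 0.0),
            "depth_normal": np.maximum(normal, 0.0),
        }
    )
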