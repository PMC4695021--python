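# Methods

`synclone` analyzes whole-exome data from *synchronous* colorectal
adenoma–carcinoma pairs — two histologically distinct lesions microdissected
from a single cancer mass, each compared against matched normal tissue.  The
central question is whether the carcinoma arose from a subclone of the
adjacent adenoma (**stepwise** evolution) or whether both lesions diverged
independently from a last common ancestor (**parallel** evolution).  The
package implements the full downstream analysis — regional variant
classification, mutant-allele-frequency clustering, microsatellite
instability calling, read-depth copy number, gene enrichment, and the
trunk–branch summary — together with generative simulators that provide
ground truth for every stage.  It consumes variant tables with allele depths
(VCF/TSV), per-read repeat observations (TSV), and binned depth tables (TSV);
alignment, somatic calling and functional annotation are upstream concerns.

## Clone model and mutant allele frequencies

For a copy-neutral heterozygous somatic variant carried by a cancer-cell
fraction *c* of the tumor cells in a lesion of purity ρ, the expected mutant
allele frequency is

    E[MAF] = ρ·c/2.

Each variant therefore maps to a point (MAF_adenoma, MAF_carcinoma), and the
four mutation classes occupy distinct positions:

| class                  | CCF (adenoma, carcinoma) | expected point     |
|------------------------|--------------------------|--------------------|
| clonal                 | (1, 1)                   | (ρ_A/2, ρ_C/2)     |
| adenoma-specific       | (1, 0)                   | (ρ_A/2, 0)         |
| carcinoma-specific     | (0, 1)                   | (0, ρ_C/2)         |
| stepwise-intermediate  | (f, 1)                   | (ρ_A·f/2, ρ_C/2)   |

The stepwise-intermediate class — subclonal in the adenoma (subclone
fraction *f*) yet clonal in the carcinoma — exists only if the carcinoma was
founded by an adenoma subclone.  Its presence or absence as a mutation
cluster is the decision criterion between the two evolutionary models.

## Simulators (`synthetic_data`)

**Lesion pairs.**  Per variant and lesion, sequencing depth is
Poisson(mean_depth) and the alt count Binomial(depth, ρ·c/2); the matched
normal carries depth but zero alt reads.  Defaults are the conditions the
pipeline is validated under: ρ_A = ρ_C = 0.75 (microdissection purity of
75–80%), mean depth 120 (exome-like), ~800 variants per pair split over the
classes, subclone fraction f = 0.3, and a 2% admixture of outliers drawn
uniformly on the MAF unit square (mimicking artifacts and
copy-number-displaced points).  Only copy-neutral diploid heterozygous SNVs
are simulated, because the clustering stage restricts itself to copy-neutral
autosomal SNVs anyway; depth overdispersion, tumor-in-normal contamination,
and cross-lesion contamination are not modeled — recovery results say
nothing about those failure modes.

**Microsatellite reads.**  Each locus has a true tract length L (10–30 bp).
A read observes L + d with the geometric stutter kernel P(d) ∝ s^|d|
truncated at |d| ≤ 3 (s = `stutter_prob`, default 0.1); at truly unstable
loci each tumor read is additionally shifted by `msi_shift` (default −3)
units with probability 0.5, giving the characteristic bimodal tumor
distribution.  The stutter model is a documented invention — real stutter is
length- and unit-dependent and asymmetric — so the power results quantify
behaviour under this noise model only.

**Depth profiles.**  Piecewise-constant tumor/normal profiles with Gaussian
depth noise and an optional smooth multiplicative GC wave
(2^(4·(gc−mean gc))) applied identically to both samples and recorded per
bin, so GC correction can be validated by comparing a corrected biased run
against the matching bias-free run.

All generators are deterministic given their config and seed.

## Regional classification (`variant_io`)

A variant is *present* in a lesion when alt reads ≥ 4 and MAF ≥ 0.05
(configurable; the thresholds operationalize "commonly observed" and are not
claimed to match any particular study's unstated criterion).  Present in
both lesions → clonal; one → lesion-specific; neither → absent.
High-confidence indels are those with MAF > 40% or coverage > 50× in a
lesion.  Substitution spectra use the six pyrimidine-context categories with
purine references complemented.

## Clustering and the verdict (`clonal_architecture`)

DBSCAN on the MAF unit square with Euclidean metric, reachability distance
eps = 0.01 (1% in MAF units) and min_pts = 5 (eps follows the 1% convention
for this analysis; min_pts is our choice).  Clusters holding < 1% of points
are discarded as outliers.  Cluster centers are coordinate-wise medians.
Per lesion a center is *absent* below 0.05, *clonal* at ≥ 0.6·ρ/2, else
*subclonal*; the pair of per-lesion categories maps to the four class labels
and anything else stays unlabeled.  Verdict: stepwise iff a retained
stepwise-intermediate cluster exists; parallel iff a clonal and at least one
lesion-specific cluster coexist without one; otherwise indeterminate.  Cases
with fewer than 50 usable points (the mutation-poor, microsatellite-stable
situation) are declared indeterminate outright.

**Purity.**  The public estimator is ρ̂ = 2 × (median MAF of the clonal
cluster), clipped to [0, 1].  Inside the pipeline one subtlety matters: at
eps = 0.01 the binomial MAF dispersion at depth ~100 (σ ≈ 0.045) makes
DBSCAN shave the clonal cloud's tails into small fragments, and anchoring the
estimate on a single fragment can bias ρ̂ by more than 0.1.  The pipeline
therefore anchors on the both-lesion cluster with the highest minimum center
coordinate (which also separates clonal from stepwise-intermediate clusters)
and takes 2 × the coordinate-wise median of *all* points within a 0.1 window
of that center, re-centering once.  The window is well below the separation
between mutation classes at the purities of interest, so no foreign class
leaks in; this recovers ρ within ±0.03 at depth 100 in the validation suite.

## MSI calling (`msi_caller`)

Reference microsatellites are maximal perfect tandem tracts of 1–4 bp units
with total length 7–60 bp.  Tracts are reported at their smallest fundamental
period with the lexicographically minimal rotation as the unit; `N` breaks
tracts; overlapping candidates resolve smallest-unit-first, then
longest-tract.  Mismatch-tolerant scoring (as in Sputnik-style scanners) is
deliberately not implemented: perfect-tract scanning is deterministic and
verifiable against a brute-force enumeration, which the test suite does on
random sequences.

Each read spanning a locus with ≥ 5 anchor bases on both sides contributes
one observed tract length (the maximal run of the locus unit at the expected
offset, so indels inside the tract shift the observation).  Per locus the
tumor and normal length multisets are compared with the two-sample
Kolmogorov–Smirnov statistic, D evaluated at all observed values (ties are
the norm for integer lengths), with the asymptotic p-value from the
Kolmogorov distribution at √(n_e)·D, n_e = mn/(m+n).  Loci with < 10 reads
in either sample are skipped.  Benjamini–Hochberg correction is applied per
comparison family (carcinoma-vs-normal and adenoma-vs-normal separately);
q < 0.05 is an MSI event.  Because independently called indels at the same
tract usually represent the same clonally fixed event, calls overlapping an
indel's reference span are flagged and excluded from the final event list;
the retained count always equals calls minus overlaps.  With heavy ties and
discrete support the asymptotic KS test is conservative, which the null
simulations confirm (observed false-positive rate ≈ 0 at α = 0.05).

## Copy number (`copy_number`)

Depths are GC-corrected per sample by dividing by (median depth of the bin's
2%-wide GC stratum / global median), sparse strata inheriting the nearest
populated stratum; then library-size normalized (tumor scaled so unmasked
totals match) and transformed to log2((t+0.5)/(n+0.5)).  Bins with normal
depth < 10 are masked.  Note that whole-library normalization shifts the
baseline when aberrations cover a large genome fraction — segment calls are
relative to the library baseline, as with any ratio-based method.

Segmentation is a native circular binary segmentation: on the circularized
signal, find the arc maximizing |mean_arc − mean_complement|·√(k(n−k)/n),
assess it by permutation (p = fraction of shuffles with an equal-or-larger
maximum; 1000 permutations, α = 0.01), split if significant and both parts
have ≥ 3 bins, and recurse.  The variance-pruning refinements of mature CBS
implementations ("undo splits") are intentionally omitted.  Permutations
stop early once the exceedance count already exceeds α·n_perm — the
accept/reject decision is identical to the full run — and the O(n²) arc scan
is JIT-compiled.  Deterministic under seed.  Segments with mean log2 ≥ +0.25
are gains, ≤ −0.25 losses (≈ one copy gained/lost at purity ~0.5–1 on this
scale); neutral segments define the clustering input region.

## Enrichment and reporting (`enrichment_report`)

Per gene and direction (clonal / adenoma-specific / carcinoma-specific) a
2×2 table of nonsilent mutation counts (gene vs all other genes ×
in-direction vs other classes) is tested with a two-sided Fisher's exact
test, pooled across cases, reported as raw p-values without multiple-testing
correction (a deliberate reporting choice for small candidate sets; treat
the values as descriptive).  For hypermutated microsatellite-unstable
genomes, recurrence of truncating events (nonsense/frameshift, ≥ 3 per gene
within a class) replaces the test.  The per-case summary is a trunk–branch
tree whose trunk is the clonal count and whose two branches are the
lesion-specific counts, serialized as
`((Adenoma:a,Carcinoma:c)LCA:t)Normal;`, with driver-gene and copy-number
annotations attached to the edge where they occur (copy-number events called
in both lesions go to the trunk).

## Numerical and design notes

- DBSCAN semantics: a core point counts itself among its ≥ min_pts
  neighbors; border points reachable from several clusters join the
  earliest-created one — the exact contract the brute-force
  density-reachability oracle (`bruteforce.dbscan_reference`) implements, so
  partitions are compared verbatim, not up to relabeling.
- Fisher's two-sided p sums hypergeometric probabilities ≤ the observed
  table's within a 1+1e-7 relative tolerance, matching the enumeration
  oracle to ~1e-16 over all margins ≤ 30.
- BH adjustment is the standard step-up; KS, Fisher and BH go through
  scipy/statsmodels, with independent oracles (exact enumeration, rational
  arithmetic) in `synclone.bruteforce`.
- Coordinates: VCF positions are 1-based; BED/locus/segment intervals
  0-based half-open; conversions happen at the interfaces only.
- Degenerate inputs: empty point sets cluster to nothing; constant signals
  yield one segment; (0,0) depth pairs give MAF 0 with a no-coverage flag;
  loci with insufficient reads are skipped and reported.

## Validation scale and limitations

The acceptance suite (and `scripts/acceptance.py`) uses 100 lesion-pair
simulations of ~816 variants for verdict recovery, 100 random instances
(≤ 200 points) for DBSCAN oracle equivalence, 50+50 seeds × 200 loci for MSI
error control and power, exhaustive enumeration for KS (all multiset pairs
of size ≤ 8 over three values) and Fisher (all margins ≤ 30), 1,000 random
2-kb sequences for the repeat scanner, 50 replicates of a 500-bin
single-step signal for CBS, and 60 runs for purity recovery — sizes chosen
so each block completes in seconds to a couple of minutes on one core.
Passing these says the machinery is correct under the stated generative
models; it does not certify performance on real exomes with mapping
artifacts, overdispersed depth, contaminated normals, or subclonal copy
number, none of which the simulators emulate.
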