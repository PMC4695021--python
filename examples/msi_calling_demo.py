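"""Call microsatellite instability events from simulated repeat-length reads.

Simulates tumor/normal repeat-length distributions (geometric PCR stutter; a
-3-unit mixture shift at truly unstable loci), runs the per-locus
Kolmogorov-Smirnov test with Benjamini-Hochberg FDR control, and compares the
calls against the generator's truth.
"""

from synclone.msi_caller import call_msi, group_distributions
from synclone.synthetic_data import MsiSimulationConfig, simulate_msi_observations

cfg = MsiSimulationConfig(n_null_loci=180, n_msi_loci=20, reads_per_locus=50,
                          stutter_prob=0.1, msi_shift=-3, seed=1)
loci, dists, truth = simulate_msi_observations(cfg)
calls, skipped = call_msi(
    group_distributions(dists, "carcinoma"),
    group_distributions(dists, "normal"),
    alpha=0.05,
)

tp = sum(c.is_msi and truth[c.locus_id] for c in calls)
fp = sum(c.is_msi and not truth[c.locus_id] for c in calls)
fn = sum(truth[c.locus_id] and not c.is_msi for c in calls)
print(f"loci tested: {len(calls)} (skipped for coverage: {len(skipped)})")
print(f"MSI calls (q < 0.05): {tp + fp}")
print(f"true positives: {tp}   false positives: {fp}   missed: {fn}")
top = sorted(calls, key=lambda c: c.q)[:3]
for c in top:
    print(f"  {c.locus_id}: D={c.D:.2f}  p={c.p:.2e}  q={c.q:.2e}  msi={c.is_msi}")

# At 50 reads per sample a half-mixture shift of -3 repeat units gives KS
# statistics near 0.5, so nearly all 20 unstable loci reach q < 0.05 while the
# stutter-only null loci stay quiet: the FDR threshold controls false calls.
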