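"""Mutation-spectrum statistics on a synthetic callset.

Collapses SNVs to the six strand-symmetric classes, reports Wilson 95%
intervals per class, the Ts/Tv ratio with a bootstrap interval, and the
G/C-site origin bias tested against the callable-site composition.
"""

import malines as m

config = m.SimulationConfig(seed=3, snv_rate=6e-8)  # more SNVs for a
experiment = m.generate_experiment(config)          # readable spectrum
snvs = [e for e in experiment.truth.events if e.category == "SNV"]
pairs = [e.ref_alts[0] for e in snvs]

summary = m.snv_spectrum(pairs, seed=0)
print(f"{len(pairs)} SNVs")
for klass, count in summary.class_counts.items():
    lo, hi = summary.wilson_ci[klass]
    print(f"  {klass}: {count:4d}  ({summary.proportions[klass]:.3f}, "
          f"Wilson 95% [{lo:.3f}, {hi:.3f}])")
print(f"Ts/Tv = {summary.ts_tv:.2f}, bootstrap 95% CI "
      f"({summary.ts_tv_ci[0]:.2f}, {summary.ts_tv_ci[1]:.2f})")

gc_fraction = (
    experiment.mask.callable_gc_sites() / experiment.mask.callable_sites()
)
observed, test = m.gc_at_bias(pairs, gc_fraction)
print(f"{observed:.1%} of SNVs at G/C sites vs {gc_fraction:.1%} of callable "
      f"sites (binomial p = {test.p_value:.2g})")
# a p-value well below 0.05 says mutations hit G/C sites more often than the
# genome's composition alone would produce.

indels = [e for e in experiment.truth.events if e.category == "INDEL"]
stats = m.indel_stats([e.indel_lengths[0] for e in indels])
print(f"indels: {stats['n_deletions']} deletions / {stats['n_insertions']} "
      f"insertions (deletion-bias p = {stats['deletion_bias_test'].p_value:.2g}); "
      f"median sizes {stats['median_deletion_bp']} / "
      f"{stats['median_insertion_bp']} bp")
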