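"""Simulate a small MA panel, run the calling pipeline, score recovery.

The generator plants mutations with known line, position and zygosity, plus
artifacts that must each trip one named filter; the pipeline should recover
the planted events exactly and reject every artifact for the right reason.
"""

import malines as m
from malines.simulate import score_recovery

config = m.SimulationConfig(
    seed=5,
    n_lines_per_group=(4, 5),
    contig_lengths={c: 500_000 for c in ("2L", "2R", "X")},
    te_insertion_rate={"dsb_plus": 0.2, "dsb_minus": 0.28},
    te_excision_rate={"dsb_plus": 0.05, "dsb_minus": 0.06},
    n_windows=100,
)
experiment = m.generate_experiment(config)
result = m.run_pipeline(
    experiment.records,
    experiment.sv_records,
    experiment.te_calls,
    experiment.line_meta,
    gene_track=experiment.gene_track,
)

print(f"callable sites: {experiment.mask.callable_sites():,} "
      f"of {experiment.mask.total_sites():,}")
print(f"mutation events called: {len(result.events)}  "
      f"de novo TE events: {len(result.te_de_novo)}")
report = score_recovery(
    result.events, result.te_de_novo, result.rejections, experiment.truth
)
for category, r in sorted(report["by_category"].items()):
    print(f"  {category:8s} precision={r['precision']:.2f} "
          f"recall={r['recall']:.2f} (tp={r['tp']})")
print("all planted artifacts rejected with the intended reason:",
      report["artifacts_all_ok"])
# precision = recall = 1.0 everywhere means the filter stack, clustering and
# TE merging reproduced the planted truth without false calls.
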