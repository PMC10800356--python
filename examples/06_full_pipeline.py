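"""Run the whole pipeline behind one configuration and inspect the report.

Simulation -> QC -> normalization -> candidate selection -> pairwise PCC ->
membership -> co-occupancy -> cell states -> quiescence -> DE -> enrichment,
with one global seed deriving every per-stage seed.
"""

import json

from escreg import PipelineConfig, SimConfig, run_pipeline

config = PipelineConfig(
    out_dir="scratch/example_run",
    seed=1,
    simulate=SimConfig(seed=1),
    exemplar_n=100,
)
report = run_pipeline(config)
reg = report["stages"]["regulome"]
print(f"regulome: {reg['n_members']}/{reg['n_candidates']} candidates kept "
      f"(sensitivity {reg['membership_sensitivity']:.2f}, "
      f"admission {reg['background_admission']:.2f})")
print(f"phase accuracy: {report['stages']['cellstate']['phase_accuracy']:.3f}")
print(f"quiescence precision/recall: "
      f"{report['stages']['quiescence']['precision']:.2f}/"
      f"{report['stages']['quiescence']['recall']:.2f}")
print(f"significant quiescent-vs-cycling genes: {report['stages']['de']['n_significant']}")
print("artifacts:", len(report["artifacts"]), "files under", config.out_dir)
print(json.dumps(report["stages"]["qc"], indent=2))
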