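"""Run the end-to-end monitoring pipeline and print its report.

Simulates a calibration batch and a monitored batch, trains the PLS moisture
model and the MSPC endpoint chart, follows the monitored batch in "real
time", and extracts the mass-transfer resistances from the NIR-predicted
drying curve.  Artefacts (models, charts, traces, report.json) land in
./pipeline_out.
"""

import json

from granudry.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=3), "pipeline_out")

print(json.dumps({k: report[k] for k in ("pls", "mspc", "endpoint",
                                         "resistance")}, indent=2))
print()
print("pls.e_rel_percent  : calibration error vs the LOD reference samples")
print("endpoint.time_min  : first of 10 consecutive sub-limit Q observations")
print("resistance.*       : Eq-of-state of the drying process, fitted from")
print("                     the NIR-predicted moisture of the monitored batch")
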