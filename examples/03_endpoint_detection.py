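"""Detect the drying endpoint with a Q-statistic control chart.

Builds a PCA model from endpoint spectra (moisture < 2 wt%) of seven
normal-operation batches, then monitors a fresh batch and a truncated
(off-specification) batch.  The endpoint is the first of 10 consecutive
Q values below the Jackson-Mudholkar 95% limit.
"""

import numpy as np

from granudry import (
    BedConfig,
    OpticsConfig,
    ResistanceFit,
    aggregate_isotherm,
    build_mspc,
    detect_endpoint,
    generate_spectra,
    load_formulation,
    q_statistic,
    simulate_drying,
)
from granudry.preprocess import preprocess_pipeline

formulation = load_formulation()
_, agg = aggregate_isotherm(formulation)
truth = ResistanceFit(omega_ext=0.028, omega_max=0.58, f_w_crit=0.10,
                      f_w_end=0.05)
run = simulate_drying(BedConfig(), truth, agg)                 # reaches ~1.5%
run_off = simulate_drying(BedConfig(), truth, agg, duration=3000.0)  # stops at ~7%


def preprocessed(batch, seed):
    return preprocess_pipeline(
        generate_spectra(batch, OpticsConfig(rng_seed=seed)), 10, 75)


# training: endpoint spectra from 7 NOC batches, labelled by the moisture of
# the material the smoothed spectrum actually measured (window-centroid lag)
lag = (75 - 1) / 2 * 10.0
rows = []
for seed in range(7):
    pp = preprocessed(run, seed)
    f_content = np.interp(np.maximum(pp.timestamps - lag, 0.0),
                          run.time, run.moisture_fraction)
    rows.append(pp.values[f_content < 0.02])
model = build_mspc(np.vstack(rows), n_pc="auto")
print(f"MSPC model: {model.n_pc} principal component(s), "
      f"Q limits {model.limit_95:.2e} (95%) / {model.limit_99:.2e} (99%)")

pp = preprocessed(run, 100)
q = q_statistic(model, pp.values)
ep = detect_endpoint(q, model.limit_95, run_length=10)
f_true = np.interp(pp.timestamps, run.time, run.moisture_fraction)
print(f"on-spec batch : endpoint at observation {ep + 1} "
      f"(t = {pp.timestamps[ep] / 60:.1f} min, true moisture "
      f"{100 * f_true[ep]:.2f} wt%)")

pp_off = preprocessed(run_off, 101)
ep_off = detect_endpoint(q_statistic(model, pp_off.values), model.limit_95, 10)
print(f"off-spec batch: endpoint {'NOT detected' if ep_off is None else ep_off}")
print()
print("Q measures how far a spectrum lies off the endpoint-spectra plane; it")
print("needs no moisture reference at monitoring time, only the NIR signal.")
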