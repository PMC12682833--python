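"""Tracer dose partitioning and excess-15N mass balance.

Partitions the facility tracer dose (1.51725 g 15N and 1 L labelled water
over 200 row sides), converts a grain sample's delta15N to tracer-derived
15N mass, and expresses it as percent recovery of the per-row dose.
"""

import pandas as pd

from rhizotrace import TracerDose, dose_per_row_side, excess_15n_g, recovery_percent, transform_for_model

dose = TracerDose()
print(f"15N per row side:  {dose.per_row_side_15n_g:.5f} g "
      f"({dose.total_15n_g} g over {dose.n_row_sides} row sides)")
print(f"2H2O per row side: {dose.per_row_side_2h2o_ml:.1f} mL")
print(f"15N applied per crop row: {dose.per_row_applied_15n_g:.5f} g (two sides)")

sample = dict(dry_mass_g=1400.0, n_pct=2.2, delta15N=28.0)
excess = excess_15n_g(**{k: v for k, v in sample.items() if k != "delta15N"},
                      delta15n=sample["delta15N"])
print(f"\ngrain sample ({sample['dry_mass_g']:.0f} g, {sample['n_pct']}%N, "
      f"delta15N {sample['delta15N']} permil): excess 15N = {excess * 1000:.3f} mg")

row = pd.DataFrame([dict(row_id="R1", tissue="grain", **sample)])
print(f"recovery of the per-row dose: {recovery_percent(row, dose):.1f} %")

ln15 = transform_for_model(pd.Series([sample["delta15N"]]), "15N").iloc[0]
print(f"model transform ln(delta15N) = {ln15:.3f} (used in the statistical models)")
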