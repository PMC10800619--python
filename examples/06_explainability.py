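"""Explain a trained model with per-token Shapley-style attributions.

Each prediction decomposes into a base value plus one additive contribution
per token.  Summing contributions across a class-balanced patient sample
ranks the features driving predictions population-wide; bin tokens are
rendered back to original units so the ranking reads clinically.
"""

from ehrseq import explain as ex
from ehrseq import pipeline as pl
from ehrseq import simulate as sim

study = pl.run_study(seed=0, n_patients=5000, disease="diabetes",
                     epochs=5, shap_n=120)

summary = ex.clinical_summary(study.shap_summary)
desc = sim.default_code_maps().descriptions

print("top clinical features by summed attribution:")
for row in summary.table.head(8).itertuples():
    label = ex.render_label(row.token, study.scaler, desc)
    print(f"  {row.rank:>2d}. {row.summed_shap:+8.3f}  (n={row.count:>4d})  "
          f"{label}")

print("\nplanted drivers:", study.driver_recovery["driver_tokens"])
print(f"recovered in top 10: {study.driver_recovery['n_recovered']} / "
      f"{study.driver_recovery['n_drivers']}")

ex_one = study.explanations[0]
print(f"\npatient {ex_one.patient_id}: score {ex_one.score:.3f} = "
      f"base {ex_one.base_value:.3f} + sum of {len(ex_one.tokens)} "
      f"contributions (gap {ex_one.additivity_gap:.2e})")
# High-ranked glucose/HbA1c top-bin tokens mirror how a clinician would read
# an elevated-lab history; the additivity gap bounds the approximation error
# of the attribution method.
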