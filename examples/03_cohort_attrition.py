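"""Select a disease cohort and audit the exclusion cascade.

Patients are labeled by first diagnosis inside the 2018-2020 prediction
window (descendant codes included); exclusions remove minors, near-empty
records, disqualifying diagnoses, pre-existing disease, and patients whose
medications or labs show undiagnosed disease.  The attrition table records
every step.
"""

from ehrseq import cohort as coh
from ehrseq import simulate as sim

cfg = sim.default_sim_config(n_patients=4000, seed=0)
patients, events, _ = sim.generate_population(cfg)
maps = cfg.code_maps

for disease in ("diabetes", "mi"):
    spec = coh.default_disease_cohort_specs()[disease]
    labels = coh.label_patients(events, spec,
                                hierarchy=maps.diagnosis_parent,
                                patient_ids=patients["patient_id"])
    res = coh.apply_exclusions(patients, events, labels, spec,
                               hierarchy=maps.diagnosis_parent,
                               med_atc=maps.med_atc)
    n_pos = sum(res.labels.values())
    print(f"\n=== {disease} ===")
    print(res.attrition_frame().to_string(index=False))
    print(f"cohort: {len(res.labels)} patients, {n_pos} cases "
          f"({100 * n_pos / len(res.labels):.1f}%)")
# MI keeps patients with prior infarctions (recurrence is predicted), so its
# pre-existing-disease step excludes nobody.
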