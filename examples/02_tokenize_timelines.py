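"""Turn raw event records into token timelines.

Numeric observation values are winsorized (1st/99th percentile), min-max
scaled against the training split, and mapped into ten decile bins, so
`8480-6_9` reads "systolic blood pressure in the top decile of the
population range".  Age tokens open each calendar year; race and gender
close the record.
"""

from datetime import date

import pandas as pd

from ehrseq import simulate as sim
from ehrseq import tokens as tok

cfg = sim.default_sim_config(n_patients=500, seed=0)
patients, events, _ = sim.generate_population(cfg)

cutoff = date(2018, 1, 1)  # feature cutoff = start of prediction window
train_events = events[events["date"] < pd.Timestamp(cutoff)]
scaler = tok.fit_observation_scaler(train_events)

seqs = tok.build_timelines(patients, events, scaler, cutoff, shuffle_seed=0)
seq = next(s for s in seqs if len(s) > 40)
print(f"patient {seq.patient_id}: {len(seq)} tokens up to {cutoff}")
print(" ".join(seq.tokens[:30]), "...")
print("terminal tokens:", seq.tokens[-2:])

print("\nde-normalized bins for systolic blood pressure (8480-6):")
for r in tok.denormalize_bins("8480-6", scaler)[6:]:
    print(f"  bin {r.bin_index}: {r.low:.1f}-{r.high:.1f} mmHg")
# The top bins correspond to hypertensive readings; those are the tokens
# the risk models and the attribution ranking operate on.
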