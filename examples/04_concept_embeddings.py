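"""Pre-train skip-gram concept embeddings and query neighbors.

Tokens that occur in similar clinical contexts — adjacent value bins,
consecutive ages, co-managed conditions — acquire nearby vectors.  Only
pre-cutoff history enters pre-training (leakage guard).
"""

from datetime import date

import pandas as pd

from ehrseq import embed as em
from ehrseq import simulate as sim
from ehrseq import tokens as tok

cfg = sim.default_sim_config(n_patients=4000, seed=0)
patients, events, _ = sim.generate_population(cfg)
cutoff = date(2018, 1, 1)
pre = events[events["date"] < pd.Timestamp(cutoff)]
scaler = tok.fit_observation_scaler(pre)
seqs = tok.build_timelines(patients, events, scaler, cutoff, shuffle_seed=0)

matrix = em.train_skipgram(seqs, d=64, window=5, epochs=3, min_count=5,
                           seed=0, max_cutoff=cutoff)
print(f"vocabulary: {len(matrix.vocabulary) - 2} tokens, d={matrix.d}")

desc = cfg.code_maps.descriptions
for probe in ("age_60", "8480-6_9", "44054006"):
    if probe not in matrix.vocabulary:
        continue
    print(f"\nneighbors of {probe}:")
    for t, s in em.nearest_neighbors(matrix, probe, k=5).neighbors:
        print(f"  {s:+.3f}  {t:22s} {desc.get(t.split('_')[0], '')}")
# Adjacent ages dominate age_60's neighbors because consecutive age tokens
# share contexts.  Value-bin locality (8480-6_8 near 8480-6_9) needs larger
# corpora than this quick demo: rare tokens first cluster by rarity.
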