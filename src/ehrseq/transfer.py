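"""Transfer-learning experiments with pre-trained concept embeddings.

Two protocols are supported:

* **within-population** — small labeled samples (500–6,000 positives at a
  60:40 negative:positive ratio, i.e. total sizes 1,250–15,000) are drawn
  from a held-out transfer pool; for each sample size and seed, a model is
  trained once with randomly initialized embeddings and once initialized
  from pre-trained vectors (fine-tuned), with an 80:20 train/validation
  split, and both are evaluated on the full test split at the real class
  distribution;
* **cross-region** — a geographic subpopulation is excluded from embedding
  pre-training entirely, then split 70:30 into its own transfer pool and
  test set, and the same sampling protocol is run against the out-of-region
  embeddings.

Manifest disjointness (embedding-training vs transfer pool vs test) is
asserted before any training run; results are persisted per seed so the
reported means can always be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import split_patients
from .embed import EmbeddingMatrix
from .errors import ConfigError, LeakageError, SamplingError
from .risk import ModelConfig, evaluate, predict_risk, train_model
from .tokens import TokenSequence

__all__ = [
    "TransferPlan",
    "TransferResult",
    "sample_transfer_set",
    "run_transfer_experiment",
    "region_holdout_protocol",
]


@dataclass
class TransferPlan:
    positive_sample_sizes: tuple[int, ...] = (500, 1000, 2000, 4000, 6000)
    ratio_neg_to_pos: float = 1.5
    n_seeds: int = 3
    arms: tuple[str, ...] = ("random_init", "finetuned_pretrained")
    seed: int = 0

    def __post_init__(self):
        if self.n_seeds < 1:
            raise ConfigError("n_seeds must be >= 1")
        sizes = list(self.positive_sample_sizes)
        if any(s <= 0 for s in sizes) or sizes != sorted(sizes):
            raise ConfigError(
                "positive_sample_sizes must be positive and increasing")


@dataclass
class TransferResult:
    per_run: pd.DataFrame      # size, arm, seed, roc_auc
    aggregate: pd.DataFrame    # size, arm, mean_roc_auc (+ per-size delta)

    @staticmethod
    def aggregate_from_runs(per_run: pd.DataFrame) -> pd.DataFrame:
        agg = (per_run.groupby(["size", "arm"])["roc_auc"]
               .mean().rename("mean_roc_auc").reset_index())
        wide = agg.pivot(index="size", columns="arm", values="mean_roc_auc")
        if {"finetuned_pretrained", "random_init"} <= set(wide.columns):
            wide["delta_pretrained_minus_random"] = (
                wide["finetuned_pretrained"] - wide["random_init"])
        return wide.reset_index()


def sample_transfer_set(labels: Mapping[str, int], n_pos: int,
                        ratio_neg_to_pos: float = 1.5,
                        seed: int = 0) -> list[str]:
    """Exactly ``n_pos`` positives plus ``ratio * n_pos`` negatives sampled
    without replacement from the pool (total 2.5x at the 60:40 default)."""
    pos = sorted(p for p, y in labels.items() if y == 1)
    neg = sorted(p for p, y in labels.items() if y == 0)
    n_neg = int(ratio_neg_to_pos * n_pos)
    if len(pos) < n_pos:
        raise SamplingError(
            f"pool has {len(pos)} positives, {n_pos} requested")
    if len(neg) < n_neg:
        raise SamplingError(
            f"pool has {len(neg)} negatives, {n_neg} requested")
    rng = np.random.default_rng(seed)
    take_pos = [pos[i] for i in rng.choice(len(pos), n_pos, replace=False)]
    take_neg = [neg[i] for i in rng.choice(len(neg), n_neg, replace=False)]
    return sorted(take_pos + take_neg)


def run_transfer_experiment(
    plan: TransferPlan,
    pool_sequences: Mapping[str, TokenSequence],
    pool_labels: Mapping[str, int],
    test_sequences: Mapping[str, TokenSequence],
    test_labels: Mapping[str, int],
    embeddings: EmbeddingMatrix,
    config: ModelConfig,
    embedding_manifest: set[str] | None = None,
) -> TransferResult:
    """Run every (size, seed, arm) cell of the plan and aggregate.

    ``embedding_manifest`` is the set of patient ids whose histories entered
    embedding pre-training; any overlap with the transfer pool or the test
    set is a leakage error."""
    if embedding_manifest is not None:
        for name, ids in (("transfer pool", pool_labels),
                          ("test set", test_labels)):
            overlap = embedding_manifest & set(ids)
            if overlap:
                raise LeakageError(
                    f"{len(overlap)} {name} patients present in the "
                    "embedding-training manifest")
    rows = []
    for n_pos in plan.positive_sample_sizes:
        for i in range(plan.n_seeds):
            rep_seed = plan.seed + i
            ids = sample_transfer_set(pool_labels, n_pos,
                                      plan.ratio_neg_to_pos, rep_seed)
            seqs = [pool_sequences[p] for p in ids]
            labels = {p: pool_labels[p] for p in ids}
            for arm in plan.arms:
                cfg = replace(config, embedding_mode=arm, seed=rep_seed,
                              val_fraction=0.2)
                model = train_model(
                    seqs, labels, cfg,
                    embeddings=embeddings if arm != "random_init" else None)
                scores = predict_risk(model,
                                      list(test_sequences.values()))
                report = evaluate(scores, test_labels)
                rows.append((n_pos, arm, rep_seed, report.roc_auc))
    per_run = pd.DataFrame(rows, columns=["size", "arm", "seed", "roc_auc"])
    return TransferResult(per_run,
                          TransferResult.aggregate_from_runs(per_run))


def region_holdout_protocol(
    patients: pd.DataFrame, region: str, seed: int = 0,
    transfer_fraction: float = 0.7,
) -> tuple[list[str], list[str], list[str]]:
    """Manifests for the cross-region protocol: (embedding-training ids
    excluding the region, region transfer-pool ids, region test ids)."""
    regions = set(patients["home_region"].astype(str))
    if region not in regions:
        raise ConfigError(f"unknown region {region!r}; have {sorted(regions)}")
    in_region = patients.loc[patients["home_region"] == region,
                             "patient_id"].astype(str).tolist()
    out_region = patients.loc[patients["home_region"] != region,
                              "patient_id"].astype(str).tolist()
    parts = split_patients(in_region, seed,
                           fractions=(transfer_fraction,
                                      1.0 - transfer_fraction, 0.0))
    transfer_ids, test_ids = parts["train_val"], parts["test"]
    assert not (set(out_region) & set(in_region))
    return sorted(out_region), sorted(transfer_ids), sorted(test_ids)
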