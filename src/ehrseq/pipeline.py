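"""End-to-end study orchestration on synthetic populations.

``run_study`` wires the whole pipeline together for one disease: generate a
population, select the cohort, split 90/5/5, fit the observation scaler on
the training split, build token timelines at the label cutoff, pre-train
skip-gram embeddings on pre-cutoff training histories, train the BiGRU
classifier on the 60:40 downsampled cohort, evaluate on the untouched test
split, and explain a class-balanced sample of test patients.

``run_transfer_study`` reuses a study's pre-trained embeddings against a
disjoint transfer population (statistically exchangeable with the
pre-training one) per the small-sample transfer protocol.

Default problem sizes are desk scale: tens of thousands of patients,
embedding dimension 64 and a few epochs, so a full study runs in minutes on
one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import cohort as coh
from . import embed as emb
from . import explain as expl
from . import risk
from . import simulate as sim
from . import tokens as tok
from . import transfer as trans
from .errors import LeakageError

__all__ = ["StudyResult", "run_study", "run_transfer_study"]


@dataclass
class StudyResult:
    disease: str
    seed: int
    patients: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    scaler: tok.ObservationScaler
    cohort: coh.CohortResult
    splits: dict[str, list[str]]
    timelines: dict[str, tok.TokenSequence]
    embeddings: emb.EmbeddingMatrix
    embedding_manifest: set[str]
    model: risk.RiskModel
    report: risk.EvalReport
    explanations: list = field(default_factory=list)
    shap_summary: expl.ShapSummary | None = None
    driver_recovery: dict | None = None


def _timeline_map(patients, events, scaler, cutoff, seed):
    seqs = tok.build_timelines(patients, events, scaler, cutoff,
                               shuffle_seed=seed)
    return {s.patient_id: s for s in seqs}


def run_study(
    seed: int,
    n_patients: int = 20_000,
    disease: str = "diabetes",
    d: int = 128,
    window: int = 5,
    sg_epochs: int = 5,
    sg_min_count: int = 5,
    gru_hidden: int = 64,
    epochs: int = 14,
    patience: int = 4,
    embedding_mode: str = "finetuned_pretrained",
    shap_n: int = 500,
    sim_config: sim.SimConfig | None = None,
) -> StudyResult:
    """Run the full pipeline for one disease and return every artifact."""
    cfg = sim_config or sim.default_sim_config(n_patients, seed)
    maps = cfg.code_maps
    patients, events, truth = sim.generate_population(cfg)
    windows = coh.DEFAULT_WINDOWS
    cutoff = windows.label_cutoff

    spec = coh.default_disease_cohort_specs()[disease]
    pre_events = events[events["date"] < pd.Timestamp(cutoff)]
    scaler = tok.fit_observation_scaler(pre_events)

    labels_all = coh.label_patients(events, spec, windows,
                                    hierarchy=maps.diagnosis_parent,
                                    patient_ids=patients["patient_id"])
    cohort_res = coh.apply_exclusions(
        patients, events, labels_all, spec, windows,
        hierarchy=maps.diagnosis_parent, med_atc=maps.med_atc, scaler=scaler)
    labels = cohort_res.labels
    cohort_ids = sorted(labels)

    splits = coh.split_patients(cohort_ids, seed)
    cohort_patients = patients[patients["patient_id"].isin(labels)]
    timelines = _timeline_map(cohort_patients, events, scaler, cutoff, seed)

    # pre-training: training split only, pre-cutoff histories by construction
    train_ids = splits["train_val"]
    embeddings = emb.train_skipgram(
        [timelines[p] for p in train_ids], d=d, window=window,
        epochs=sg_epochs, min_count=sg_min_count, seed=seed,
        max_cutoff=cutoff)
    manifest = set(train_ids)

    # 60:40 downsample of the training split, then train
    train_labels = {p: labels[p] for p in train_ids}
    balanced = coh.downsample_controls(train_labels, seed)
    config = risk.ModelConfig(
        embedding_mode=embedding_mode, d=d, gru_hidden=gru_hidden,
        epochs=epochs, patience=patience, seed=seed)
    model = risk.train_model(
        [timelines[p] for p in balanced],
        {p: labels[p] for p in balanced},
        config,
        embeddings=embeddings if embedding_mode != "random_init" else None)

    # evaluation on the untouched test split (real class distribution)
    test_ids = splits["test"]
    scores = risk.predict_risk(model, [timelines[p] for p in test_ids])
    report = risk.evaluate(scores, {p: labels[p] for p in test_ids})

    # explanation sample at the training class balance (40:60), drawn from
    # the train/validation pool: at desk scale the 5% test split cannot
    # support a class-balanced sample of useful size
    explanations, summary, recovery = [], None, None
    if shap_n:
        pool_labels = {p: labels[p] for p in balanced}
        n_pos_avail = sum(pool_labels.values())
        n = min(shap_n, int(n_pos_avail / 0.4), len(balanced))
        sample_ids = expl.sample_for_shap(pool_labels, n=n, seed=seed)
        explanations = expl.compute_shap(
            model, [timelines[p] for p in sample_ids], method="ig")
        summary = expl.summarize_population(explanations)
        recovery = driver_recovery_report(summary, cfg, disease)
    return StudyResult(
        disease=disease, seed=seed, patients=patients, events=events,
        truth=truth, scaler=scaler, cohort=cohort_res, splits=splits,
        timelines=timelines, embeddings=embeddings,
        embedding_manifest=manifest, model=model, report=report,
        explanations=explanations, shap_summary=summary,
        driver_recovery=recovery)


def driver_recovery_report(summary: expl.ShapSummary, cfg: sim.SimConfig,
                           disease: str, top_k: int = 10) -> dict:
    """How many planted drivers rank among the top summed-attribution
    tokens (a driver counts as recovered if any of its realizing tokens is
    in the top ``top_k``)."""
    spec = next(s for s in cfg.disease_specs if s.name == disease)
    token_sets = sim.planted_driver_token_sets(spec)
    top = list(expl.clinical_summary(summary).table.head(top_k)["token"])
    recovered = [bool(ts & set(top)) for ts in token_sets]
    return {
        "n_drivers": len(token_sets),
        "n_recovered": int(sum(recovered)),
        "top_tokens": top,
        "driver_tokens": [sorted(ts) for ts in token_sets],
    }


def run_transfer_study(
    seed: int,
    embeddings: emb.EmbeddingMatrix,
    embedding_manifest: set[str],
    n_pool_patients: int = 12_000,
    disease: str = "diabetes",
    plan: trans.TransferPlan | None = None,
    d: int = 128,
    gru_hidden: int = 64,
    epochs: int = 14,
    patience: int = 4,
    sim_config: sim.SimConfig | None = None,
) -> trans.TransferResult:
    """Small-sample transfer protocol against a disjoint transfer population.

    A fresh population (distinct id namespace) provides the transfer pool
    (70%) and the test set (30%); the supplied embeddings must have been
    trained with no overlap with either."""
    cfg = sim_config or sim.default_sim_config(n_pool_patients, seed + 1,
                                               id_prefix="t")
    maps = cfg.code_maps
    patients, events, _ = sim.generate_population(cfg)
    windows = coh.DEFAULT_WINDOWS
    cutoff = windows.label_cutoff
    if embedding_manifest & set(patients["patient_id"]):
        raise LeakageError("transfer population overlaps embedding manifest")

    spec = coh.default_disease_cohort_specs()[disease]
    pre_events = events[events["date"] < pd.Timestamp(cutoff)]
    scaler = tok.fit_observation_scaler(pre_events)
    labels_all = coh.label_patients(events, spec, windows,
                                    hierarchy=maps.diagnosis_parent,
                                    patient_ids=patients["patient_id"])
    cohort_res = coh.apply_exclusions(
        patients, events, labels_all, spec, windows,
        hierarchy=maps.diagnosis_parent, med_atc=maps.med_atc, scaler=scaler)
    labels = cohort_res.labels

    parts = coh.split_patients(sorted(labels), seed, fractions=(0.7, 0.3, 0.0))
    pool_ids, test_ids = parts["train_val"], parts["test"]
    cohort_patients = patients[patients["patient_id"].isin(labels)]
    timelines = _timeline_map(cohort_patients, events, scaler, cutoff, seed)

    plan = plan or trans.TransferPlan(positive_sample_sizes=(500,),
                                      n_seeds=3, seed=seed)
    config = risk.ModelConfig(d=d, gru_hidden=gru_hidden, epochs=epochs,
                              patience=patience, seed=seed)
    return trans.run_transfer_experiment(
        plan,
        {p: timelines[p] for p in pool_ids},
        {p: labels[p] for p in pool_ids},
        {p: timelines[p] for p in test_ids},
        {p: labels[p] for p in test_ids},
        embeddings, config, embedding_manifest=embedding_manifest)
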