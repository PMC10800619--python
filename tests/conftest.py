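"""Shared fixtures: a tiny synthetic population for fast module tests, a
hand-built 12-patient cohort fixture with hand-enumerated attrition, and one
session-scoped full-size study reused by the heavyweight end-to-end tests."""

from __future__ import annotations

from datetime import date as Date

import numpy as np
import pandas as pd
import pytest

from ehrseq import cohort as coh
from ehrseq import simulate as sim


@pytest.fixture(scope="session")
def tiny_population():
    cfg = sim.default_sim_config(400, seed=7)
    patients, events, truth, info = sim.generate_population(
        cfg, return_info=True)
    return {"config": cfg, "patients": patients, "events": events,
            "truth": truth, "info": info}


def _filler(pid, n=20, year=2012, code="430193006"):
    return [
        {"patient_id": pid, "date": pd.Timestamp(year, 1 + i % 12,
                                                 1 + i // 12),
         "domain": "procedure", "code": code,
         "value_numeric": np.nan, "value_categorical": None, "unit": None}
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def hand_cohort():
    """Twelve hand-built patients, each designed to trip exactly one
    exclusion rule (or to be labeled), plus the hand-enumerated attrition
    tables for all four disease specs."""
    rows = []

    def dx(pid, code, y, m=6, d=15):
        rows.append({"patient_id": pid, "date": pd.Timestamp(y, m, d),
                     "domain": "diagnosis", "code": code,
                     "value_numeric": np.nan, "value_categorical": None,
                     "unit": None})

    def med(pid, code, y):
        rows.append({"patient_id": pid, "date": pd.Timestamp(y, 3, 1),
                     "domain": "medication", "code": code,
                     "value_numeric": np.nan, "value_categorical": None,
                     "unit": None})

    demo = []
    for i in range(1, 13):
        pid = f"h{i:02d}"
        demo.append({"patient_id": pid,
                     "birth_year": 2005 if i == 1 else 1960,
                     "gender": "female", "race": "unknown",
                     "home_region": "midwest"})
        rows.extend(_filler(pid, n=5 if i == 2 else 20))
    dx("h03", "46635009", 2014)        # type 1 diabetes -> diabetes excl dx
    dx("h03", "302866003", 2015)       # hypoglycemia (same step)
    dx("h04", "44054006", 2015)        # pre-existing T2DM
    med("h05", "ndc498010", 2016)      # A10 med, no diabetes dx
    dx("h06", "44054006", 2019, 5, 1)  # first T2DM inside prediction window
    dx("h07", "59621000", 2015)        # pre-existing hypertension
    med("h08", "ndc310798", 2016)      # C03 med, no hypertension dx
    dx("h09", "13645005", 2013)        # pre-existing COPD
    med("h10", "ndc745679", 2016)      # R03 med, no COPD dx
    dx("h11", "57054005", 2014)        # prior MI (retained for MI spec)
    dx("h11", "57054005001", 2019)     # descendant MI code in window
    # h12: clean control

    patients = pd.DataFrame(demo)
    events = pd.DataFrame(rows)

    expected_attrition = {
        "diabetes": [("initial", 0, 12), ("age_under_18", 1, 11),
                     ("short_record", 1, 10), ("exclusion_diagnosis", 1, 9),
                     ("pre_existing_disease", 1, 8),
                     ("exclusion_medication_or_lab", 1, 7)],
        "hypertension": [("initial", 0, 12), ("age_under_18", 1, 11),
                         ("short_record", 1, 10),
                         ("exclusion_diagnosis", 0, 10),
                         ("pre_existing_disease", 1, 9),
                         ("exclusion_medication_or_lab", 1, 8)],
        "copd": [("initial", 0, 12), ("age_under_18", 1, 11),
                 ("short_record", 1, 10), ("exclusion_diagnosis", 0, 10),
                 ("pre_existing_disease", 1, 9),
                 ("exclusion_medication_or_lab", 1, 8)],
        "mi": [("initial", 0, 12), ("age_under_18", 1, 11),
               ("short_record", 1, 10), ("exclusion_diagnosis", 0, 10),
               ("pre_existing_disease", 0, 10),
               ("exclusion_medication_or_lab", 0, 10)],
    }
    expected_labels = {
        "diabetes": {"h06": 1},
        "hypertension": {},
        "copd": {},
        "mi": {"h11": 1},
    }
    return {"patients": patients, "events": events,
            "expected_attrition": expected_attrition,
            "expected_labels": expected_labels,
            "maps": sim.default_code_maps(),
            "windows": coh.DEFAULT_WINDOWS}


@pytest.fixture(scope="session")
def full_study():
    """The full-size end-to-end study (generation, cohort, embeddings,
    BiGRU, evaluation, attributions) shared by the heavyweight tests."""
    from ehrseq import pipeline as pl
    return pl.run_study(seed=1, n_patients=20_000, shap_n=500)


@pytest.fixture(scope="session")
def transfer_study(full_study):
    from ehrseq import pipeline as pl
    return pl.run_transfer_study(
        seed=1, embeddings=full_study.embeddings,
        embedding_manifest=full_study.embedding_manifest)
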