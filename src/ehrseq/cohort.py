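"""Cohort selection: windowing, labeling, exclusions, splits and balancing.

The study design divides time into an observation window (features) and a
prediction window (outcomes).  A patient is a case (label 1) if their first
diagnosis of the target disease — after expanding the target codes to all
hierarchy descendants — falls inside the prediction window, and a control
(label 0) if the disease never appears.  Patients first diagnosed before the
window start carry the disease already and are excluded, except for acute
recurrent outcomes (myocardial infarction) where prior disease is allowed
and any in-window event counts as a case.

Exclusions are applied in a fixed order and recorded step by step in an
attrition table so cohorts are auditable and comparable across runs:

1. age under 18 at the start of the prediction window;
2. fewer than 20 recorded items inside the observation window;
3. presence of a disqualifying diagnosis (e.g. type 1 diabetes for the
   type 2 cohort);
4. pre-existing target diagnosis (skipped when prior disease is allowed);
5. disease-typical medication classes (ATC prefixes) or diagnostic lab
   values without any target diagnosis — patients who plainly have the
   disease but lack a diagnosis code.

Model training uses a 90/5/5 train-validation / test / transfer split and
trains on a 60:40 control:case downsample; evaluation always uses the
untouched test split at the real class distribution.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, HierarchyError

__all__ = [
    "DiseaseSpec",
    "StudyWindows",
    "CohortResult",
    "expand_descendants",
    "label_patients",
    "apply_exclusions",
    "split_patients",
    "downsample_controls",
    "default_disease_cohort_specs",
]


@dataclass
class DiseaseSpec:
    """Cohort definition for one disease (target codes are expanded to all
    hierarchy descendants before use)."""

    name: str
    target_codes: set[str]
    exclusion_diagnoses: set[str] = field(default_factory=set)
    exclusion_medication_classes: set[str] = field(default_factory=set)
    exclusion_lab_rule: Callable[[pd.DataFrame], "pd.Series | None"] | None = None
    allow_prior_disease: bool = False

    def __post_init__(self):
        if not self.target_codes:
            raise ConfigError(f"DiseaseSpec[{self.name}].target_codes empty")


@dataclass(frozen=True)
class StudyWindows:
    observation: tuple[Date, Date]
    prediction: tuple[Date, Date]

    @property
    def label_cutoff(self) -> Date:
        """Start of the prediction window; also the feature-truncation date."""
        return self.prediction[0]

    def __post_init__(self):
        if not (self.observation[0] < self.label_cutoff
                <= self.prediction[0] < self.prediction[1]):
            raise ConfigError("StudyWindows: observation.start < label_cutoff "
                              "<= prediction.start < prediction.end required")


DEFAULT_WINDOWS = StudyWindows(
    observation=(Date(2010, 1, 1), Date(2018, 12, 31)),
    prediction=(Date(2018, 1, 1), Date(2020, 12, 31)),
)


@dataclass
class CohortResult:
    labels: dict[str, int]
    attrition: list[tuple[str, int, int]]   # (step, n_excluded, n_remaining)

    def attrition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.attrition,
                            columns=["step", "excluded", "remaining"])


def default_disease_cohort_specs() -> dict[str, DiseaseSpec]:
    """Cohort definitions for the four default diseases, keyed by name.

    Target/exclusion codes and ATC class prefixes follow the standard
    chronic-disease cohort conventions: anti-diabetics (A10) for type 2
    diabetes; anti-hypertensives, diuretics, beta blockers, calcium channel
    blockers and renin-angiotensin agents (C02/C03/C07/C08/C09) for
    hypertension; obstructive-airway drugs (R03) for COPD.  MI allows prior
    disease — repeat infarctions are predicted, and patients on heart
    medication are retained.
    """
    # diagnostic labs: repeated (>= 2) glucose values in the top decile bin
    glucose_top = _binned_lab_rule("2345-7", {9}, min_count=2)
    return {
        "diabetes": DiseaseSpec(
            name="diabetes",
            target_codes={"44054006"},
            exclusion_diagnoses={"46635009", "302866003"},
            exclusion_medication_classes={"A10"},
            exclusion_lab_rule=glucose_top,
        ),
        "hypertension": DiseaseSpec(
            name="hypertension",
            target_codes={"59621000"},
            exclusion_medication_classes={"C02", "C03", "C07", "C08", "C09"},
        ),
        "copd": DiseaseSpec(
            name="copd",
            target_codes={"13645005"},
            exclusion_medication_classes={"R03"},
        ),
        "mi": DiseaseSpec(
            name="mi",
            target_codes={"57054005"},
            allow_prior_disease=True,
        ),
    }


def _binned_lab_rule(code: str, bins: set[int], min_count: int = 1):
    """Predicate: patient has at least ``min_count`` observations of
    ``code`` whose decile bin (against the supplied scaler bounds) is in
    ``bins``.  Returns a callable (events, scaler) -> boolean Series per
    patient id."""

    def rule(events: pd.DataFrame, scaler=None) -> pd.Series:
        if scaler is None or code not in scaler:
            return pd.Series(dtype=bool)
        lo, hi = scaler.bounds(code)
        obs = events[(events["domain"] == "observation")
                     & (events["code"] == code)
                     & events["value_numeric"].notna()]
        if not len(obs):
            return pd.Series(dtype=bool)
        v = np.clip(obs["value_numeric"].to_numpy(dtype=float), lo, hi)
        x = (v - lo) / (hi - lo) if hi > lo else np.zeros(len(v))
        b = np.searchsorted(np.arange(1, 10) / 10.0, x, side="right")
        hit = obs.loc[np.isin(b, list(bins)), "patient_id"]
        n = hit.value_counts()
        return pd.Series(True, index=n.index[n >= min_count])

    rule.code = code
    rule.bins = bins
    rule.min_count = min_count
    return rule


# ---------------------------------------------------------------------------


def expand_descendants(codes: Iterable[str],
                       hierarchy: Mapping[str, str]) -> set[str]:
    """Input codes plus all transitive descendants under a child->parent
    is-a map.  Raises :class:`HierarchyError` on a cycle."""
    children: dict[str, list[str]] = {}
    for child, parent in hierarchy.items():
        children.setdefault(parent, []).append(child)
    # cycle check over the full map
    state: dict[str, int] = {}
    for node in hierarchy:
        seen = set()
        cur = node
        while cur in hierarchy:
            if cur in seen:
                raise HierarchyError(f"cycle involving code {cur!r}")
            if state.get(cur) == 2:
                break
            seen.add(cur)
            cur = hierarchy[cur]
        for s in seen:
            state[s] = 2
    out = set(codes)
    queue = deque(out)
    while queue:
        node = queue.popleft()
        for ch in children.get(node, ()):
            if ch not in out:
                out.add(ch)
                queue.append(ch)
    return out


def _first_target_dates(events: pd.DataFrame, codes: set[str]) -> pd.Series:
    hits = events[(events["domain"] == "diagnosis")
                  & events["code"].isin(codes)]
    return hits.groupby("patient_id")["date"].min()


def label_patients(
    events: pd.DataFrame,
    spec: DiseaseSpec,
    windows: StudyWindows = DEFAULT_WINDOWS,
    hierarchy: Mapping[str, str] | None = None,
    patient_ids: Iterable[str] | None = None,
) -> dict[str, int]:
    """Binary onset labels.

    Label 1 iff the first target diagnosis (all descendants included) falls
    inside the prediction window; with ``allow_prior_disease``, iff *any*
    target diagnosis falls inside the window.  Patients whose first target
    diagnosis predates the window are pre-existing and handled by
    :func:`apply_exclusions` (they keep a provisional label here).
    """
    targets = expand_descendants(spec.target_codes, hierarchy or {})
    start = pd.Timestamp(windows.prediction[0])
    end = pd.Timestamp(windows.prediction[1])
    if patient_ids is None:
        patient_ids = pd.unique(events["patient_id"])
    labels = {str(p): 0 for p in patient_ids}
    hits = events[(events["domain"] == "diagnosis")
                  & events["code"].isin(targets)]
    if spec.allow_prior_disease:
        dates = pd.to_datetime(hits["date"])
        in_window = hits.loc[(dates >= start) & (dates <= end), "patient_id"]
        for p in pd.unique(in_window):
            labels[str(p)] = 1
    else:
        first = _first_target_dates(hits, targets)
        for p, d in first.items():
            d = pd.Timestamp(d)
            if start <= d <= end:
                labels[str(p)] = 1
    return labels


def apply_exclusions(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    labels: Mapping[str, int],
    spec: DiseaseSpec,
    windows: StudyWindows = DEFAULT_WINDOWS,
    hierarchy: Mapping[str, str] | None = None,
    med_atc: Mapping[str, str] | None = None,
    scaler=None,
) -> CohortResult:
    """Sequential cohort exclusions with an ordered attrition table."""
    hierarchy = hierarchy or {}
    med_atc = med_atc or {}
    targets = expand_descendants(spec.target_codes, hierarchy)
    cutoff = pd.Timestamp(windows.label_cutoff)
    obs_start = pd.Timestamp(windows.observation[0])

    pts = patients.set_index(patients["patient_id"].astype(str))
    remaining = set(pts.index)
    attrition: list[tuple[str, int, int]] = [("initial", 0, len(remaining))]

    def record(step: str, excluded: set[str]):
        nonlocal remaining
        excluded &= remaining
        remaining -= excluded
        attrition.append((step, len(excluded), len(remaining)))

    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    ev["patient_id"] = ev["patient_id"].astype(str)

    # 1. age under 18 at the start of the prediction window
    age = windows.label_cutoff.year - pts["birth_year"].astype(int)
    record("age_under_18", set(age.index[age < 18]))

    # 2. record length < 20 items inside the observation window (raw events,
    #    before any synthetic age/demographic token insertion)
    in_win = ev[(ev["date"] >= obs_start) & (ev["date"] < cutoff)]
    n_items = in_win.groupby("patient_id").size()
    counts = n_items.reindex(pts.index, fill_value=0)
    record("short_record", set(counts.index[counts < 20]))

    # 3. disqualifying diagnoses (descendants included)
    excl_dx = expand_descendants(spec.exclusion_diagnoses, hierarchy) \
        if spec.exclusion_diagnoses else set()
    has_excl = set(ev.loc[(ev["domain"] == "diagnosis")
                          & ev["code"].isin(excl_dx), "patient_id"]) \
        if excl_dx else set()
    record("exclusion_diagnosis", has_excl)

    # 4. pre-existing target disease (unless prior disease is allowed)
    if spec.allow_prior_disease:
        record("pre_existing_disease", set())
    else:
        first = _first_target_dates(ev, targets)
        pre = set(first.index[pd.to_datetime(first.values) < cutoff].astype(str))
        record("pre_existing_disease", pre)

    # 5. disease-typical medication or diagnostic labs without any diagnosis
    undx = {p for p in remaining
            if labels.get(p, 0) == 0} - set(
                ev.loc[(ev["domain"] == "diagnosis")
                       & ev["code"].isin(targets), "patient_id"])
    flagged: set[str] = set()
    if spec.exclusion_medication_classes:
        meds = ev[ev["domain"] == "medication"].copy()
        atc = meds["code"].map(lambda c: med_atc.get(c, ""))
        prefixes = tuple(spec.exclusion_medication_classes)
        hit = meds.loc[atc.str.startswith(prefixes), "patient_id"]
        flagged |= set(hit) & undx
    if spec.exclusion_lab_rule is not None:
        hit = spec.exclusion_lab_rule(ev, scaler)
        flagged |= set(hit.index[hit]) & undx
    record("exclusion_medication_or_lab", flagged)

    kept_labels = {p: int(labels.get(p, 0)) for p in sorted(remaining)}
    return CohortResult(labels=kept_labels, attrition=attrition)


def split_patients(patient_ids: Iterable[str], seed: int,
                   fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)
                   ) -> dict[str, list[str]]:
    """Deterministic disjoint train_val / test / transfer partition."""
    ids = sorted(str(p) for p in patient_ids)
    if len(set(ids)) != len(ids):
        raise ConfigError("patient_ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_test = int(round(n * fractions[1]))
    n_transfer = int(round(n * fractions[2]))
    n_train = n - n_test - n_transfer
    shuffled = [ids[i] for i in order]
    return {
        "train_val": shuffled[:n_train],
        "test": shuffled[n_train:n_train + n_test],
        "transfer": shuffled[n_train + n_test:],
    }


def downsample_controls(labels: Mapping[str, int], seed: int,
                        ratio_neg_to_pos: float = 1.5) -> list[str]:
    """Keep all cases; sample controls without replacement down to
    ``floor(ratio * n_pos)`` (60:40 at the default ratio).  If there are too
    few controls, all are kept and a warning is logged."""
    pos = sorted(p for p, y in labels.items() if y == 1)
    neg = sorted(p for p, y in labels.items() if y == 0)
    if not pos:
        raise ConfigError("downsample_controls requires at least one positive")
    n_keep = int(ratio_neg_to_pos * len(pos))
    if len(neg) <= n_keep:
        if len(neg) < n_keep:
            import logging
            logging.getLogger(__name__).warning(
                "only %d controls available for %d requested", len(neg), n_keep
            )
        kept = neg
    else:
        rng = np.random.default_rng(seed)
        kept = [neg[i] for i in rng.choice(len(neg), size=n_keep,
                                           replace=False)]
    return sorted(pos + kept)
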