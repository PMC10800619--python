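"""Seeded synthetic longitudinal EHR populations.

The generator emulates the statistical structure of a large US claims/EMR
extract at desk scale: per-patient visit clusters over a multi-year period,
SNOMED-style diagnosis/procedure codes with a toy is-a hierarchy, NDC-style
medication codes mapped to ATC classes, LOINC-style observations with
numeric values or categorical outcomes, admission types, smoking/alcohol
habit records, insurance-type changes, demographics, right-truncation
(dropout), and disease onset driven by planted token-level risk factors.

Onset model
-----------
Each disease has a set of *driver* risk factors.  Patient ``i``'s count
``c_ij`` of driver ``j`` is Poisson; the probability of onset within the
prediction window is ``sigmoid(b0 + sum_j w_j c_ij + a * (age-55)/10 +
region shift)``, with ``b0`` calibrated by root finding so the population
mean equals the configured prevalence.  Driver observation events are
emitted with values drawn from the extreme decile of the code's value
distribution, so the decile-binned token — not the raw code — carries the
signal.  At onset, a diagnosis event with the disease code (root or a toy
descendant) is emitted, followed by disease-consistent medication events.

Everything is drawn from one ``numpy`` generator seeded by ``config.seed``
in a fixed order, so a configuration reproduces byte-identical populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

__all__ = [
    "ObsCodeSpec",
    "CodeMaps",
    "Driver",
    "SimDiseaseSpec",
    "RegionEffect",
    "SimConfig",
    "default_code_maps",
    "default_sim_config",
    "generate_population",
    "planted_driver_token_sets",
    "write_event_tables",
    "read_event_tables",
    "EVENT_COLUMNS",
    "PATIENT_COLUMNS",
    "TRUTH_COLUMNS",
]

EVENT_COLUMNS = [
    "patient_id", "date", "domain", "code",
    "value_numeric", "value_categorical", "unit",
]
PATIENT_COLUMNS = ["patient_id", "birth_year", "gender", "race", "home_region"]
TRUTH_COLUMNS = ["patient_id", "disease", "onset_date", "latent_risk"]


@dataclass(frozen=True)
class ObsCodeSpec:
    description: str
    unit: str
    mean: float
    sd: float


@dataclass
class CodeMaps:
    """The toy coding world: hierarchy, class maps and descriptions."""

    diagnosis_parent: dict[str, str]          # child -> parent (is-a)
    med_atc: dict[str, str]                   # medication code -> ATC class
    obs_numeric: dict[str, ObsCodeSpec]
    obs_categorical: dict[str, list[str]]     # code -> outcomes
    descriptions: dict[str, str]
    background_diagnoses: list[str]
    background_procedures: list[str]
    background_medications: list[str]
    admission_types: list[str]
    insurance_types: list[str]
    races: list[str]
    regions: list[str]
    exclusion_noise_diagnoses: list[str]
    exclusion_noise_medications: list[str]


@dataclass(frozen=True)
class Driver:
    """A planted token-level risk factor.

    kind: ``diagnosis`` | ``medication`` | ``obs_high`` | ``obs_low`` |
    ``habit``.  ``rate`` is the Poisson mean of the per-patient count;
    ``weight`` its log-odds contribution per occurrence.
    """

    kind: str
    code: str
    weight: float
    rate: float
    habit_value: str = "yes"

    def key(self) -> tuple[str, str, str]:
        return (self.kind, self.code, self.habit_value)


@dataclass
class SimDiseaseSpec:
    name: str
    onset_codes: list[str]            # diagnosis codes emitted at onset
    prevalence: float                 # target onset fraction in the window
    drivers: list[Driver]
    onset_medications: list[str]
    age_coef: float = 0.4             # log-odds per decade above 55


@dataclass(frozen=True)
class RegionEffect:
    visit_rate_mult: float = 1.0
    prevalence_shift: float = 0.0     # added to the linear predictor


@dataclass
class SimConfig:
    n_patients: int
    seed: int
    period: tuple[Date, Date] = (Date(2010, 1, 1), Date(2020, 12, 31))
    onset_window: tuple[Date, Date] = (Date(2018, 1, 1), Date(2020, 12, 31))
    disease_specs: list[SimDiseaseSpec] = field(default_factory=list)
    dropout_rate: float = 0.02        # per-year truncation hazard
    visits_per_year: float = 3.0
    events_per_visit: tuple[int, int] = (1, 8)
    birth_year_range: tuple[int, int] = (1930, 2006)
    exclusion_noise_rate: float = 0.015
    # shared patient frailty: gamma(shape, 1/shape) multiplies every driver
    # rate, so risk factors co-occur within patients
    frailty_shape: float = 2.0
    # within-patient repeatability of observation values (correlation of a
    # patient's repeat measurements of one code)
    value_consistency: float = 0.6
    region_weights: dict[str, float] = field(default_factory=dict)
    region_effects: dict[str, RegionEffect] = field(default_factory=dict)
    code_maps: CodeMaps | None = None
    id_prefix: str = "p"

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.period[0] >= self.period[1]:
            raise ConfigError("period start must precede period end")
        if not (self.period[0] <= self.onset_window[0] < self.onset_window[1]
                <= self.period[1]):
            raise ConfigError("onset_window must lie inside period")
        if self.events_per_visit[0] < 1 or \
                self.events_per_visit[0] > self.events_per_visit[1]:
            raise ConfigError("events_per_visit must satisfy 1 <= lo <= hi")
        if self.frailty_shape <= 0:
            raise ConfigError("frailty_shape must be > 0")
        if not (0.0 <= self.value_consistency < 1.0):
            raise ConfigError("value_consistency must be in [0, 1)")
        for spec in self.disease_specs:
            if not (0.0 < spec.prevalence < 1.0):
                raise ConfigError(
                    f"disease_specs[{spec.name}].prevalence must be in (0, 1)"
                )
            for d in spec.drivers:
                if not np.isfinite(d.weight):
                    raise ConfigError(
                        f"disease_specs[{spec.name}] driver {d.code}: "
                        "weight must be finite"
                    )
                if d.rate < 0:
                    raise ConfigError(
                        f"disease_specs[{spec.name}] driver {d.code}: "
                        "rate must be >= 0"
                    )


# ---------------------------------------------------------------------------
# default toy world


def default_code_maps() -> CodeMaps:
    descriptions = {
        # disease roots and toy descendants (SNOMED-style identifiers)
        "44054006": "Type 2 diabetes mellitus",
        "44054006001": "Type II diabetes mellitus uncontrolled",
        "44054006002": "Disorder due to type 2 diabetes mellitus",
        "59621000": "Essential hypertension",
        "59621000001": "Benign essential hypertension",
        "13645005": "Chronic obstructive pulmonary disease",
        "13645005001": "Acute exacerbation of chronic obstructive airways disease",
        "57054005": "Acute myocardial infarction",
        "57054005001": "Acute myocardial infarction of anterior wall",
        "57054005002": "Acute subendocardial infarction",
        # exclusion diagnoses
        "46635009": "Type 1 diabetes mellitus",
        "302866003": "Hypoglycemia",
        # risk-factor diagnoses (planted drivers)
        "414916001": "Obesity",
        "55822004": "Hyperlipidemia",
        "77176002": "Tobacco dependence",
        "195967001": "Asthma",
        "63480004": "Chronic bronchitis",
        "53741008": "Coronary arteriosclerosis",
        # background diagnoses
        "195662009": "Acute viral pharyngitis",
        "444814009": "Viral sinusitis",
        "271737000": "Anemia",
        "82423001": "Chronic pain",
        "35489007": "Depressive disorder",
        "193462001": "Insomnia",
        "39848009": "Whiplash injury to neck",
        "70704007": "Sprain of wrist",
        "36971009": "Sinusitis",
        "40055000": "Chronic sinusitis",
        "68496003": "Polyp of colon",
        "26929004": "Alzheimer's disease",
        # procedures
        "399208008": "Plain chest X-ray",
        "104326007": "Blood chemistry panel",
        "268400002": "12 lead ECG",
        "171207006": "Depression screening",
        "430193006": "Medication reconciliation",
        "76601001": "Intramuscular injection",
        "225158009": "Fall risk assessment",
        "443529005": "Colonoscopy screening",
        # medications (NDC-style toy codes)
        "ndc498010": "Metformin 500 MG oral tablet",
        "ndc120001": "Methyldopa 250 MG oral tablet",
        "ndc310798": "Hydrochlorothiazide 25 MG oral tablet",
        "ndc866511": "Metoprolol tartrate 50 MG oral tablet",
        "ndc197361": "Amlodipine 5 MG oral tablet",
        "ndc314076": "Lisinopril 10 MG oral tablet",
        "ndc745679": "Albuterol 0.09 MG/ACTUAT inhaler",
        "ndc617312": "Atorvastatin 20 MG oral tablet",
        "ndc243670": "Aspirin 81 MG oral tablet",
        "ndc313782": "Acetaminophen 325 MG oral tablet",
        "ndc834061": "Amoxicillin 500 MG oral capsule",
        "ndc904639": "Omeprazole 20 MG oral capsule",
        "ndc312961": "Sertraline 50 MG oral tablet",
        "ndc966571": "Levothyroxine 50 UG oral tablet",
        # numeric observations (LOINC-style)
        "8480-6": "Systolic blood pressure",
        "8462-4": "Diastolic blood pressure",
        "39156-5": "Body mass index BMI (Ratio)",
        "2345-7": "Glucose [Mass/volume] in Serum or Plasma",
        "4548-4": "Hemoglobin A1c/Hemoglobin.total in Blood",
        "2093-3": "Cholesterol [Mass/volume] in Serum or Plasma",
        "2571-8": "Triglyceride [Mass/volume] in Serum or Plasma",
        "718-7": "Hemoglobin [Mass/volume] in Blood",
        "2160-0": "Creatinine [Mass/volume] in Serum or Plasma",
        "8867-4": "Heart rate",
        "20150-9": "FEV1 [Volume] Respiratory system",
        # categorical observations
        "10331-6": "Rh [Type] in Blood",
        "80382-5": "Influenza virus A Ag [Presence]",
    }
    diagnosis_parent = {
        "44054006001": "44054006",
        "44054006002": "44054006",
        "59621000001": "59621000",
        "13645005001": "13645005",
        "57054005001": "57054005",
        "57054005002": "57054005",
        "40055000": "36971009",
    }
    med_atc = {
        "ndc498010": "A10",
        "ndc120001": "C02",
        "ndc310798": "C03",
        "ndc866511": "C07",
        "ndc197361": "C08",
        "ndc314076": "C09",
        "ndc745679": "R03",
        "ndc617312": "C10",
        "ndc243670": "B01",
        "ndc313782": "N02",
        "ndc834061": "J01",
        "ndc904639": "A02",
        "ndc312961": "N06",
        "ndc966571": "H03",
    }
    obs_numeric = {
        "8480-6": ObsCodeSpec("Systolic blood pressure", "mmHg", 122.0, 14.0),
        "8462-4": ObsCodeSpec("Diastolic blood pressure", "mmHg", 78.0, 9.0),
        "39156-5": ObsCodeSpec("Body mass index BMI (Ratio)", "kg/m2", 27.0, 5.0),
        "2345-7": ObsCodeSpec("Glucose", "mg/dL", 98.0, 18.0),
        "4548-4": ObsCodeSpec("Hemoglobin A1c", "%", 5.5, 0.6),
        "2093-3": ObsCodeSpec("Total cholesterol", "mg/dL", 190.0, 35.0),
        "2571-8": ObsCodeSpec("Triglyceride", "mg/dL", 120.0, 50.0),
        "718-7": ObsCodeSpec("Hemoglobin", "g/dL", 14.0, 1.3),
        "2160-0": ObsCodeSpec("Creatinine", "mg/dL", 0.95, 0.2),
        "8867-4": ObsCodeSpec("Heart rate", "bpm", 72.0, 10.0),
        "20150-9": ObsCodeSpec("FEV1", "L", 3.0, 0.7),
    }
    obs_categorical = {
        "10331-6": ["positive", "negative"],
        "80382-5": ["positive", "negative", "not detected"],
    }
    return CodeMaps(
        diagnosis_parent=diagnosis_parent,
        med_atc=med_atc,
        obs_numeric=obs_numeric,
        obs_categorical=obs_categorical,
        descriptions=descriptions,
        background_diagnoses=[
            "195662009", "444814009", "271737000", "82423001", "35489007",
            "193462001", "39848009", "70704007", "36971009", "40055000",
            "68496003", "26929004",
        ],
        background_procedures=[
            "399208008", "104326007", "268400002", "171207006", "430193006",
            "76601001", "225158009", "443529005",
        ],
        background_medications=[
            "ndc617312", "ndc243670", "ndc313782", "ndc834061", "ndc904639",
            "ndc312961", "ndc966571",
        ],
        admission_types=["emergency", "elective", "urgent"],
        insurance_types=["private", "medicaid", "medicare", "selfpay"],
        races=["caucasian", "african_american", "asian", "hispanic_latino",
               "other", "unknown"],
        regions=["midwest", "south", "northeast", "west", "maryland"],
        exclusion_noise_diagnoses=["46635009", "302866003"],
        exclusion_noise_medications=[
            "ndc498010", "ndc120001", "ndc310798", "ndc866511", "ndc197361",
            "ndc314076", "ndc745679",
        ],
    )


def default_disease_specs() -> list[SimDiseaseSpec]:
    """The four default disease generators, mirroring a chronic-disease
    prediction study design (type 2 diabetes, hypertension, COPD, MI), with
    five planted drivers each.  Prevalences are deliberately higher than
    real-world three-year onset rates so that desk-scale populations contain
    workable numbers of positives."""
    return [
        SimDiseaseSpec(
            name="diabetes",
            onset_codes=["44054006", "44054006001", "44054006002"],
            prevalence=0.10,
            drivers=[
                Driver("obs_high", "2345-7", 2.4, 0.5),
                Driver("obs_high", "4548-4", 2.2, 0.4),
                Driver("obs_high", "39156-5", 1.6, 0.5),
                Driver("diagnosis", "414916001", 1.9, 0.35),
                Driver("diagnosis", "55822004", 1.4, 0.45),
            ],
            onset_medications=["ndc498010"],
        ),
        SimDiseaseSpec(
            name="hypertension",
            onset_codes=["59621000", "59621000001"],
            prevalence=0.10,
            drivers=[
                Driver("obs_high", "8480-6", 2.4, 0.6),
                Driver("obs_high", "8462-4", 1.9, 0.5),
                Driver("obs_high", "39156-5", 1.4, 0.5),
                Driver("diagnosis", "55822004", 1.6, 0.45),
                Driver("diagnosis", "414916001", 1.4, 0.35),
            ],
            onset_medications=["ndc314076"],
        ),
        SimDiseaseSpec(
            name="copd",
            onset_codes=["13645005", "13645005001"],
            prevalence=0.08,
            drivers=[
                Driver("habit", "smoking", 2.6, 0.8),
                Driver("diagnosis", "77176002", 2.2, 0.4),
                Driver("obs_low", "20150-9", 2.1, 0.4),
                Driver("diagnosis", "195967001", 1.6, 0.3),
                Driver("diagnosis", "63480004", 1.6, 0.3),
            ],
            onset_medications=["ndc745679"],
        ),
        SimDiseaseSpec(
            name="mi",
            onset_codes=["57054005", "57054005001", "57054005002"],
            prevalence=0.08,
            drivers=[
                Driver("diagnosis", "53741008", 2.6, 0.35),
                Driver("obs_high", "8480-6", 1.2, 0.6),
                Driver("obs_high", "2093-3", 1.9, 0.5),
                Driver("diagnosis", "55822004", 1.8, 0.45),
                Driver("habit", "smoking", 1.6, 0.8),
            ],
            onset_medications=["ndc866511", "ndc243670"],
        ),
    ]


def default_sim_config(n_patients: int, seed: int, **overrides) -> SimConfig:
    cfg = SimConfig(
        n_patients=n_patients,
        seed=seed,
        disease_specs=default_disease_specs(),
        region_weights={"midwest": 0.30, "south": 0.25, "northeast": 0.20,
                        "west": 0.20, "maryland": 0.05},
        region_effects={"maryland": RegionEffect(visit_rate_mult=0.6,
                                                 prevalence_shift=0.5)},
        code_maps=default_code_maps(),
    )
    return replace(cfg, **overrides) if overrides else cfg


def planted_driver_token_sets(spec: SimDiseaseSpec) -> list[set[str]]:
    """For each planted driver, the set of tokens that realize it in a
    timeline (extreme-decile bins for value drivers)."""
    sets = []
    for d in spec.drivers:
        if d.kind == "obs_high":
            sets.append({f"{d.code}_8", f"{d.code}_9"})
        elif d.kind == "obs_low":
            sets.append({f"{d.code}_0", f"{d.code}_1"})
        elif d.kind == "habit":
            sets.append({f"{d.code}_{d.habit_value}"})
        else:
            sets.append({d.code})
    return sets


# ---------------------------------------------------------------------------
# generation


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """b0 with mean(sigmoid(b0 + eta)) = target, by bisection."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / (np.arange(n) + 2.0)
    return w / w.sum()


def _empty_population(maps: CodeMaps):
    patients = pd.DataFrame(columns=PATIENT_COLUMNS)
    events = pd.DataFrame(columns=EVENT_COLUMNS)
    truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    return patients, events, truth


def generate_population(config: SimConfig, return_info: bool = False):
    """Generate a population: ``(demographics, events, ground_truth)``.

    With ``return_info=True`` also returns a dict of internal simulation
    state (truncation dates, driver counts) used by diagnostics and tests.
    """
    config.validate()
    maps = config.code_maps or default_code_maps()
    N = config.n_patients
    if N == 0:
        out = _empty_population(maps)
        return (*out, {}) if return_info else out

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    p_start = np.datetime64(config.period[0])
    p_end = np.datetime64(config.period[1])

    # --- demographics -----------------------------------------------------
    birth_year = rng.integers(config.birth_year_range[0],
                              config.birth_year_range[1] + 1, size=N)
    gender = rng.choice(["female", "male"], size=N)
    race = rng.choice(maps.races, size=N,
                      p=[0.45, 0.12, 0.06, 0.12, 0.05, 0.20])
    if config.region_weights:
        regions = list(config.region_weights)
        rw = np.array([config.region_weights[r] for r in regions], dtype=float)
        rw = rw / rw.sum()
    else:
        regions, rw = maps.regions, None
    region = rng.choice(regions, size=N, p=rw)
    pid = np.array([f"{config.id_prefix}{i:06d}" for i in range(N)])
    patients = pd.DataFrame({
        "patient_id": pid, "birth_year": birth_year, "gender": gender,
        "race": race, "home_region": region,
    })

    visit_mult = np.ones(N)
    prev_shift = np.zeros(N)
    for rname, eff in config.region_effects.items():
        m = region == rname
        visit_mult[m] = eff.visit_rate_mult
        prev_shift[m] = eff.prevalence_shift

    # --- visit clusters ---------------------------------------------------
    years = np.arange(config.period[0].year, config.period[1].year + 1)
    Y = len(years)
    lam = config.visits_per_year * np.repeat(visit_mult, Y)
    nv = rng.poisson(lam)                      # (N*Y,) patient-major
    visit_patient = np.repeat(np.repeat(np.arange(N), Y), nv)
    visit_year = np.repeat(np.tile(years, N), nv)
    vdays = rng.integers(0, 365, size=nv.sum())
    visit_date = ((visit_year - 1970).astype("datetime64[Y]")
                  .astype("datetime64[D]") + vdays)
    visit_date = np.minimum(visit_date, p_end)
    V = len(visit_date)

    # first visit and visit index ranges per patient (visits are already
    # patient-major and date order within patient does not matter here)
    visit_counts = np.bincount(visit_patient, minlength=N)
    visit_start = np.concatenate([[0], np.cumsum(visit_counts)[:-1]])

    ev_frames: list[pd.DataFrame] = []

    def emit(patient_idx, dates, domain, codes, vnum=None, vcat=None, unit=None):
        n = len(patient_idx)
        if n == 0:
            return
        ev_frames.append(pd.DataFrame({
            "patient_id": pid[patient_idx],
            "date": dates.astype("datetime64[ns]"),
            "domain": domain,
            "code": codes,
            "value_numeric": np.full(n, np.nan) if vnum is None else vnum,
            "value_categorical": np.full(n, None, dtype=object)
            if vcat is None else vcat,
            "unit": np.full(n, None, dtype=object) if unit is None else unit,
        }))

    # --- background events ------------------------------------------------
    lo, hi = config.events_per_visit
    nev = rng.integers(lo, hi + 1, size=V)
    ev_visit = np.repeat(np.arange(V), nev)
    E = len(ev_visit)
    ev_pat = visit_patient[ev_visit]
    ev_date = visit_date[ev_visit]
    dom_names = np.array(["diagnosis", "procedure", "medication",
                          "obs_num", "obs_cat", "admission"])
    dom_idx = rng.choice(len(dom_names), size=E,
                         p=[0.28, 0.15, 0.18, 0.28, 0.04, 0.07])

    m = dom_idx == 0
    codes = np.array(maps.background_diagnoses)
    emit(ev_pat[m], ev_date[m], "diagnosis",
         rng.choice(codes, size=m.sum(), p=_zipf_weights(len(codes))))
    m = dom_idx == 1
    codes = np.array(maps.background_procedures)
    emit(ev_pat[m], ev_date[m], "procedure",
         rng.choice(codes, size=m.sum(), p=_zipf_weights(len(codes))))
    m = dom_idx == 2
    codes = np.array(maps.background_medications)
    emit(ev_pat[m], ev_date[m], "medication",
         rng.choice(codes, size=m.sum(), p=_zipf_weights(len(codes))))

    m = dom_idx == 3
    ocodes = list(maps.obs_numeric)
    oidx = rng.choice(len(ocodes), size=m.sum(), p=_zipf_weights(len(ocodes)))
    means = np.array([maps.obs_numeric[c].mean for c in ocodes])
    sds = np.array([maps.obs_numeric[c].sd for c in ocodes])
    units = np.array([maps.obs_numeric[c].unit for c in ocodes], dtype=object)
    # a patient's repeat measurements of one code share a persistent offset,
    # so their values land in nearby bins
    a = np.sqrt(config.value_consistency)
    b = np.sqrt(1.0 - config.value_consistency)
    patient_code_offset = rng.standard_normal((N, len(ocodes)))
    z = (a * patient_code_offset[ev_pat[m], oidx]
         + b * rng.standard_normal(m.sum()))
    vals = z * sds[oidx] + means[oidx]
    emit(ev_pat[m], ev_date[m], "observation",
         np.array(ocodes, dtype=object)[oidx], vnum=np.round(vals, 2),
         unit=units[oidx])

    m = dom_idx == 4
    ccodes = list(maps.obs_categorical)
    cidx = rng.choice(len(ccodes), size=m.sum())
    outc = np.array([
        maps.obs_categorical[ccodes[i]][
            rng.integers(0, len(maps.obs_categorical[ccodes[i]]))]
        for i in cidx
    ], dtype=object) if m.sum() else np.array([], dtype=object)
    emit(ev_pat[m], ev_date[m], "observation",
         np.array(ccodes, dtype=object)[cidx], vcat=outc)

    m = dom_idx == 5
    emit(ev_pat[m], ev_date[m], "admission",
         rng.choice(np.array(maps.admission_types), size=m.sum(),
                    p=[0.45, 0.35, 0.20]))

    # --- insurance --------------------------------------------------------
    ins0 = rng.choice(np.array(maps.insurance_types), size=N,
                      p=[0.5, 0.2, 0.2, 0.1])
    has_visit = visit_counts > 0
    first_visit_date = np.full(N, p_end)
    if V:
        np.minimum.at(first_visit_date, visit_patient, visit_date)
    emit(np.flatnonzero(has_visit), first_visit_date[has_visit],
         "insurance", ins0[has_visit])
    changer = rng.random(N) < 0.25
    ch = np.flatnonzero(changer & has_visit)
    if len(ch):
        new_type = rng.choice(np.array(maps.insurance_types), size=len(ch))
        span = (p_end - p_start).astype(int)
        ch_date = p_start + rng.integers(span // 4, span, size=len(ch))
        emit(ch, ch_date, "insurance", new_type)

    # --- planted driver counts (shared across diseases) -------------------
    registry: dict[tuple, Driver] = {}
    for spec in config.disease_specs:
        for d in spec.drivers:
            registry.setdefault(d.key(), d)
    # shared frailty: risk factors co-occur within patients
    frailty = rng.gamma(config.frailty_shape,
                        1.0 / config.frailty_shape, size=N)
    counts: dict[tuple, np.ndarray] = {
        key: rng.poisson(frailty * drv.rate, size=N)
        for key, drv in registry.items()
    }

    def random_visit_dates(patient_idx):
        """A random visit date per entry; random in-period date if the
        patient has no visits."""
        k = rng.integers(0, np.maximum(visit_counts[patient_idx], 1))
        dates = visit_date[visit_start[patient_idx] + k] if V else None
        missing = visit_counts[patient_idx] == 0
        if dates is None:
            dates = np.full(len(patient_idx), p_start)
            missing = np.ones(len(patient_idx), dtype=bool)
        if missing.any():
            span = (p_end - p_start).astype(int)
            dates = dates.copy()
            dates[missing] = p_start + rng.integers(0, span,
                                                    size=missing.sum())
        return dates

    smoking_key = ("habit", "smoking", "yes")
    for key, drv in registry.items():
        c = counts[key]
        owners = np.repeat(np.arange(N), c)
        if len(owners) == 0:
            continue
        dates = random_visit_dates(owners)
        if drv.kind == "diagnosis":
            emit(owners, dates, "diagnosis", np.full(len(owners), drv.code))
        elif drv.kind == "medication":
            emit(owners, dates, "medication", np.full(len(owners), drv.code))
        elif drv.kind == "habit":
            emit(owners, dates, "habit", np.full(len(owners), drv.code),
                 vcat=np.full(len(owners), drv.habit_value, dtype=object))
        else:
            spec_o = maps.obs_numeric[drv.code]
            # extreme decile of the code's value distribution
            if drv.kind == "obs_high":
                qlo, qhi = spec_o.mean + 1.2816 * spec_o.sd, \
                    spec_o.mean + 2.5758 * spec_o.sd
            else:
                qlo, qhi = spec_o.mean - 2.5758 * spec_o.sd, \
                    spec_o.mean - 1.2816 * spec_o.sd
            vals = rng.uniform(qlo, qhi, size=len(owners))
            emit(owners, dates, "observation", np.full(len(owners), drv.code),
                 vnum=np.round(vals, 2),
                 unit=np.full(len(owners), spec_o.unit, dtype=object))

    # background habit records for patients without planted smoking
    if smoking_key in counts:
        nonsmoker = counts[smoking_key] == 0
    else:
        nonsmoker = rng.random(N) < 0.75
    rec = np.flatnonzero(nonsmoker & (rng.random(N) < 0.6))
    if len(rec):
        status = rng.choice(np.array(["no", "former"]), size=len(rec),
                            p=[0.8, 0.2])
        emit(rec, random_visit_dates(rec), "habit",
             np.full(len(rec), "smoking"), vcat=status.astype(object))
    alc = np.flatnonzero(rng.random(N) < 0.4)
    if len(alc):
        emit(alc, random_visit_dates(alc), "habit",
             np.full(len(alc), "alcohol"),
             vcat=rng.choice(np.array(["yes", "no"], dtype=object),
                             size=len(alc)))

    # --- exclusion-rule noise --------------------------------------------
    for pool in (maps.exclusion_noise_diagnoses,
                 maps.exclusion_noise_medications):
        if not pool:
            continue
        hit = np.flatnonzero(rng.random(N) < config.exclusion_noise_rate)
        if len(hit):
            domain = ("diagnosis" if pool is maps.exclusion_noise_diagnoses
                      else "medication")
            emit(hit, random_visit_dates(hit), domain,
                 rng.choice(np.array(pool), size=len(hit)))

    # --- disease onset ----------------------------------------------------
    age_2018 = config.onset_window[0].year - birth_year
    w_start = np.datetime64(config.onset_window[0])
    w_days = (np.datetime64(config.onset_window[1]) - w_start).astype(int)
    truth_rows = []
    onset_flags: dict[str, np.ndarray] = {}
    for spec in config.disease_specs:
        eta = prev_shift + spec.age_coef * (age_2018 - 55) / 10.0
        for d in spec.drivers:
            eta = eta + d.weight * counts[d.key()]
        b0 = _solve_intercept(eta, spec.prevalence)
        latent = b0 + eta
        onset = rng.random(N) < _sigmoid(latent)
        onset_flags[spec.name] = onset
        oi = np.flatnonzero(onset)
        odays = rng.integers(0, w_days + 1, size=len(oi))
        odate = w_start + odays
        ocode = rng.choice(np.array(spec.onset_codes), size=len(oi))
        emit(oi, odate, "diagnosis", ocode)
        for med in spec.onset_medications:
            mdate = np.minimum(odate + rng.integers(7, 120, size=len(oi)),
                               p_end)
            emit(oi, mdate, "medication", np.full(len(oi), med))
        onset_series = np.full(N, np.datetime64("NaT"), dtype="datetime64[D]")
        onset_series[oi] = odate
        truth_rows.append(pd.DataFrame({
            "patient_id": pid, "disease": spec.name,
            "onset_date": onset_series.astype("datetime64[ns]"),
            "latent_risk": latent,
        }))

    truth = (pd.concat(truth_rows, ignore_index=True)
             if truth_rows else pd.DataFrame(columns=TRUTH_COLUMNS))

    # --- dropout (right truncation) --------------------------------------
    if config.dropout_rate > 0:
        years_to_trunc = rng.geometric(config.dropout_rate, size=N)
        trunc_days = years_to_trunc * 365 + rng.integers(0, 365, size=N)
        trunc_date = p_start + trunc_days
        truncated = trunc_date <= p_end
    else:
        trunc_date = np.full(N, p_end)
        truncated = np.zeros(N, dtype=bool)
    trunc_date = np.minimum(trunc_date, p_end)

    events = pd.concat(ev_frames, ignore_index=True)
    pos = pd.Series(np.arange(N), index=pid)
    keep = (events["date"].to_numpy()
            <= trunc_date.astype("datetime64[ns]")[pos[events["patient_id"]].to_numpy()])
    events = events[keep]
    events = events.sort_values(["patient_id", "date"],
                                kind="stable").reset_index(drop=True)

    info = {
        "truncation_date": pd.Series(trunc_date, index=pid),
        "truncated": pd.Series(truncated, index=pid),
        "driver_counts": {k: v for k, v in counts.items()},
        "onset": onset_flags,
    }
    return (patients, events, truth, info) if return_info \
        else (patients, events, truth)


# ---------------------------------------------------------------------------
# I/O


def write_event_tables(demographics: pd.DataFrame, events: pd.DataFrame,
                       path, truth: pd.DataFrame | None = None) -> None:
    """Write ``patients.csv`` / ``events.csv`` (and optionally ``truth.csv``)
    with ISO-8601 dates under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    demographics.to_csv(path / "patients.csv", index=False)
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"]).dt.strftime("%Y-%m-%d")
    ev.to_csv(path / "events.csv", index=False)
    if truth is not None:
        tr = truth.copy()
        tr["onset_date"] = pd.to_datetime(tr["onset_date"]).dt.strftime("%Y-%m-%d")
        tr.to_csv(path / "truth.csv", index=False)


def _check_columns(frame: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{name} missing columns: {missing}")


def read_event_tables(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``patients.csv`` and ``events.csv`` written by
    :func:`write_event_tables`; raises :class:`FormatError` listing any
    missing columns."""
    path = Path(path)
    patients = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
    _check_columns(patients, PATIENT_COLUMNS, "patients.csv")
    events = pd.read_csv(
        path / "events.csv",
        dtype={"patient_id": str, "code": str, "value_categorical": object,
               "unit": object},
    )
    _check_columns(events, EVENT_COLUMNS, "events.csv")
    events["date"] = pd.to_datetime(events["date"])
    return patients, events
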