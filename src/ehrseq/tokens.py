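"""Token timelines from raw EHR event records.

A patient's longitudinal record is rendered as a single sequence of string
tokens drawn from a closed grammar:

==================  ==============================================
kind                token form
==================  ==============================================
bare code           ``44054006`` (diagnosis / procedure / medication)
categorical result  ``10331-6_negative``  (observation code + outcome)
binned value        ``8480-6_3``          (observation code + decile bin)
age                 ``age_45``            (one per calendar year)
admission           ``emergency_admission``
habit               ``smoking_yes``
insurance           ``insurance_private``
race / gender       ``race_caucasian``, ``gender_female`` (terminal)
==================  ==============================================

Numeric observation values are min-max scaled against per-code training
minima/maxima (recorded after winsorizing the training values at the 1st and
99th percentiles) and assigned to one of ten bins, half-open
``[0.0,0.1), ..., [0.8,0.9)`` with a closed top bin ``[0.9,1.0]``.  At
inference, values outside the training range are clamped to the saved
min/max so every value lands in a bin.  Bare codes never contain an
underscore; that restriction is what makes the grammar unambiguous.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UnknownCodeError

__all__ = [
    "ObservationScaler",
    "TokenSequence",
    "BinRange",
    "Vocabulary",
    "PAD_TOKEN",
    "OOV_TOKEN",
    "fit_observation_scaler",
    "bin_value",
    "categorical_token",
    "age_tokens",
    "build_timeline",
    "build_timelines",
    "denormalize_bins",
    "build_vocabulary",
    "parse_token",
    "token_kind",
]

PAD_TOKEN = "<pad>"
OOV_TOKEN = "<oov>"

# Bin edges 0.1 .. 0.9 built as integer/10 so that the boundary floats are
# bit-identical to the constants an independent reimplementation would write.
_BIN_EDGES = np.arange(1, 10) / 10.0

_HABIT_CODES = frozenset({"smoking", "alcohol"})


# ---------------------------------------------------------------------------
# scaler


@dataclass
class ObservationScaler:
    """Per-code training min/max used for value binning and de-normalization.

    ``train_min``/``train_max`` are the 1st and 99th percentiles (linear
    interpolation between order statistics) of the numeric training values
    for the code, i.e. the min/max of the winsorized training values.
    """

    codes: dict[str, tuple[float, float, int, str]] = field(default_factory=dict)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def bounds(self, code: str) -> tuple[float, float]:
        try:
            lo, hi, _, _ = self.codes[code]
        except KeyError:
            raise UnknownCodeError(f"observation code {code!r} not in scaler")
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, lo, hi, n, unit)
            for c, (lo, hi, n, unit) in sorted(self.codes.items())
        ]
        return pd.DataFrame(
            rows, columns=["code", "train_min", "train_max", "n_values", "unit"]
        )

    def save(self, path) -> None:
        # full float precision so the round trip is token-exact
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservationScaler":
        required = {"code", "train_min", "train_max", "n_values", "unit"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"scaler table missing columns: {sorted(missing)}")
        codes = {
            str(r.code): (float(r.train_min), float(r.train_max), int(r.n_values),
                          "" if pd.isna(r.unit) else str(r.unit))
            for r in frame.itertuples()
        }
        return cls(codes)

    @classmethod
    def load(cls, path) -> "ObservationScaler":
        return cls.from_frame(pd.read_csv(path, dtype={"code": str}))


def fit_observation_scaler(train_events: pd.DataFrame) -> ObservationScaler:
    """Fit per-code winsorized min/max from training-split observation events.

    Codes with no numeric values are omitted.  Percentiles use numpy's
    linear-interpolation convention.
    """
    obs = train_events[
        (train_events["domain"] == "observation")
        & train_events["value_numeric"].notna()
    ]
    codes: dict[str, tuple[float, float, int, str]] = {}
    for code, grp in obs.groupby("code", sort=True):
        vals = grp["value_numeric"].to_numpy(dtype=float)
        lo, hi = np.percentile(vals, [1.0, 99.0])
        units = grp["unit"].dropna()
        unit = str(units.iloc[0]) if len(units) else ""
        codes[str(code)] = (float(lo), float(hi), int(len(vals)), unit)
    return ObservationScaler(codes)


def _bin_index(x: float) -> int:
    # count of edges <= x; boundary values 0.1..0.9 promote to the upper bin,
    # 1.0 stays in the closed top bin 9.
    return int(np.searchsorted(_BIN_EDGES, x, side="right"))


def bin_value(
    code: str,
    raw_value: float,
    scaler: ObservationScaler,
    mode: str = "inference",
) -> str:
    """Min-max scale ``raw_value`` against the code's saved training range and
    return the decile-bin token ``"<code>_<b>"``.

    In ``inference`` mode out-of-range values are clamped to the saved
    min/max before scaling; in ``train`` mode an out-of-range value means the
    scaler does not belong to this data and is an error.
    """
    lo, hi = scaler.bounds(code)
    if hi == lo:
        return f"{code}_0"
    if raw_value < lo or raw_value > hi:
        if mode == "train":
            raise ValueError(
                f"value {raw_value} for {code} outside winsorized training "
                f"range [{lo}, {hi}]"
            )
        raw_value = min(max(raw_value, lo), hi)
    x = (raw_value - lo) / (hi - lo)
    return f"{code}_{_bin_index(x)}"


@dataclass(frozen=True)
class BinRange:
    code: str
    bin_index: int
    low: float
    high: float


def denormalize_bins(code: str, scaler: ObservationScaler) -> list[BinRange]:
    """Original-unit value range of each of the 10 bins for ``code``."""
    lo, hi = scaler.bounds(code)
    span = hi - lo
    return [
        BinRange(code, b, lo + 0.1 * b * span, lo + 0.1 * (b + 1) * span)
        for b in range(10)
    ]


# ---------------------------------------------------------------------------
# token constructors and grammar


_WS = re.compile(r"\s+")


def _normalize_outcome(outcome: str) -> str:
    out = _WS.sub("_", outcome.strip().lower())
    if re.fullmatch(r"\d", out):
        raise ValueError(
            f"categorical outcome {outcome!r} collides with the bin grammar"
        )
    return out


def categorical_token(code: str, outcome: str) -> str:
    """Concatenate an observation code with its categorical outcome,
    e.g. ``("10331-6", "negative") -> "10331-6_negative"``."""
    if not outcome or not outcome.strip():
        raise ValueError("categorical outcome must be non-empty")
    if "_" in code:
        raise ValueError(f"codes may not contain underscores: {code!r}")
    return f"{code}_{_normalize_outcome(outcome)}"


def age_tokens(
    birth_year: int, first_event_date: Date, cutoff_date: Date
) -> list[tuple[int, str]]:
    """One ``age_N`` token per calendar year from the first event's year to
    the cutoff year inclusive; years without events still yield a token, so
    gaps in the record appear as runs of consecutive age tokens."""
    if birth_year > first_event_date.year:
        raise ValueError("birth_year after first event")
    if cutoff_date < first_event_date:
        return []
    return [
        (year, f"age_{year - birth_year}")
        for year in range(first_event_date.year, cutoff_date.year + 1)
    ]


def parse_token(token: str, habit_codes: frozenset[str] = _HABIT_CODES):
    """Parse a token back into ``(kind, components)`` under the closed grammar.

    Kinds: ``pad``, ``oov``, ``age``, ``race``, ``gender``, ``insurance``,
    ``admission``, ``habit``, ``obs_bin``, ``obs_cat``, ``code``.
    """
    if token == PAD_TOKEN:
        return ("pad", ())
    if token == OOV_TOKEN:
        return ("oov", ())
    if "_" not in token:
        return ("code", (token,))
    head, rest = token.split("_", 1)
    if head == "age" and rest.isdigit():
        return ("age", (int(rest),))
    if head in ("race", "gender", "insurance"):
        return (head, (rest,))
    if rest == "admission":
        return ("admission", (head,))
    if head in habit_codes:
        return ("habit", (head, rest))
    if len(rest) == 1 and rest.isdigit():
        return ("obs_bin", (head, int(rest)))
    return ("obs_cat", (head, rest))


def token_kind(token: str) -> str:
    return parse_token(token)[0]


# ---------------------------------------------------------------------------
# timelines


@dataclass
class TokenSequence:
    """A patient's ordered token timeline truncated at ``cutoff_date``."""

    patient_id: str
    tokens: list[str]
    cutoff_date: Date

    def __len__(self) -> int:
        return len(self.tokens)


def _event_token(
    domain: str,
    code: str,
    value_numeric,
    value_categorical,
    scaler: ObservationScaler,
    mode: str,
    unknown_code_policy: str,
) -> str | None:
    if domain in ("diagnosis", "procedure", "medication"):
        return code
    if domain == "observation":
        if value_numeric is not None and not (
            isinstance(value_numeric, float) and math.isnan(value_numeric)
        ):
            if code not in scaler:
                if unknown_code_policy == "drop":
                    return None
                if unknown_code_policy == "error":
                    raise UnknownCodeError(code)
                return code  # bare-code fallback (default)
            return bin_value(code, float(value_numeric), scaler, mode)
        if value_categorical is not None and not pd.isna(value_categorical):
            return categorical_token(code, str(value_categorical))
        return code  # observation recorded without a result
    if domain == "admission":
        return f"{code}_admission"
    if domain == "habit":
        return f"{code}_{_normalize_outcome(str(value_categorical))}"
    if domain == "insurance":
        return f"insurance_{code}"
    raise ValueError(f"unknown event domain {domain!r}")


def _patient_rng(shuffle_seed: int, patient_id: str) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=int(shuffle_seed) & 0x7FFFFFFF,
        spawn_key=tuple(patient_id.encode("utf-8")),
    )
    return np.random.Generator(np.random.PCG64(ss))


def build_timeline(
    patient: Mapping,
    events: pd.DataFrame,
    scaler: ObservationScaler,
    cutoff_date: Date,
    shuffle_seed: int = 0,
    mode: str = "inference",
    unknown_code_policy: str = "bare",
    precomputed_tokens: pd.Series | None = None,
) -> TokenSequence:
    """Build one patient's token timeline.

    Events after ``cutoff_date`` are dropped; the rest are ordered by date
    with within-date order drawn from a generator seeded by
    ``(shuffle_seed, patient_id)``; an age token opens each calendar year
    from the first event's year through the cutoff year; race and gender
    tokens are appended last.
    """
    pid = str(patient["patient_id"])
    dates = pd.to_datetime(events["date"]).dt.date if len(events) else events["date"]
    keep = np.array([d <= cutoff_date for d in dates], dtype=bool)
    events = events.iloc[np.flatnonzero(keep)]
    if precomputed_tokens is not None:
        tok = precomputed_tokens.loc[events.index]
        dated = [
            (d, t)
            for d, t in zip(pd.to_datetime(events["date"]).dt.date, tok)
            if t is not None
        ]
    else:
        dated = []
        for row in events.itertuples():
            t = _event_token(
                row.domain, str(row.code), row.value_numeric,
                row.value_categorical, scaler, mode, unknown_code_policy,
            )
            if t is not None:
                dated.append((pd.Timestamp(row.date).date(), t))

    tokens: list[str] = []
    if dated:
        rng = _patient_rng(shuffle_seed, pid)
        # stable sort by date, then a per-date random permutation
        dated.sort(key=lambda dt: dt[0])
        by_year: dict[int, list[tuple[Date, str]]] = {}
        for d, t in dated:
            by_year.setdefault(d.year, []).append((d, t))
        first_year = dated[0][0].year
        for year, age_tok in age_tokens(
            int(patient["birth_year"]), dated[0][0], cutoff_date
        ):
            tokens.append(age_tok)
            for d, group in _groupby_date(by_year.get(year, [])):
                group = list(group)
                if len(group) > 1:
                    order = rng.permutation(len(group))
                    group = [group[i] for i in order]
                tokens.extend(t for _, t in group)
    race = patient.get("race")
    gender = patient.get("gender")
    if race is not None and not pd.isna(race):
        tokens.append(f"race_{_normalize_outcome(str(race))}")
    if gender is not None and not pd.isna(gender):
        tokens.append(f"gender_{_normalize_outcome(str(gender))}")
    return TokenSequence(pid, tokens, cutoff_date)


def _groupby_date(items: list[tuple[Date, str]]):
    i = 0
    while i < len(items):
        j = i
        while j < len(items) and items[j][0] == items[i][0]:
            j += 1
        yield items[i][0], items[i:j]
        i = j


def build_timelines(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    scaler: ObservationScaler,
    cutoff_date: Date,
    shuffle_seed: int = 0,
    mode: str = "inference",
    unknown_code_policy: str = "bare",
) -> list[TokenSequence]:
    """Vectorized batch variant of :func:`build_timeline` (same output).

    Tokenizes all events column-wise, then assembles each patient's timeline
    with the same per-patient ordering rule as the single-patient builder.
    """
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    ev = ev[ev["date"].dt.date <= cutoff_date]
    tok = _tokenize_events_columnwise(ev, scaler, mode, unknown_code_policy)
    ev = ev.assign(_token=tok)
    ev = ev[ev["_token"].notna()]
    grouped = dict(tuple(ev.groupby("patient_id", sort=False)))
    out = []
    empty = ev.iloc[0:0]
    for prow in patients.to_dict("records"):
        pid = str(prow["patient_id"])
        sub = grouped.get(pid, empty)
        out.append(
            _assemble_timeline(prow, sub, cutoff_date, shuffle_seed)
        )
    return out


def _tokenize_events_columnwise(
    ev: pd.DataFrame, scaler: ObservationScaler, mode: str, policy: str
) -> pd.Series:
    tok = pd.Series(index=ev.index, dtype=object)
    dom = ev["domain"]
    code = ev["code"].astype(str)

    bare = dom.isin(["diagnosis", "procedure", "medication"])
    tok[bare] = code[bare]

    adm = dom == "admission"
    tok[adm] = code[adm] + "_admission"

    hab = dom == "habit"
    if hab.any():
        tok[hab] = code[hab] + "_" + ev.loc[hab, "value_categorical"].map(
            lambda v: _normalize_outcome(str(v))
        )

    ins = dom == "insurance"
    tok[ins] = "insurance_" + code[ins]

    obs = dom == "observation"
    num = obs & ev["value_numeric"].notna()
    cat = obs & ~num & ev["value_categorical"].notna()
    none = obs & ~num & ~cat
    tok[none] = code[none]
    if cat.any():
        tok[cat] = code[cat] + "_" + ev.loc[cat, "value_categorical"].map(
            lambda v: _normalize_outcome(str(v))
        )
    if num.any():
        vals = ev.loc[num, "value_numeric"].to_numpy(dtype=float)
        ncodes = code[num]
        out = np.empty(len(vals), dtype=object)
        for c, idx in ncodes.groupby(ncodes).groups.items():
            sel = ncodes.index.get_indexer(idx)
            if c in scaler:
                lo, hi = scaler.bounds(c)
                v = vals[sel]
                if hi == lo:
                    b = np.zeros(len(v), dtype=int)
                else:
                    if mode == "train" and ((v < lo).any() or (v > hi).any()):
                        raise ValueError(
                            f"values for {c} outside training range in train mode"
                        )
                    v = np.clip(v, lo, hi)
                    x = (v - lo) / (hi - lo)
                    b = np.searchsorted(_BIN_EDGES, x, side="right")
                out[sel] = [f"{c}_{bi}" for bi in b]
            else:
                if policy == "error":
                    raise UnknownCodeError(c)
                out[sel] = None if policy == "drop" else c
        tok[num] = out
    return tok


def _assemble_timeline(
    patient: Mapping, ev: pd.DataFrame, cutoff_date: Date, shuffle_seed: int
) -> TokenSequence:
    pid = str(patient["patient_id"])
    tokens: list[str] = []
    if len(ev):
        dates = ev["date"].dt.date.to_numpy()
        toks = ev["_token"].to_numpy()
        order = np.argsort(dates, kind="stable")
        dates, toks = dates[order], toks[order]
        rng = _patient_rng(shuffle_seed, pid)
        years = np.array([d.year for d in dates])
        first = dates[0]
        codes_by_year: dict[int, tuple] = {}
        for y in np.unique(years):
            m = years == y
            codes_by_year[int(y)] = (dates[m], toks[m])
        for year, age_tok in age_tokens(int(patient["birth_year"]), first, cutoff_date):
            tokens.append(age_tok)
            if year in codes_by_year:
                d, t = codes_by_year[year]
                i = 0
                while i < len(d):
                    j = i
                    while j < len(d) and d[j] == d[i]:
                        j += 1
                    if j - i > 1:
                        perm = rng.permutation(j - i)
                        tokens.extend(t[i + k] for k in perm)
                    else:
                        tokens.append(t[i])
                    i = j
    race, gender = patient.get("race"), patient.get("gender")
    if race is not None and not pd.isna(race):
        tokens.append(f"race_{_normalize_outcome(str(race))}")
    if gender is not None and not pd.isna(gender):
        tokens.append(f"gender_{_normalize_outcome(str(gender))}")
    return TokenSequence(pid, tokens, cutoff_date)


# ---------------------------------------------------------------------------
# vocabulary


class Vocabulary:
    """Token -> index map with reserved padding (0) and out-of-vocabulary (1)
    indices; ordering is frequency-descending, ties broken lexicographically."""

    def __init__(self, tokens: Sequence[str], counts: Sequence[int] | None = None):
        self.index: dict[str, int] = {PAD_TOKEN: 0, OOV_TOKEN: 1}
        for t in tokens:
            if t not in self.index:
                self.index[t] = len(self.index)
        self.tokens: list[str] = [None] * len(self.index)
        for t, i in self.index.items():
            self.tokens[i] = t
        self.counts = dict(zip(tokens, counts)) if counts is not None else {}

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def id(self, token: str) -> int:
        return self.index.get(token, 1)

    def encode(self, tokens: Iterable[str]) -> np.ndarray:
        get = self.index.get
        return np.fromiter((get(t, 1) for t in tokens), dtype=np.int32)

    def decode(self, ids: Iterable[int]) -> list[str]:
        return [self.tokens[i] for i in ids]


def build_vocabulary(
    sequences: Iterable[TokenSequence | Sequence[str]], min_count: int = 1
) -> Vocabulary:
    """Count tokens over a corpus and keep those with frequency >= min_count."""
    counts: dict[str, int] = {}
    for seq in sequences:
        toks = seq.tokens if isinstance(seq, TokenSequence) else seq
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    kept = [(t, c) for t, c in counts.items() if c >= min_count]
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    return Vocabulary([t for t, _ in kept], [c for _, c in kept])
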