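"""Attribution: exact Shapley against an independent brute-force oracle,
integrated-gradients additivity, population summaries and label rendering."""

from datetime import date as Date
from itertools import combinations
from math import factorial

import numpy as np
import pytest

from ehrseq import explain as ex
from ehrseq import risk
from ehrseq.cohort import DiseaseSpec
from ehrseq.errors import SamplingError
from ehrseq.tokens import ObservationScaler, TokenSequence


def brute_force_shapley(score_fn, ids):
    """Independent Shapley computation: iterate players, sum weighted
    marginal contributions over all coalitions of the others."""
    n = len(ids)
    phi = np.zeros(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        for r in range(n):
            for S in combinations(others, r):
                w = factorial(len(S)) * factorial(n - len(S) - 1) / factorial(n)
                keep = sorted(S)
                keep_i = sorted(S + (i,))
                phi[i] += w * (score_fn([ids[j] for j in keep_i])
                               - score_fn([ids[j] for j in keep]))
    return phi


@pytest.fixture(scope="module")
def toy_model():
    rng = np.random.default_rng(0)
    seqs, labels = [], {}
    for i in range(80):
        toks = [f"w{rng.integers(0, 8)}" for _ in range(6)]
        if i % 2 == 0:
            toks[rng.integers(0, 6)] = "sick"
        seqs.append(TokenSequence(f"p{i:02d}", toks, Date(2018, 1, 1)))
        labels[f"p{i:02d}"] = int(i % 2 == 0)
    cfg = risk.ModelConfig(d=8, gru_hidden=4, epochs=4, seed=0)
    return risk.train_model(seqs, labels, cfg)


class TestExactShapley:
    def test_matches_brute_force_oracle(self, toy_model):
        seq = TokenSequence("q", ["w1", "sick", "w3"], Date(2018, 1, 1))
        [exp] = ex.compute_shap(toy_model, [seq], method="exact")
        ids = toy_model.vocab.encode(seq.tokens)

        def score(sub_ids):
            return float(toy_model.net.predict(
                [np.asarray(sub_ids, dtype=np.int32)])[0])

        oracle = brute_force_shapley(score, list(ids))
        np.testing.assert_allclose(exp.contributions, oracle, atol=1e-6)
        assert exp.base_value == pytest.approx(score([]), abs=1e-9)
        assert exp.additivity_gap <= 1e-9

    def test_single_token_attribution_is_score_minus_base(self, toy_model):
        seq = TokenSequence("q", ["sick"], Date(2018, 1, 1))
        [exp] = ex.compute_shap(toy_model, [seq], method="exact")
        assert exp.contributions[0] == pytest.approx(
            exp.score - exp.base_value, abs=1e-9)

    def test_long_sequence_rejected(self, toy_model):
        seq = TokenSequence("q", ["w1"] * 20, Date(2018, 1, 1))
        with pytest.raises(ValueError, match="intractable"):
            ex.compute_shap(toy_model, [seq], method="exact")


class TestIntegratedGradients:
    def test_additivity_within_tolerance(self, toy_model):
        rng = np.random.default_rng(1)
        seqs = [TokenSequence(f"q{i}",
                              [f"w{rng.integers(0, 8)}" for _ in range(30)],
                              Date(2018, 1, 1)) for i in range(20)]
        exps = ex.compute_shap(toy_model, seqs, method="ig", tol=0.01)
        for e in exps:
            assert e.additivity_gap <= e.tolerance
            assert e.method == "ig"

    def test_sentinel_token_gets_largest_attribution(self, toy_model):
        toks = ["w1", "w2", "sick", "w3", "w4"] * 4
        seq = TokenSequence("q", toks, Date(2018, 1, 1))
        [e] = ex.compute_shap(toy_model, [seq], method="ig")
        by_token = {}
        for t, c in zip(e.tokens, e.contributions):
            by_token[t] = by_token.get(t, 0.0) + c
        assert max(by_token, key=by_token.get) == "sick"


class TestSummaries:
    @staticmethod
    def _explanation(pid, tokens, contribs):
        return ex.PatientExplanation(
            patient_id=pid, tokens=tokens,
            contributions=np.asarray(contribs, dtype=float),
            base_value=0.0, score=float(np.sum(contribs)),
            method="exact", tolerance=1e-9)

    def test_within_patient_duplicates_sum(self):
        s = ex.summarize_population(
            [self._explanation("p", ["A", "A", "B"], [0.2, 0.1, -0.05])])
        table = s.table.set_index("token")
        assert table.loc["A", "summed_shap"] == pytest.approx(0.3)
        assert table.loc["B", "summed_shap"] == pytest.approx(-0.05)
        assert table.loc["A", "rank"] == 1
        assert table.loc["A", "count"] == 2

    def test_matches_flat_group_by_oracle(self):
        rng = np.random.default_rng(0)
        exps, flat = [], {}
        for i in range(30):
            toks = [f"t{rng.integers(0, 12)}" for _ in range(15)]
            c = rng.normal(size=15)
            exps.append(self._explanation(f"p{i}", toks, c))
            for t, v in zip(toks, c):
                flat[t] = flat.get(t, 0.0) + v
        table = ex.summarize_population(exps).table.set_index("token")
        for t, v in flat.items():
            assert table.loc[t, "summed_shap"] == pytest.approx(v)

    def test_permutation_invariance(self):
        exps = [self._explanation("a", ["x", "y"], [0.1, 0.2]),
                self._explanation("b", ["y", "z"], [0.3, -0.1])]
        t1 = ex.summarize_population(exps).table
        t2 = ex.summarize_population(exps[::-1]).table
        assert t1.equals(t2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ex.summarize_population([])

    def test_clinical_summary_drops_demographic_tokens(self):
        exps = [self._explanation("a", ["age_50", "44054006", "8480-6_9",
                                        "race_other"],
                                  [0.5, 0.4, 0.3, 0.2])]
        table = ex.clinical_summary(ex.summarize_population(exps)).table
        assert list(table["token"]) == ["44054006", "8480-6_9"]
        assert list(table["rank"]) == [1, 2]


class TestSampling:
    def test_ratio_40_60(self):
        labels = {f"a{i}": 1 for i in range(500)}
        labels.update({f"b{i}": 0 for i in range(2000)})
        ids = ex.sample_for_shap(labels, n=1000, seed=0)
        assert len(ids) == 1000
        assert sum(1 for p in ids if p.startswith("a")) == 400

    def test_oversized_request_rejected(self):
        with pytest.raises(SamplingError):
            ex.sample_for_shap({"a": 1, "b": 0}, n=100)


class TestRendering:
    scaler = ObservationScaler({"8480-6": (125.0, 232.0, 100, "mmHg")})
    desc = {"8480-6": "Systolic blood pressure",
            "44054006": "Type 2 diabetes mellitus"}

    def test_binned_token_denormalized(self):
        label = ex.render_label("8480-6_3", self.scaler, self.desc)
        assert label.startswith("Systolic blood pressure, ")
        lo, hi = label.rsplit(", ", 1)[1].split("–")
        assert float(lo) == pytest.approx(125.0 + 0.3 * 107.0)
        assert float(hi) == pytest.approx(125.0 + 0.4 * 107.0)

    @pytest.mark.parametrize("token,expect", [
        ("gender_female", "Gender: female"),
        ("insurance_medicaid", "Insurance type: Medicaid"),
        ("race_african_american", "Race: african american"),
        ("age_63", "Age 63"),
        ("smoking_yes", "Smoking: yes"),
        ("emergency_admission", "Admission type: emergency"),
        ("44054006", "Type 2 diabetes mellitus"),
    ])
    def test_templates(self, token, expect):
        assert ex.render_label(token, self.scaler, self.desc) == expect

    def test_unknown_code_falls_back_to_literal(self):
        assert ex.render_label("999999", None, {}) == "999999"


class TestAudit:
    spec = DiseaseSpec(name="hypertension", target_codes={"59621000"},
                       exclusion_medication_classes={"C02", "C03"})
    med_atc = {"ndc310798": "C03", "ndc617312": "C10"}

    @staticmethod
    def _summary(tokens):
        return ex.ShapSummary(
            __import__("pandas").DataFrame({
                "token": tokens,
                "summed_shap": np.linspace(1, 0.1, len(tokens)),
                "count": 1,
                "rank": np.arange(1, len(tokens) + 1)}))

    def test_exclusion_class_token_flagged(self):
        s = self._summary(["59621000", "ndc310798", "ndc617312"])
        assert ex.audit_suspect_features(s, self.spec, self.med_atc) == \
            ["ndc310798"]

    def test_no_flag_when_absent(self):
        s = self._summary(["59621000", "ndc617312"])
        assert ex.audit_suspect_features(s, self.spec, self.med_atc) == []

    def test_matches_prefix_match_oracle(self):
        rng = np.random.default_rng(0)
        meds = {f"m{i}": rng.choice(["C02", "C03", "C07", "A10", "N02"])
                for i in range(40)}
        tokens = [f"m{i}" for i in range(40)]
        s = self._summary(tokens)
        got = ex.audit_suspect_features(s, self.spec, meds, top_k=25)
        oracle = [t for t in tokens[:25]
                  if meds[t].startswith(("C02", "C03"))]
        assert got == oracle
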