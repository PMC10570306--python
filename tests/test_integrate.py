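"""Cross-modality integration: correlations, categorization, differentials."""

import numpy as np
import pandas as pd
import pytest

from pharmotype import integrate as integ
from pharmotype import pharmacoscopy as ph


def _matrix(values, proteins=None, samples=None):
    values = np.asarray(values, float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=proteins, columns=samples)


def _responses(values, drug="dx", readout="HSPC", classes=None):
    rows = []
    for i, (pid, v) in enumerate(values.items()):
        rows.append({"patient_id": pid, "drug": drug, "readout": readout,
                     "relative_change": v / 10.0, "p_value": 0.5,
                     "signed_sig": v, "valid": True,
                     "response_class": (classes or {}).get(pid,
                                                           "non-responder")})
    return pd.DataFrame(rows)


class TestDrugProteinCorrelation:
    def test_monotone_transform_of_protein_gives_rho_one(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(20, 1, (10, 12)))
        resp = _responses({s: float(np.exp(m.loc["P0", s] / 5.0))
                           for s in m.columns})
        corr, _, _ = integ.drug_protein_correlation(
            resp, m, sets={}, n_perm=10)
        row = corr[corr["protein"] == "P0"].iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_constant_response_skipped(self):
        m = _matrix(np.random.default_rng(1).normal(0, 1, (5, 8)))
        resp = _responses({s: 1.0 for s in m.columns})
        with pytest.warns(UserWarning):
            corr, _, _ = integ.drug_protein_correlation(resp, m, sets={},
                                                        n_perm=10)
        assert corr.empty

    def test_too_few_shared_patients_skipped(self):
        m = _matrix(np.random.default_rng(2).normal(0, 1, (5, 3)))
        resp = _responses({s: float(i) for i, s in enumerate(m.columns)})
        with pytest.warns(UserWarning):
            corr, _, _ = integ.drug_protein_correlation(resp, m, sets={},
                                                        n_perm=10)
        assert corr.empty


class TestDrugClinicalAnova:
    def test_constant_factor_yields_no_counts(self):
        resp = _responses({f"p{i}": float(i) for i in range(10)})
        clinical = pd.DataFrame({"patient_id": [f"p{i}" for i in range(10)],
                                 "driver": "CALR"})
        full, counts = integ.drug_clinical_anova(resp, clinical, ["driver"])
        assert full.empty and counts.empty

    def test_planted_driver_effect_counted_as_sensitivity(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(20):
            driver = "CALR" if i < 10 else "JAK2"
            boost = 3.0 if driver == "JAK2" else 0.0
            rows.append((f"p{i}", driver,
                         boost + rng.normal(0, 0.3)))
        clinical = pd.DataFrame({"patient_id": [r[0] for r in rows],
                                 "driver": [r[1] for r in rows]})
        resp = _responses({r[0]: r[2] for r in rows})
        full, counts = integ.drug_clinical_anova(resp, clinical, ["driver"])
        assert (full["p_value"] < 0.001).all()
        assert counts.set_index("factor").loc["driver"].sum() == 1


class TestResponderProteome:
    def test_planted_low_block_in_responders_detected(self):
        rng = np.random.default_rng(4)
        patients = [f"p{i}" for i in range(16)]
        m = _matrix(rng.normal(20, 0.3, (30, 16)), samples=patients)
        responders = patients[:6]
        m.loc[m.index[:5], responders] -= 2.0  # low block in responders
        classes = {p: "responder" for p in responders}
        resp = _responses({p: 1.0 + rng.random() for p in patients},
                          classes=classes)
        volcano, _ = integ.responder_proteome(resp, m, "dx")
        low = volcano.head(5)  # first five proteins carry the planted block
        assert (volcano.iloc[:5]["log2fc"] < -1.5).all()
        assert (volcano.iloc[:5]["p_value"] < 1e-6).all()
        assert sorted(volcano.attrs["responders"]) == sorted(responders)

    def test_no_nonresponders_rejected(self):
        patients = [f"p{i}" for i in range(6)]
        m = _matrix(np.random.default_rng(5).normal(0, 1, (5, 6)),
                    samples=patients)
        resp = _responses({p: 1.0 for p in patients},
                          classes={p: "responder" for p in patients})
        with pytest.raises(ValueError):
            integ.responder_proteome(resp, m, "dx")

    def test_class_pooling_requires_min_members(self):
        patients = [f"p{i}" for i in range(12)]
        m = _matrix(np.random.default_rng(6).normal(0, 1, (5, 12)),
                    samples=patients)
        frames = []
        for drug in ("d1", "d2", "d3"):
            classes = {p: "responder" for p in patients[:5]}
            frames.append(_responses({p: 1.0 for p in patients}, drug=drug,
                                     classes=classes))
        resp = pd.concat(frames, ignore_index=True)
        volcano, _ = integ.responder_proteome(resp, m, ["d1", "d2", "d3"],
                                              min_class_responses=3)
        assert volcano.attrs["responders"] == sorted(patients[:5])


class TestReplicativeSignature:
    def test_k2_anchors_only(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(20, 1, (10, 30))
        m = _matrix(vals, proteins=["MCM4", "MCM7"]
                    + [f"P{i}" for i in range(8)])
        m.loc["MCM7"] = m.loc["MCM4"] + rng.normal(0, 0.01, 30)
        sig, table = integ.derive_replicative_signature({"gran": m}, k=2)
        assert sorted(sig) == ["MCM4", "MCM7"]

    def test_anticorrelated_protein_never_in_topk(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.normal(20, 1, (10, 40)),
                    proteins=["MCM4", "MCM7"] + [f"P{i}" for i in range(8)])
        m.loc["MCM7"] = m.loc["MCM4"]
        m.loc["P0"] = 40.0 - m.loc["MCM4"]  # perfectly anti-correlated
        sig, _ = integ.derive_replicative_signature({"gran": m}, k=9)
        assert "P0" not in sig

    def test_missing_anchor_cell_type_excluded(self):
        m_ok = _matrix(np.random.default_rng(9).normal(0, 1, (4, 10)),
                       proteins=["MCM4", "MCM7", "A", "B"])
        m_bad = _matrix(np.ones((2, 10)), proteins=["A", "B"])
        with pytest.warns(UserWarning):
            sig, table = integ.derive_replicative_signature(
                {"ok": m_ok, "bad": m_bad}, k=3)
        assert set(table.columns) == {"protein", "ok", "mean_r"}


class TestMcmCategories:
    def _matrices(self, levels):
        patients = list(levels)
        vals = np.array([list(levels.values())] * 2, float)
        m = _matrix(vals, proteins=["MCM4", "MCM7"], samples=patients)
        return {"gran": m}

    def test_nine_ordered_patients_split_3_3_3(self):
        levels = {f"p{i}": float(i) for i in range(9)}
        cats = integ.categorize_mcm(self._matrices(levels))
        by_cat = cats.groupby("mcm_category")["patient_id"].apply(set)
        assert by_cat["low"] == {"p0", "p1", "p2"}
        assert by_cat["medium"] == {"p3", "p4", "p5"}
        assert by_cat["high"] == {"p6", "p7", "p8"}

    def test_ties_broken_by_patient_id(self):
        levels = {"b": 1.0, "a": 1.0, "c": 1.0}
        cats = integ.categorize_mcm(self._matrices(levels))
        ordered = cats.sort_values("patient_id")
        assert cats.iloc[0]["patient_id"] == "a"

    def test_single_cell_type_patient_still_categorized(self):
        m1 = self._matrices({f"p{i}": float(i) for i in range(6)})["gran"]
        m2 = m1[[c for c in m1.columns if c != "p5"]]
        cats = integ.categorize_mcm({"gran": m1, "hspc": m2})
        row = cats[cats["patient_id"] == "p5"].iloc[0]
        assert row["n_cell_types"] == 1
        assert row["mcm_category"] == "high"


class TestSignatureDrugCorrelation:
    def test_response_equal_to_score_gives_r_one(self):
        scores = pd.Series({f"p{i}": float(i) for i in range(10)})
        resp = _responses(scores.to_dict())
        table = integ.signature_drug_correlation(scores, resp)
        assert table.iloc[0]["pearson_r"] == pytest.approx(1.0)
        assert table.iloc[0]["p_value"] < 1e-10

    def test_few_shared_patients_skipped(self):
        scores = pd.Series({"p0": 1.0, "p1": 2.0})
        resp = _responses({"p0": 1.0, "p1": 2.0})
        with pytest.warns(UserWarning):
            table = integ.signature_drug_correlation(scores, resp)
        assert table.empty


class TestVafCorrelation:
    def test_constant_vaf_rejected(self):
        m = _matrix(np.random.default_rng(10).normal(0, 1, (5, 6)))
        clinical = pd.DataFrame({"patient_id": m.columns, "driver": "CALR",
                                 "cohort": "MF", "vaf": 50.0})
        with pytest.raises(ValueError):
            integ.vaf_correlation(m, clinical, "CALR")

    def test_small_stratum_rejected(self):
        m = _matrix(np.random.default_rng(11).normal(0, 1, (5, 3)))
        clinical = pd.DataFrame({"patient_id": m.columns, "driver": "CALR",
                                 "cohort": "MF", "vaf": [30.0, 50.0, 80.0]})
        with pytest.raises(ValueError):
            integ.vaf_correlation(m, clinical, "CALR")

    def test_planted_slopes_recovered_with_sign(self):
        rng = np.random.default_rng(12)
        vaf = rng.uniform(20, 100, 30)
        clinical = pd.DataFrame({"patient_id": [f"p{i}" for i in range(30)],
                                 "driver": "CALR", "cohort": "MF",
                                 "vaf": vaf})
        m = _matrix(rng.normal(20, 0.2, (20, 30)),
                    samples=list(clinical["patient_id"]))
        m.iloc[0] += 0.05 * vaf   # positive slope
        m.iloc[1] -= 0.05 * vaf   # negative slope
        table, _, significant = integ.vaf_correlation(m, clinical, "CALR")
        assert table.iloc[0]["pearson_r"] > 0.9
        assert table.iloc[1]["pearson_r"] < -0.9
        assert {"P0", "P1"} <= set(significant)


class TestSubgroupDifferential:
    def _clinical(self):
        rows = []
        for i in range(4):
            rows.append({"patient_id": f"h{i}", "cohort": "MF",
                         "driver": "CALR", "homozygous": True, "vaf": 90.0})
            rows.append({"patient_id": f"e{i}", "cohort": "MF",
                         "driver": "CALR", "homozygous": False, "vaf": 40.0})
            rows.append({"patient_id": f"j{i}", "cohort": "MF",
                         "driver": "JAK2", "homozygous": False, "vaf": 40.0})
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_delta(self):
        clinical = self._clinical()
        resp = _responses({p: 2.0 for p in clinical["patient_id"]},
                          readout="oncogenic")
        table = integ.subgroup_drug_differential(resp, clinical)
        assert table.iloc[0]["delta_vs_het"] == 0.0
        assert table.iloc[0]["delta_vs_jak2"] == 0.0

    def test_homozygous_specific_effect_maximal_on_both_axes(self):
        clinical = self._clinical()
        values = {p: (4.0 if p.startswith("h") else 0.2)
                  for p in clinical["patient_id"]}
        planted = _responses(values, drug="hit", readout="oncogenic")
        null = _responses({p: 0.2 for p in clinical["patient_id"]},
                          drug="null", readout="oncogenic")
        table = integ.subgroup_drug_differential(
            pd.concat([planted, null], ignore_index=True), clinical)
        top = table.sort_values("delta_vs_het", ascending=False).iloc[0]
        assert top["drug"] == "hit"
        assert top["delta_vs_het"] == pytest.approx(3.8)
        assert top["delta_vs_jak2"] == pytest.approx(3.8)

    def test_small_group_flagged_na(self):
        clinical = self._clinical().iloc[:3]  # one patient per group
        resp = _responses({p: 1.0 for p in clinical["patient_id"]},
                          readout="oncogenic")
        table = integ.subgroup_drug_differential(resp, clinical)
        assert not table.iloc[0]["valid"]
        assert np.isnan(table.iloc[0]["delta_vs_het"])
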