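"""Cell classification, well summarization, QC and drug scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pharmotype import pharmacoscopy as ph


def _toy_cells(n_per_class=200, seed=0, separation=50.0):
    """Fully separated synthetic single cells (4 classes, all viable)."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, cls in enumerate(("HSPC", "T-cell", "monocyte", "other")):
        base = separation * (i + 1)
        frames.append(pd.DataFrame({
            "nuclear_stain": base + rng.random(n_per_class),
            "lineage": base * 2 + rng.random(n_per_class),
            "cd34": base * 3 + rng.random(n_per_class),
            "oncogenic": base * 4 + rng.random(n_per_class),
            "nuclear_area": base + rng.random(n_per_class),
            "true_class": cls,
            "true_viable": True,
        }))
    dead = frames[0].copy()
    dead["true_viable"] = False
    dead[["nuclear_stain", "lineage", "cd34", "oncogenic",
          "nuclear_area"]] = rng.random((n_per_class, 5))
    frames.append(dead)
    return pd.concat(frames, ignore_index=True)


class TestClassifier:
    def test_separable_cells_classified_perfectly(self):
        clf = ph.train_cell_classifier(_toy_cells(), seed=0)
        assert clf.report["accuracy"] == 1.0
        assert all(v == 1.0 for v in clf.report["sensitivity"].values())

    def test_probability_rows_sum_to_one(self):
        cells = _toy_cells()
        clf = ph.train_cell_classifier(cells, seed=0)
        proba = clf.predict_proba(cells.head(50))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_permuted_labels_give_chance_accuracy(self):
        cells = _toy_cells(n_per_class=300)
        rng = np.random.default_rng(1)
        cells = cells[cells["true_viable"]].copy()
        cells["true_class"] = rng.permutation(cells["true_class"].to_numpy())
        clf = ph.train_cell_classifier(cells, seed=1)
        n_test = clf.report["n_test"]
        ci = 4 * np.sqrt(0.25 * 0.75 / n_test)
        assert abs(clf.report["accuracy"] - 0.25) < ci

    def test_single_class_rejected(self):
        cells = _toy_cells()
        cells["true_class"] = "HSPC"
        with pytest.raises(ValueError):
            ph.train_cell_classifier(cells, seed=0)

    def test_realistic_cells_classified_accurately(self, mf_screen):
        sample = mf_screen["cells"].sample(12000, random_state=0)
        clf = ph.train_cell_classifier(sample, seed=0)
        assert clf.report["accuracy"] > 0.9          # cell-type calls
        assert clf.report["viability_accuracy"] > 0.9  # live/dead calls


class TestGating:
    def test_truth_bypass_is_identity_on_labels(self):
        cells = _toy_cells()
        gated = ph.classify_and_gate(cells, use_truth=True)
        assert (gated["cell_class"] == gated["true_class"]).all()
        assert gated["true_viable"].all()
        assert len(gated) == int(cells["true_viable"].sum())

    def test_empty_input_no_crash(self):
        gated = ph.classify_and_gate(_toy_cells().iloc[0:0], use_truth=True)
        assert gated.empty

    def test_missing_feature_column_raises(self):
        cells = _toy_cells().drop(columns=["cd34"])
        clf = ph.train_cell_classifier(_toy_cells(), seed=0)
        with pytest.raises(KeyError):
            ph.classify_and_gate(cells, clf)


def _manual_well(counts, patient="p1", well="W1", role="DMSO", drug="",
                 onc=10.0):
    rows = []
    for cls, n in counts.items():
        for _ in range(n):
            rows.append({"patient_id": patient, "well": well, "drug": drug,
                         "concentration": np.nan, "role": role,
                         "cell_class": cls, "oncogenic": onc,
                         "lineage": 1.0, "cd34": 1.0})
    return pd.DataFrame(rows)


class TestWellSummaries:
    def test_fractions_from_known_counts(self):
        gated = _manual_well({"HSPC": 10, "T-cell": 40, "monocyte": 20,
                              "other": 30})
        summ = ph.summarize_wells(gated)
        row = summ.iloc[0]
        assert row["frac_HSPC"] == pytest.approx(0.1)
        assert row["frac_T-cell"] == pytest.approx(0.4)
        assert row["frac_monocyte"] == pytest.approx(0.2)
        assert row["frac_other"] == pytest.approx(0.3)
        assert row["n_viable"] == 100

    def test_class_fractions_sum_to_one(self, mf_screen):
        gated = ph.classify_and_gate(mf_screen["cells"], use_truth=True)
        summ = ph.summarize_wells(gated)
        fracs = summ[[f"frac_{c}" for c in
                      ("HSPC", "T-cell", "monocyte", "other")]].sum(axis=1)
        np.testing.assert_allclose(fracs, 1.0)

    def test_all_below_threshold_gives_zero_positive_fraction(self):
        # constant oncogenic intensity: threshold equals the value, nothing
        # is strictly above it
        gated = _manual_well({"HSPC": 5, "T-cell": 5, "monocyte": 5,
                              "other": 5}, onc=10.0)
        summ = ph.summarize_wells(gated)
        assert summ.iloc[0]["pos_frac"] == 0.0

    def test_patient_zscores_have_zero_mean_unit_sd(self, mf_screen):
        gated = ph.classify_and_gate(mf_screen["cells"], use_truth=True)
        thresholds = ph.marker_thresholds(gated)
        df = gated.copy()
        for pid, sub in df.groupby("patient_id"):
            z = (sub["oncogenic"] - sub["oncogenic"].mean()) / \
                sub["oncogenic"].std()
            assert abs(z.mean()) < 1e-10
            assert z.std() == pytest.approx(1.0)
        assert thresholds.index.is_unique

    def test_empty_wells_flagged_via_all_cells(self):
        cells = _manual_well({"HSPC": 5, "T-cell": 5})
        dead_well = cells.copy()
        dead_well["well"] = "W2"
        all_cells = pd.concat([cells, dead_well], ignore_index=True)
        summ = ph.summarize_wells(cells, all_cells=all_cells)
        flagged = summ[summ["well"] == "W2"]
        assert len(flagged) == 1
        assert not flagged.iloc[0]["valid"]


class TestQc:
    def _summaries(self, fractions):
        rows = []
        for pid, frac in fractions.items():
            for w in range(3):
                rows.append({"patient_id": pid, "well": f"W{w}",
                             "drug": "", "role": "DMSO", "valid": True,
                             "frac_HSPC": frac})
        return pd.DataFrame(rows)

    def test_boundary_closed_at_threshold(self):
        summ = self._summaries({"lo": 0.0029, "hi": 0.0031, "at": 0.003})
        included, report = ph.qc_patients(summ)
        assert included == ["at", "hi"]
        assert not report.loc[report["patient_id"] == "lo",
                              "included"].iloc[0]

    def test_zero_threshold_includes_all(self):
        summ = self._summaries({"a": 0.0, "b": 0.001})
        included, _ = ph.qc_patients(summ, min_hspc_fraction=0.0)
        assert included == ["a", "b"]

    def test_patient_without_controls_raises(self):
        summ = self._summaries({"a": 0.01})
        summ["role"] = "drug"
        with pytest.raises(ValueError):
            ph.qc_patients(summ)


class TestScoring:
    def _summaries(self, drug_vals, ctrl_vals, col="frac_HSPC"):
        rows = []
        for i, v in enumerate(drug_vals):
            rows.append({"patient_id": "p", "well": f"D{i}", "drug": "dx",
                         "concentration": 1.0, "role": "drug", "valid": True,
                         col: v})
        for i, v in enumerate(ctrl_vals):
            rows.append({"patient_id": "p", "well": f"C{i}", "drug": "",
                         "concentration": np.nan, "role": "DMSO",
                         "valid": True, col: v})
        return pd.DataFrame(rows)

    def test_printed_toy_wells_r_and_p(self):
        drug = [0.2, 0.25, 0.15, 0.2]
        ctrl = [0.4, 0.45, 0.35, 0.4]
        resp = ph.score_drug(self._summaries(drug, ctrl), "p", "dx", "HSPC")
        assert resp["relative_change"] == pytest.approx(0.5)
        # independent closed-form pooled-variance t-test
        na, nb = len(drug), len(ctrl)
        sp2 = (((na - 1) * np.var(drug, ddof=1)
                + (nb - 1) * np.var(ctrl, ddof=1)) / (na + nb - 2))
        t = (np.mean(drug) - np.mean(ctrl)) / np.sqrt(sp2 * (1/na + 1/nb))
        p_hand = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert resp["p_value"] == pytest.approx(p_hand, rel=1e-12)
        assert resp["signed_sig"] == pytest.approx(-np.log10(p_hand))

    def test_identical_zero_variance_wells(self):
        resp = ph.score_drug(self._summaries([0.3, 0.3], [0.3, 0.3]),
                             "p", "dx", "HSPC")
        assert resp["relative_change"] == 0.0
        assert resp["p_value"] == 1.0
        assert resp["signed_sig"] == 0.0
        assert resp["response_class"] == "non-responder"

    def test_zero_control_mean_flagged_invalid(self):
        resp = ph.score_drug(self._summaries([0.1, 0.1], [0.0, 0.0]),
                             "p", "dx", "HSPC")
        assert not resp["valid"]
        assert resp["response_class"] == "invalid"

    def test_off_target_increase_scores_negative(self):
        resp = ph.score_drug(self._summaries([0.6, 0.62], [0.3, 0.31, 0.29]),
                             "p", "dx", "HSPC")
        assert resp["relative_change"] < 0
        assert resp["signed_sig"] < 0

    def test_planted_graded_kills_recovered_monotonically(self, mf_screen):
        gated = ph.classify_and_gate(mf_screen["cells"], use_truth=True)
        summ = ph.summarize_wells(gated)
        resp = ph.score_all(summ, mf_screen["layout"], readouts=("HSPC",))
        med = resp.groupby("drug")["relative_change"].median()
        assert med["drug_01"] < med["drug_02"] < med["drug_03"]
        assert med["drug_02"] == pytest.approx(0.5, abs=0.1)
        sig = resp.groupby("drug")["signed_sig"].median()
        assert sig["drug_01"] < sig["drug_02"] < sig["drug_03"]
        # null drugs center near zero
        assert abs(med[["drug_04", "drug_05", "drug_06"]].mean()) < 0.05

    def test_split_half_controls_center_at_zero(self, mf_screen):
        gated = ph.classify_and_gate(mf_screen["cells"], use_truth=True)
        summ = ph.summarize_wells(gated)
        ctrl = summ[summ["role"] == "DMSO"].copy()
        # relabel half of the control wells as a pseudo-drug
        pseudo = []
        for _, sub in ctrl.groupby("patient_id"):
            half = sub.iloc[: len(sub) // 2].copy()
            half["role"] = "drug"
            half["drug"] = "pseudo"
            pseudo.append(pd.concat([half, sub.iloc[len(sub) // 2:]]))
        pseudo = pd.concat(pseudo, ignore_index=True)
        rows = [ph.score_drug(pseudo, pid, "pseudo", "HSPC")
                for pid in pseudo["patient_id"].unique()]
        rs = pd.DataFrame(rows)["relative_change"]
        assert abs(rs.mean()) < 3 * rs.std() / np.sqrt(len(rs))


class TestResponseClassification:
    @pytest.mark.parametrize("r,p,expected", [
        (0.4, 0.01, "responder"),
        (0.4, 0.5, "non-responder"),
        (-0.4, 0.01, "resistant"),
        (-0.4, 0.5, "non-responder"),
    ])
    def test_classification_rule(self, r, p, expected):
        assert ph.classify_response(r, p) == expected

    def test_resistant_switch(self):
        assert ph.classify_response(
            -0.4, 0.5, resistant_requires_significance=False) == "resistant"


class TestCohortSummary:
    def test_mean_signed_sig_and_fraction_arithmetic(self):
        clinical = pd.DataFrame({"patient_id": [f"p{i}" for i in range(10)],
                                 "driver": "CALR"})
        rows = []
        for i in range(10):
            for readout, sig_n in (("HSPC", 3), ("oncogenic", 5)):
                significant = i < sig_n
                rows.append({
                    "patient_id": f"p{i}", "drug": "dx", "readout": readout,
                    "relative_change": 0.5,
                    "p_value": 0.01 if significant else 0.5,
                    "signed_sig": 2.0 if readout == "HSPC" else 4.0,
                    "valid": True})
        summary = ph.cohort_summary(pd.DataFrame(rows), clinical)
        row = summary.iloc[0]
        assert row["mean_signed_sig_HSPC"] == pytest.approx(2.0)
        assert row["mean_signed_sig_oncogenic"] == pytest.approx(4.0)
        # 3/10 and 5/10 significant on-target -> averaged fraction 0.4
        assert row["frac_significant_on_target"] == pytest.approx(0.4)
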