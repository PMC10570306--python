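"""End-to-end validation measurements on the named synthetic scenarios.

Each function runs one study condition from :mod:`pharmotype.synth.scenarios`
through the relevant pipeline stages and returns the measured quantities
(error rates, recovered effects, recall, overlaps) together with the problem
size. They are the single implementation behind both the acceptance test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from pharmotype import association as assoc
from pharmotype import integrate as integ
from pharmotype import pharmacoscopy as ph
from pharmotype import proteotype as prot
from pharmotype import signature as sigmod
from pharmotype._rng import child_seed
from pharmotype.synth import scenarios, simulate_cohort, simulate_pharmacoscopy, simulate_proteomes


def _screen_responses(config, seed: int, readouts=("HSPC",),
                      use_truth_gate: bool = False):
    """Simulate plates, classify/gate, summarize, QC and score."""
    clinical = simulate_cohort(config, seed)
    cells, layout, truth = simulate_pharmacoscopy(clinical, config, seed)
    if use_truth_gate:
        gated = ph.classify_and_gate(cells, use_truth=True)
    else:
        n_train = min(20_000, len(cells))
        train = cells.sample(n_train, random_state=child_seed(seed, "classifier"))
        clf = ph.train_cell_classifier(train, seed=child_seed(seed,
                                                              "classifier", 1))
        gated = ph.classify_and_gate(cells, clf)
    summaries = ph.summarize_wells(gated, all_cells=cells)
    included, qc_report = ph.qc_patients(summaries)
    summaries = summaries[summaries["patient_id"].isin(included)]
    responses = ph.score_all(summaries, layout, readouts=readouts)
    return {"clinical": clinical, "truth": truth, "responses": responses,
            "included": included, "qc_report": qc_report}


def toy_scoring() -> dict:
    """The printed four-well example: r must be exactly 0.5 and p must match
    the closed-form pooled-variance t-test."""
    drug, ctrl = [0.2, 0.25, 0.15, 0.2], [0.4, 0.45, 0.35, 0.4]
    rows = ([{"patient_id": "p", "well": f"D{i}", "drug": "dx",
              "concentration": 1.0, "role": "drug", "valid": True,
              "frac_HSPC": v} for i, v in enumerate(drug)]
            + [{"patient_id": "p", "well": f"C{i}", "drug": "",
                "concentration": np.nan, "role": "DMSO", "valid": True,
                "frac_HSPC": v} for i, v in enumerate(ctrl)])
    resp = ph.score_drug(pd.DataFrame(rows), "p", "dx", "HSPC")
    na, nb = len(drug), len(ctrl)
    sp2 = (((na - 1) * np.var(drug, ddof=1) + (nb - 1) * np.var(ctrl, ddof=1))
           / (na + nb - 2))
    t = (np.mean(drug) - np.mean(ctrl)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p_hand = 2 * stats.t.sf(abs(t), na + nb - 2)
    return {"relative_change": resp["relative_change"],
            "p_value": resp["p_value"],
            "p_abs_error": abs(resp["p_value"] - p_hand),
            "n": na + nb}


def type_one_error(seed: int, n_patients: int = 40, n_drugs: int = 20) -> dict:
    """Fraction of p < 0.05 on-target (HSPC-readout) calls on a null screen."""
    out = _screen_responses(scenarios.null_screen(n_patients, n_drugs),
                            seed, readouts=("HSPC",))
    resp = out["responses"]
    resp = resp[resp["valid"]]
    return {"rate": float((resp["p_value"] < 0.05).mean()),
            "n": int(len(resp))}


def effect_recovery(seed: int) -> dict:
    """Recovery of a planted HSPC survival of 0.5 on one drug."""
    out = _screen_responses(scenarios.effect_recovery(0.5), seed,
                            readouts=("HSPC",))
    resp = out["responses"]
    planted = resp[(resp["drug"] == "drug_01") & resp["valid"]]
    return {"median_r": float(planted["relative_change"].median()),
            "responder_recall": float(
                (planted["response_class"] == "responder").mean()),
            "n": int(len(planted))}


def qc_inclusion(seed: int) -> dict:
    """43 patients with 3 planted below the 0.3% control-HSPC bar."""
    config = scenarios.qc_scenario()
    clinical = simulate_cohort(config, seed)
    cells, _, _ = simulate_pharmacoscopy(clinical, config, seed)
    gated = ph.classify_and_gate(cells, use_truth=True)
    summaries = ph.summarize_wells(gated, all_cells=cells)
    included, _ = ph.qc_patients(summaries)
    return {"n_included": int(len(included)), "n": int(len(clinical))}


def filter_and_imputation_toy(seed: int) -> dict:
    """Exact application of the 90%-per-group rule on a six-protein toy and
    the imputation bound min_p <= imputed <= min_p + log2(1.05)."""
    samples = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
    groups = pd.Series(["A"] * 10 + ["B"] * 10, index=samples)
    m = pd.DataFrame(20.0, index=list("PQRSTU"), columns=samples)
    m.loc["Q", "a0"] = np.nan
    m.loc["R", [f"b{i}" for i in range(10)]] = np.nan
    m.loc["S", ["a0", "a1", "b0", "b1"]] = np.nan
    m.loc["T", ["a0", "a1"]] = np.nan
    m.loc["U", ["a0", "a1", "a2", "b0", "b1", "b2"]] = np.nan
    kept = prot.filter_missingness(m, groups)
    imputed = prot.impute_left_censored(kept, noise_frac=0.05, seed=seed)
    mask = kept.isna()
    row_min = kept.min(axis=1)
    vals = imputed.where(mask)
    ok = ((vals.ge(row_min, axis=0) & vals.le(row_min + np.log2(1.05),
                                              axis=0)) | ~mask)
    return {"n_retained": int(len(kept)),
            "imputed_in_bounds_fraction": float(ok.all(axis=None)),
            "n": int(mask.to_numpy().sum())}


def contaminant_orthogonality(seed: int, n_proteins: int = 4000) -> dict:
    """Max |Pearson r| of any protein with the hemoglobin covariate after
    regression, on a matrix sized to the 113-sample proteotyping cohort."""
    config = scenarios.proteome_cohort(n_proteins)
    clinical = simulate_cohort(config, seed)
    matrices, _ = simulate_proteomes(clinical, config, seed)
    m = matrices["granulocyte"]
    groups = clinical.set_index("patient_id")["group"].reindex(m.columns)
    filtered = prot.filter_missingness(m, groups)
    imputed = prot.impute_left_censored(filtered, seed=child_seed(seed,
                                                                  "imputation"))
    corrected = prot.regress_contaminant(imputed)
    c = corrected.attrs["contaminant_covariate"].to_numpy()
    r, _ = integ._pearson_vec(corrected.to_numpy(), c)
    return {"max_abs_corr": float(np.nanmax(np.abs(r))),
            "n_proteins": int(corrected.shape[0]),
            "n": int(corrected.shape[1])}


def gsea_enumeration(seed: int, n_perm: int = 10_000) -> dict:
    """Monte-Carlo permutation p against the exhaustive C(10,3) oracle."""
    ranking = pd.Series(np.arange(10, 0, -1, dtype=float),
                        index=[f"g{i}" for i in range(10)])
    members = ["g0", "g1", "g4"]
    out = assoc.gsea_preranked(ranking, {"s": members}, n_perm=n_perm,
                               seed=seed, min_size=1)
    es_obs = float(out.iloc[0]["es"])
    weights = ranking.sort_values(ascending=False).abs().to_numpy()

    def es_of(positions):
        hits = np.zeros(10, bool)
        hits[list(positions)] = True
        hw = np.where(hits, weights, 0.0)
        running = np.cumsum(hw / hw.sum() - (~hits) / 7.0)
        return running[np.argmax(np.abs(running))]

    null = [es_of(c) for c in itertools.combinations(range(10), 3)]
    p_exact = float(np.mean([abs(e) >= abs(es_obs) - 1e-12 for e in null]))
    return {"p_permutation": float(out.iloc[0]["p_value"]),
            "p_exact": p_exact,
            "abs_error": abs(float(out.iloc[0]["p_value"]) - p_exact),
            "n": n_perm}


def signature_recovery(seed: int, n_runs: int = 25) -> dict:
    """Planted 15-protein signature among 500 proteins, five classes of 20;
    scaled-down repeated-RFE mode (25 runs, threshold ceil(0.85 * 25))."""
    config = scenarios.signature_scenario()
    clinical = simulate_cohort(config, seed)
    matrices, _ = simulate_proteomes(clinical, config, seed)
    labels = clinical.set_index("patient_id")["group"]
    min_freq = int(np.ceil(0.85 * n_runs))
    result = sigmod.select_signature(matrices["granulocyte"], labels,
                                     n_runs=n_runs, min_freq=min_freq,
                                     base_seed=seed)
    planted = [f"SIG{i:02d}" for i in range(1, 16)]
    freqs = result.frequencies
    recall = float((freqs[planted] >= min_freq).mean())
    noise = int((freqs.drop(planted) >= min_freq).sum())
    return {"planted_recall": recall,
            "noise_proteins_in_signature": noise,
            "mean_test_accuracy": float(result.score_summary.loc["mean",
                                                                 "accuracy"]),
            "n": n_runs}


def replicative_recovery(seed: int) -> dict:
    """Top-50 recovery of the planted MCM-anchored block across three cell
    types and tertile agreement with the planted latent ordering."""
    config = scenarios.replicative_scenario()
    clinical = simulate_cohort(config, seed)
    raw, truth = simulate_proteomes(clinical, config, seed)
    # analyses run on processed (filtered + imputed) matrices, as in the
    # enforced pipeline order
    groups = clinical.set_index("patient_id")["group"]
    matrices = {}
    for i, (ct, m) in enumerate(sorted(raw.items())):
        filtered = prot.filter_missingness(m, groups.reindex(m.columns))
        matrices[ct] = prot.impute_left_censored(
            filtered, seed=child_seed(seed, "imputation", i))
    top50, _ = integ.derive_replicative_signature(matrices, k=50)
    planted = set(truth["blocks"]["replicative"]["members"])
    categories = integ.categorize_mcm(matrices)
    latent = truth["anchor_latents"]["replicative"]
    codes = categories.set_index("patient_id")["mcm_category"].map(
        {"low": 0, "medium": 1, "high": 2})
    # compare like with like: tertiles of the true latent vs the assigned
    # categories (perfect agreement -> tau = 1)
    true_codes = pd.qcut(latent.reindex(codes.index), 3,
                         labels=False)
    tau = stats.kendalltau(codes, true_codes).statistic
    return {"overlap_top50": int(len(planted & set(top50))),
            "kendall_tau": float(tau),
            "n": int(len(codes))}


def homozygous_differential(seed: int) -> dict:
    """Rank (1 = top) of the planted homozygous-CALR-specific drug on both
    differential axes of the oncogenic readout."""
    out = _screen_responses(scenarios.homozygous_scenario(), seed,
                            readouts=("oncogenic",), use_truth_gate=True)
    table = integ.subgroup_drug_differential(out["responses"],
                                             out["clinical"])
    valid = table[table["valid"]].reset_index(drop=True)
    rank_het = int((valid["delta_vs_het"]
                    > valid.loc[valid["drug"] == "drug_03",
                                "delta_vs_het"].iloc[0]).sum()) + 1
    rank_jak2 = int((valid["delta_vs_jak2"]
                     > valid.loc[valid["drug"] == "drug_03",
                                 "delta_vs_jak2"].iloc[0]).sum()) + 1
    return {"rank_vs_heterozygous": rank_het,
            "rank_vs_jak2": rank_jak2,
            "n": int(len(valid))}
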