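"""Cross-modality integration of drug responses, proteotypes and clinical data.

All joins are by ``patient_id``; patients present in one modality but not the
other are recorded in the returned tables' ``attrs['missing_patients']``
rather than silently dropped. The "drug response" value used for correlation
analyses is the signed significance (sign(r) * -log10 p) of the on-target
readout; the relative change travels alongside in every response table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from pharmotype.association import differential_t, gsea_preranked, protein_factor_anova

MCM_ANCHORS = ("MCM4", "MCM7")


def _pearson_vec(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of matrix ``x`` (rows = proteins) against vector
    ``y``, with two-sided p from the t approximation. Missing values in ``x``
    are handled pairwise-complete per row."""
    mask = np.isfinite(x)
    n = mask.sum(axis=1).astype(float)
    x0 = np.where(mask, x, 0.0)
    sy = mask @ y
    sy2 = mask @ (y * y)
    sx = x0.sum(axis=1)
    sx2 = (x0 * x0).sum(axis=1)
    sxy = x0 @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        var_x = sx2 - sx**2 / n
        var_y = sy2 - sy**2 / n
        r = cov / np.sqrt(var_x * var_y)
    r = np.clip(r, -1.0, 1.0)
    df = np.maximum(n - 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1e-12))
    p = np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, p)
    p = np.where(df < 1, np.nan, p)
    return r, p


def _response_vector(responses: pd.DataFrame, drug: str, readout: str,
                     value: str = "signed_sig") -> pd.Series:
    sub = responses[(responses["drug"] == drug)
                    & (responses["readout"] == readout)
                    & responses["valid"]]
    return sub.set_index("patient_id")[value]


# ---------------------------------------------------------------------------
# drug x proteome
# ---------------------------------------------------------------------------

def drug_protein_correlation(
    responses: pd.DataFrame,
    matrix: pd.DataFrame,
    sets: dict[str, list[str]],
    readout: str = "HSPC",
    min_patients: int = 5,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per drug: Spearman correlation of each protein with the drug response
    across patients, preranked enrichment on the correlation ranking, and
    per-set counts of drugs with significant positive (sensitivity) or
    negative (resistance) enrichment.

    Returns ``(correlations, enrichments, counts)`` in long form.
    """
    corr_rows, enrich_frames = [], []
    drugs = sorted(responses.loc[responses["readout"] == readout,
                                 "drug"].unique())
    all_missing: set[str] = set()
    for drug in drugs:
        resp = _response_vector(responses, drug, readout)
        shared = [p for p in resp.index if p in matrix.columns]
        all_missing |= (set(resp.index) ^ set(matrix.columns))
        if len(shared) < min_patients:
            warnings.warn(f"drug {drug!r}: only {len(shared)} shared patients")
            continue
        y = resp.reindex(shared).to_numpy(float)
        if np.all(y == y[0]):
            warnings.warn(f"drug {drug!r}: constant response vector, skipped")
            continue
        # Spearman: Pearson on average ranks
        x = matrix[shared].to_numpy(float)
        xr = stats.rankdata(x, axis=1)
        yr = stats.rankdata(y)
        rho, p = _pearson_vec(xr, yr)
        corr_rows.append(pd.DataFrame({
            "drug": drug, "protein": matrix.index, "rho": rho, "p_value": p,
            "n": len(shared)}))
        ranking = pd.Series(rho, index=matrix.index).dropna()
        enr = gsea_preranked(ranking, sets, n_perm=n_perm, seed=seed)
        enr.insert(0, "drug", drug)
        enrich_frames.append(enr)

    correlations = (pd.concat(corr_rows, ignore_index=True)
                    if corr_rows else pd.DataFrame())
    enrichments = (pd.concat(enrich_frames, ignore_index=True)
                   if enrich_frames else pd.DataFrame())
    counts = pd.DataFrame()
    if not enrichments.empty:
        sig = enrichments[enrichments["p_value"] < alpha]
        counts = (sig.groupby(["set_name", "direction"])["drug"]
                  .nunique().unstack(fill_value=0)
                  .reindex(columns=["positive", "negative"], fill_value=0)
                  .rename(columns={"positive": "n_sensitivity",
                                   "negative": "n_resistance"})
                  .reset_index())
    correlations.attrs["missing_patients"] = sorted(all_missing)
    return correlations, enrichments, counts


def drug_clinical_anova(
    responses: pd.DataFrame,
    clinical: pd.DataFrame,
    factors: list[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per drug x readout x clinical factor ANOVA of the signed significance,
    with per-factor counts of significant associations split into sensitivity
    (factor level/slope associated with stronger on-target response) and
    resistance."""
    clin = clinical.set_index("patient_id")
    result_frames = []
    for readout in sorted(responses["readout"].unique()):
        sub = responses[(responses["readout"] == readout) & responses["valid"]]
        wide = sub.pivot_table(index="drug", columns="patient_id",
                               values="signed_sig")
        for factor_name in factors:
            fac = clin[factor_name].reindex(wide.columns)
            # drop factor levels carried by fewer than 2 patients
            if not pd.api.types.is_numeric_dtype(fac):
                counts = fac.value_counts()
                fac = fac[fac.isin(counts[counts >= 2].index)]
            if fac.nunique() < 2:
                continue
            table = protein_factor_anova(wide, fac.dropna())
            table = table.rename(columns={"protein": "drug"})
            table.insert(1, "readout", readout)
            table.insert(2, "factor", factor_name)
            result_frames.append(table)
    full = (pd.concat(result_frames, ignore_index=True)
            if result_frames else pd.DataFrame())
    counts = pd.DataFrame()
    if not full.empty:
        sig = full[full["p_value"] < alpha]
        counts = (sig.assign(direction=np.where(sig["sign"] > 0,
                                                "sensitivity", "resistance"))
                  .groupby(["factor", "direction"]).size()
                  .unstack(fill_value=0)
                  .reindex(columns=["sensitivity", "resistance"], fill_value=0)
                  .reset_index())
    return full, counts


def responder_proteome(
    responses: pd.DataFrame,
    matrix: pd.DataFrame,
    drugs: str | list[str],
    readout: str = "HSPC",
    min_class_responses: int = 3,
    min_responders: int = 3,
    sets: dict[str, list[str]] | None = None,
    n_perm: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein-level t-tests of responders vs non-responders/resistant.

    For a single drug, responders are its responder-classified patients; for
    a drug class (list), a patient responds to the class when classified as
    responder for at least ``min_class_responses`` of its members. Enrichment
    runs on the signed -log10 p ranking of the t-tests.
    """
    drug_list = [drugs] if isinstance(drugs, str) else list(drugs)
    sub = responses[(responses["drug"].isin(drug_list))
                    & (responses["readout"] == readout) & responses["valid"]]
    n_resp = (sub[sub["response_class"] == "responder"]
              .groupby("patient_id").size())
    need = 1 if len(drug_list) == 1 else min_class_responses
    responders = set(n_resp[n_resp >= need].index)
    patients = [p for p in sub["patient_id"].unique() if p in matrix.columns]
    group_a = [p for p in patients if p in responders]
    group_b = [p for p in patients if p not in responders]
    if len(group_a) < min_responders:
        raise ValueError(f"only {len(group_a)} responders (< {min_responders})")
    if len(group_b) < 2:
        raise ValueError("fewer than 2 non-responding patients")
    volcano = differential_t(matrix, group_a, group_b)
    enrichment = pd.DataFrame()
    if sets is not None:
        ranking = volcano.set_index("protein")["signed_sig"]
        enrichment = gsea_preranked(ranking, sets, n_perm=n_perm, seed=seed)
    volcano.attrs["responders"] = sorted(group_a)
    volcano.attrs["missing_patients"] = sorted(
        set(sub["patient_id"]) - set(patients))
    return volcano, enrichment


# ---------------------------------------------------------------------------
# replicative (MCM) signature
# ---------------------------------------------------------------------------

def derive_replicative_signature(
    matrices: dict[str, pd.DataFrame],
    anchors: tuple[str, ...] = MCM_ANCHORS,
    k: int = 50,
) -> tuple[list[str], pd.DataFrame]:
    """Top-``k`` proteins by average (across cell types) Pearson correlation
    with the mean anchor (MCM4/MCM7) level; anchors rank at the top by
    construction. Cell types missing an anchor are excluded with a warning.
    Only proteins quantified in every retained cell type are ranked."""
    per_ct = {}
    for ct, matrix in matrices.items():
        missing = [a for a in anchors if a not in matrix.index]
        if missing:
            warnings.warn(f"cell type {ct!r}: anchors {missing} missing, "
                          "excluded")
            continue
        anchor_mean = matrix.loc[list(anchors)].mean(axis=0).to_numpy(float)
        ok = np.isfinite(anchor_mean)
        r, _ = _pearson_vec(matrix.to_numpy(float)[:, ok], anchor_mean[ok])
        per_ct[ct] = pd.Series(r, index=matrix.index)
    if not per_ct:
        raise ValueError("no cell type contains the anchor proteins")
    shared = set.intersection(*(set(s.index) for s in per_ct.values()))
    table = pd.DataFrame({ct: s.reindex(sorted(shared))
                          for ct, s in per_ct.items()})
    table["mean_r"] = table.mean(axis=1)
    table = table.sort_values("mean_r", ascending=False)
    table.index.name = "protein"
    signature = table.head(k).index.tolist()
    return signature, table.reset_index()


def categorize_mcm(
    matrices: dict[str, pd.DataFrame],
    anchors: tuple[str, ...] = MCM_ANCHORS,
) -> pd.DataFrame:
    """Rank patients by mean anchor level within each cell type, average the
    ranks across available cell types, and split into low/medium/high
    tertiles (ties broken by patient ID)."""
    rank_frames = {}
    for ct, matrix in matrices.items():
        present = [a for a in anchors if a in matrix.index]
        if not present:
            warnings.warn(f"cell type {ct!r}: no anchors, excluded")
            continue
        level = matrix.loc[present].mean(axis=0)
        rank_frames[ct] = level.rank(method="average")
    if not rank_frames:
        raise ValueError("no cell type contains the anchor proteins")
    ranks = pd.DataFrame(rank_frames)
    ranks = ranks.dropna(how="all")
    mean_rank = ranks.mean(axis=1)
    ordered = mean_rank.to_frame("mean_rank").reset_index(names="patient_id")
    ordered = ordered.sort_values(["mean_rank", "patient_id"]).reset_index(drop=True)
    n = len(ordered)
    bounds = [round(n / 3), round(2 * n / 3)]
    category = np.array(["low"] * n, dtype=object)
    category[bounds[0]:bounds[1]] = "medium"
    category[bounds[1]:] = "high"
    ordered["mcm_category"] = category
    ordered["n_cell_types"] = ranks.notna().sum(axis=1).reindex(
        ordered["patient_id"]).to_numpy()
    return ordered


def signature_scores(
    matrix: pd.DataFrame,
    proteins: list[str],
) -> pd.Series:
    """Mean expression of signature proteins per patient, each protein
    z-scored across patients first."""
    present = [p for p in proteins if p in matrix.index]
    if not present:
        raise ValueError("no signature proteins in matrix")
    sub = matrix.loc[present]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1).replace(0, np.nan),
                                              axis=0)
    return z.mean(axis=0)


def signature_drug_correlation(
    scores: pd.Series,
    responses: pd.DataFrame,
    readout: str = "HSPC",
    min_patients: int = 5,
) -> pd.DataFrame:
    """Per drug: Pearson correlation of the signature score with the
    on-target drug response across patients."""
    rows = []
    for drug in sorted(responses.loc[responses["readout"] == readout,
                                     "drug"].unique()):
        resp = _response_vector(responses, drug, readout)
        shared = [p for p in resp.index if p in scores.index
                  and np.isfinite(scores[p])]
        if len(shared) < min_patients:
            warnings.warn(f"drug {drug!r}: <{min_patients} shared patients, "
                          "skipped")
            continue
        r, p = stats.pearsonr(scores.reindex(shared), resp.reindex(shared))
        rows.append({"drug": drug, "pearson_r": float(r),
                     "p_value": float(p), "n": len(shared)})
    return pd.DataFrame(rows, columns=["drug", "pearson_r", "p_value", "n"])


# ---------------------------------------------------------------------------
# VAF and homozygosity
# ---------------------------------------------------------------------------

def vaf_correlation(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    driver: str,
    sets: dict[str, list[str]] | None = None,
    sig_alpha: float = 0.01,
    min_n: int = 5,
    n_perm: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Within the driver-stratified subcohort: per-protein Pearson
    correlation with VAF (plus a diagnosis-confounded ANOVA), preranked
    enrichment on the correlation ranking, and the significant-protein list
    (p < ``sig_alpha``) for network assembly."""
    clin = clinical.set_index("patient_id")
    stratum = [p for p in matrix.columns
               if clin["driver"].get(p) == driver]
    if len(stratum) < min_n:
        raise ValueError(f"driver stratum {driver!r} has n={len(stratum)} < "
                         f"{min_n}")
    vaf = clin["vaf"].reindex(stratum).astype(float)
    if vaf.nunique() < 2:
        raise ValueError("VAF is constant in the stratum")
    r, p = _pearson_vec(matrix[stratum].to_numpy(float), vaf.to_numpy())
    table = pd.DataFrame({"protein": matrix.index, "pearson_r": r,
                          "p_value": p, "n": len(stratum)})
    anova = protein_factor_anova(matrix[stratum], vaf,
                                 confounder=clin["cohort"].reindex(stratum))
    table = table.merge(
        anova[["protein", "p_value", "sign"]].rename(
            columns={"p_value": "anova_p", "sign": "anova_sign"}),
        on="protein")
    enrichment = pd.DataFrame()
    if sets is not None:
        ranking = pd.Series(r, index=matrix.index).dropna()
        enrichment = gsea_preranked(ranking, sets, n_perm=n_perm, seed=seed)
    significant = table.loc[table["p_value"] < sig_alpha, "protein"].tolist()
    return table, enrichment, significant


def subgroup_drug_differential(
    responses: pd.DataFrame,
    clinical: pd.DataFrame,
    readout: str = "oncogenic",
) -> pd.DataFrame:
    """Per drug: mean signed-significance difference of homozygous-CALR MF
    patients (VAF >= 75) versus heterozygous-CALR MF and versus JAK2 MF.
    Drugs whose groups have < 2 patients are flagged NA."""
    clin = clinical.set_index("patient_id")
    mf = clin[clin["cohort"] == "MF"]
    homo = set(mf[(mf["driver"] == "CALR") & mf["homozygous"]].index)
    het = set(mf[(mf["driver"] == "CALR") & ~mf["homozygous"]].index)
    jak2 = set(mf[mf["driver"] == "JAK2"].index)
    rows = []
    for drug in sorted(responses.loc[responses["readout"] == readout,
                                     "drug"].unique()):
        resp = _response_vector(responses, drug, readout)
        g_homo = resp.reindex([p for p in resp.index if p in homo]).dropna()
        g_het = resp.reindex([p for p in resp.index if p in het]).dropna()
        g_jak2 = resp.reindex([p for p in resp.index if p in jak2]).dropna()
        row = {"drug": drug, "n_homozygous": len(g_homo),
               "n_heterozygous": len(g_het), "n_jak2": len(g_jak2),
               "delta_vs_het": np.nan, "delta_vs_jak2": np.nan,
               "valid": False}
        if len(g_homo) >= 2:
            if len(g_het) >= 2:
                row["delta_vs_het"] = float(g_homo.mean() - g_het.mean())
            if len(g_jak2) >= 2:
                row["delta_vs_jak2"] = float(g_homo.mean() - g_jak2.mean())
            row["valid"] = (np.isfinite(row["delta_vs_het"])
                            and np.isfinite(row["delta_vs_jak2"]))
        rows.append(row)
    return pd.DataFrame(rows)
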