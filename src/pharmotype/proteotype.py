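"""Protein intensity matrix processing.

The processing chain mirrors a label-free DIA quantification workflow at the
matrix level: log2 transform with per-sample median centering and per-protein
median summarization (a documented simplified stand-in for a full
feature-level mixed model), robust outlier flagging, a group-structured
missingness filter (keep a protein if observed in >= 90% of the patients of
at least one group, so group-specific expression survives while randomly
missing proteins are removed), left-censored imputation at the per-protein
minimum plus up to 5% upward noise, and removal of red-blood-cell
contamination by regressing every protein on the mean hemoglobin (HBA/HBB/
HBD) level and keeping the residual.

Every step appends to the matrix's ``attrs['provenance']`` so the enforced
order (normalize -> outliers -> filter -> impute -> regress) is recorded in
the output metadata.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import median_abs_deviation, ttest_ind

from pharmotype._rng import stream
from pharmotype.synth.config import HEMOGLOBIN_PROTEINS


def _with_provenance(matrix: pd.DataFrame, source: pd.DataFrame | None,
                     step: str) -> pd.DataFrame:
    matrix.attrs["provenance"] = [*(source.attrs.get("provenance", [])
                                    if source is not None else []), step]
    return matrix


def normalize_summarize(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Feature-level table -> log2, median-centered, per-protein matrix.

    ``feature_table`` columns: ``protein``, ``feature``, ``sample``,
    ``intensity`` (raw, linear scale). Each sample's feature-level log2
    median is shifted to the global median; a protein's value is the median
    of its features. Single-feature proteins pass through unchanged.
    """
    required = {"protein", "feature", "sample", "intensity"}
    if not required.issubset(feature_table.columns):
        raise ValueError(f"feature table needs columns {sorted(required)}")
    if (feature_table["intensity"] <= 0).any():
        raise ValueError("raw intensities must be positive")
    df = feature_table.copy()
    df["log2"] = np.log2(df["intensity"])
    sample_medians = df.groupby("sample")["log2"].transform("median")
    df["log2"] = df["log2"] - sample_medians + df["log2"].median()
    matrix = df.pivot_table(index="protein", columns="sample", values="log2",
                            aggfunc="median")
    matrix.columns.name = None
    return _with_provenance(matrix, None, "normalize_summarize(log2, "
                            "per-sample median centering, median summary)")


def flag_outliers(
    matrix: pd.DataFrame,
    cell_types: pd.Series | None = None,
    n_mad: float = 3.0,
) -> pd.DataFrame:
    """Flag samples by (a) low median Pearson correlation to same-cell-type
    samples and (b) high missing-value count, each at median +/- n_mad
    normal-consistent MADs of the cohort."""
    if cell_types is None:
        cell_types = pd.Series("all", index=matrix.columns)
    rows = []
    for ct in sorted(cell_types.unique()):
        samples = [s for s in matrix.columns if cell_types.get(s) == ct]
        sub = matrix[samples]
        n_missing = sub.isna().sum(axis=0)
        if len(samples) < 3:
            warnings.warn(f"cell type {ct!r}: <3 samples, no outlier flags")
            for s in samples:
                rows.append({"sample": s, "cell_type": ct,
                             "median_correlation": np.nan,
                             "n_missing": int(n_missing[s]),
                             "flag_correlation": False, "flag_missing": False})
            continue
        corr = sub.corr(method="pearson", min_periods=3)
        np.fill_diagonal(corr.values, np.nan)
        med_corr = corr.median(axis=0)
        corr_cut = (med_corr.median()
                    - n_mad * median_abs_deviation(med_corr, scale="normal",
                                                   nan_policy="omit"))
        miss_cut = (n_missing.median()
                    + n_mad * median_abs_deviation(n_missing, scale="normal"))
        for s in samples:
            rows.append({
                "sample": s, "cell_type": ct,
                "median_correlation": float(med_corr[s]),
                "n_missing": int(n_missing[s]),
                "flag_correlation": bool(med_corr[s] < corr_cut),
                "flag_missing": bool(n_missing[s] > miss_cut),
            })
    report = pd.DataFrame(rows)
    report["flagged"] = report["flag_correlation"] | report["flag_missing"]
    return report


def filter_missingness(
    matrix: pd.DataFrame,
    groups: pd.Series,
    min_group_presence: float = 0.9,
) -> pd.DataFrame:
    """Retain a protein iff observed in >= ``min_group_presence`` of the
    samples of at least one group."""
    unlabeled = [s for s in matrix.columns if pd.isna(groups.get(s))]
    if unlabeled:
        raise ValueError(f"samples without group label: {unlabeled[:5]}")
    observed = matrix.notna()
    keep = pd.Series(False, index=matrix.index)
    for _, samples in groups.groupby(groups).groups.items():
        cols = [s for s in samples if s in matrix.columns]
        if not cols:
            continue
        keep |= observed[cols].mean(axis=1) >= min_group_presence
    out = matrix.loc[keep].copy()
    out.attrs["retained"] = keep[keep].index.tolist()
    return _with_provenance(
        out, matrix,
        f"filter_missingness(min_group_presence={min_group_presence})")


def impute_left_censored(
    matrix: pd.DataFrame,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Replace each missing value with the protein's lowest observed value
    plus up to ``noise_frac`` upward noise on the linear scale:
    log2(min_linear * (1 + U(0, noise_frac))). Observed values are never
    altered; the imputation mask is stored in ``attrs['imputed_mask']``."""
    values = matrix.to_numpy(float)
    missing = np.isnan(values)
    no_obs = missing.all(axis=1)
    if no_obs.any():
        raise ValueError(
            f"proteins with no observed values: "
            f"{matrix.index[no_obs].tolist()[:5]}")
    rng = stream(seed, "imputation")
    row_min = np.nanmin(values, axis=1)
    rows, cols = np.nonzero(missing)  # row-major order: deterministic
    noise = rng.uniform(0.0, noise_frac, size=rows.size)
    values = values.copy()
    values[rows, cols] = row_min[rows] + np.log2(1.0 + noise)
    out = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    out.attrs["imputed_mask"] = pd.DataFrame(missing, index=matrix.index,
                                             columns=matrix.columns)
    return _with_provenance(out, matrix,
                            f"impute_left_censored(noise_frac={noise_frac}, "
                            f"seed={seed})")


def regress_contaminant(
    matrix: pd.DataFrame,
    contaminant_proteins: tuple[str, ...] = HEMOGLOBIN_PROTEINS,
    preserve_mean: bool = True,
) -> pd.DataFrame:
    """Remove the hemoglobin-contamination component from every protein.

    The covariate is the per-sample mean of the contaminant proteins' log2
    values. Each protein is replaced by its OLS residual against the
    covariate; with ``preserve_mean`` (default) the residual is re-anchored at
    the protein's mean level (intercept evaluated at the covariate mean) so
    downstream fold changes stay on the original scale. After the transform
    every protein's sample correlation with the covariate is numerically 0.
    """
    present = [p for p in contaminant_proteins if p in matrix.index]
    if not present:
        raise ValueError(f"none of {contaminant_proteins} present in matrix")
    if matrix.isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    c = matrix.loc[present].mean(axis=0).to_numpy(float)
    c_centered = c - c.mean()
    var_c = float(np.dot(c_centered, c_centered))
    if var_c == 0.0:
        warnings.warn("constant contamination covariate; identity transform")
        out = matrix.copy()
        return _with_provenance(out, matrix, "regress_contaminant(identity)")
    x = matrix.to_numpy(float)
    slopes = (x - x.mean(axis=1, keepdims=True)) @ c_centered / var_c
    out_values = x - slopes[:, None] * c_centered[None, :]
    if not preserve_mean:
        out_values = out_values - out_values.mean(axis=1, keepdims=True)
    out = pd.DataFrame(out_values, index=matrix.index, columns=matrix.columns)
    out.attrs["contaminant_covariate"] = pd.Series(c, index=matrix.columns)
    out.attrs["contaminant_slopes"] = pd.Series(slopes, index=matrix.index)
    return _with_provenance(
        out, matrix,
        f"regress_contaminant({','.join(present)}, "
        f"preserve_mean={preserve_mean})")


def process_matrix(
    matrix: pd.DataFrame,
    groups: pd.Series,
    cell_types: pd.Series | None = None,
    min_group_presence: float = 0.9,
    noise_frac: float = 0.05,
    seed: int = 0,
    contaminant_proteins: tuple[str, ...] = HEMOGLOBIN_PROTEINS,
    drop_flagged: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enforced pipeline on an already-normalized log2 matrix:
    outlier flags -> missingness filter -> imputation -> contaminant
    regression. Returns ``(processed, outlier_report)``."""
    report = flag_outliers(matrix, cell_types=cell_types)
    kept_samples = (report.loc[~report["flagged"], "sample"].tolist()
                    if drop_flagged else matrix.columns.tolist())
    filtered = filter_missingness(matrix[kept_samples],
                                  groups.reindex(kept_samples),
                                  min_group_presence)
    imputed = impute_left_censored(filtered, noise_frac=noise_frac, seed=seed)
    processed = regress_contaminant(imputed,
                                    contaminant_proteins=contaminant_proteins)
    return processed, report


def cohort_distances(
    matrix: pd.DataFrame,
    groups: pd.Series,
    subcohort_pairs: list[tuple[str, str]],
) -> dict[tuple[str, str], np.ndarray]:
    """Between-sample Euclidean distances over the full protein vector for
    each subcohort pair; self-comparisons excluded."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for ga, gb in subcohort_pairs:
        sa = [s for s in matrix.columns if groups.get(s) == ga]
        sb = [s for s in matrix.columns if groups.get(s) == gb]
        if ga == gb:
            if len(sa) < 2:
                raise ValueError(f"within-group comparison {ga!r} needs >= 2 "
                                 "samples")
            out[(ga, gb)] = pdist(matrix[sa].to_numpy(float).T,
                                  metric="euclidean")
        else:
            if not sa or not sb:
                raise ValueError(f"empty subcohort in pair ({ga!r}, {gb!r})")
            out[(ga, gb)] = cdist(matrix[sa].to_numpy(float).T,
                                  matrix[sb].to_numpy(float).T,
                                  metric="euclidean").ravel()
    return out


def distance_ttests(
    distances: dict[tuple[str, str], np.ndarray],
    comparisons: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Student's t-tests between selected distance distributions (all pairs
    by default)."""
    keys = list(distances)
    if comparisons is None:
        comparisons = [(keys[i], keys[j]) for i in range(len(keys))
                       for j in range(i + 1, len(keys))]
    rows = []
    for a, b in comparisons:
        res = ttest_ind(distances[a], distances[b], equal_var=True)
        rows.append({"pair_a": "-".join(a), "pair_b": "-".join(b),
                     "mean_a": float(np.mean(distances[a])),
                     "mean_b": float(np.mean(distances[b])),
                     "t": float(res.statistic), "p_value": float(res.pvalue)})
    return pd.DataFrame(rows)
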