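"""Single-cell classification, well summarization and drug-response scoring.

The pharmacoscopy readout scores each drug in each patient as the relative
reduction of a cell-population fraction of interest against the matched
vehicle-control wells (DMSO for small molecules, PBS for biologics, isotype
for antibodies):

    r = 1 - mean(f_drug) / mean(f_control)

pooling all replicates and concentrations of the drug, with a two-sided
pooled-variance Student's t-test on the well-level fractions. The signed
significance is sign(r) * (-log10 p): positive for on-target depletion,
negative for an off-target increase. A patient responds to a drug when the
on-target effect is significant (p < alpha and r > 0); a significant
off-target effect marks resistance; everything else is a non-responder.

Two readouts are first-class: the viable HSPC (CD34+) fraction and the
oncogenic-marker-positive fraction of viable cells (mutant-CALR or pSTAT5
stain above a per-patient threshold placed between the T-cell and
HSPC/monocyte intensity modes in control wells). Any gated population
fraction can be scored through the same engine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from pharmotype.synth.config import CELL_CLASSES

FEATURES = ("nuclear_stain", "lineage", "cd34", "oncogenic", "nuclear_area")
CONTROL_ROLES = ("DMSO", "PBS", "isotype")
#: p-value assigned when both groups are constant: equal means -> 1 (no
#: evidence), different means -> floor (certain difference, kept in (0, 1])
DEGENERATE_P_EQUAL = 1.0
DEGENERATE_P_DIFFERENT = 1e-16


# ---------------------------------------------------------------------------
# cell classification and gating
# ---------------------------------------------------------------------------

@dataclass
class CellClassifier:
    """Feature-based cell-type + viability classifier.

    A multinomial logistic regression on log-transformed channel intensities
    and nuclear area assigns one of the four cell classes; a second logistic
    model makes the live/dead call. The training report carries held-out
    accuracy and per-class sensitivity.
    """

    class_model: Pipeline
    viability_model: Pipeline
    classes_: list[str]
    report: dict = field(default_factory=dict)

    def predict_class(self, cells: pd.DataFrame) -> np.ndarray:
        return self.class_model.predict(_features(cells))

    def predict_proba(self, cells: pd.DataFrame) -> pd.DataFrame:
        proba = self.class_model.predict_proba(_features(cells))
        return pd.DataFrame(proba, columns=self.class_model.classes_,
                            index=cells.index)

    def predict_viable(self, cells: pd.DataFrame) -> np.ndarray:
        return self.viability_model.predict(_features(cells)).astype(bool)


def _features(cells: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURES if c not in cells.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    x = cells.loc[:, list(FEATURES)].to_numpy(float)
    return np.log1p(x)


def _model(seed: int) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("logreg", LogisticRegression(max_iter=1000, random_state=seed)),
    ])


def train_cell_classifier(
    labeled_cells: pd.DataFrame,
    seed: int,
    holdout: float = 0.25,
) -> CellClassifier:
    """Train class + viability models on truth-labeled cells.

    Requires ``true_class`` and ``true_viable`` columns; raises if fewer than
    two classes are present.
    """
    classes = labeled_cells["true_class"].unique()
    if len(classes) < 2:
        raise ValueError("need >= 2 cell classes to train a classifier")
    viable = labeled_cells[labeled_cells["true_viable"].astype(bool)]

    xv_train, xv_test = train_test_split(
        labeled_cells, test_size=holdout, random_state=seed,
        stratify=labeled_cells["true_viable"])
    if labeled_cells["true_viable"].nunique() < 2:
        # curated viable-only training sets: constant live call
        viability = Pipeline([("const", DummyClassifier(
            strategy="most_frequent"))])
    else:
        viability = _model(seed)
    viability.fit(_features(xv_train), xv_train["true_viable"].astype(bool))

    xc_train, xc_test = train_test_split(
        viable, test_size=holdout, random_state=seed,
        stratify=viable["true_class"])
    class_model = _model(seed)
    class_model.fit(_features(xc_train), xc_train["true_class"])

    y_pred = class_model.predict(_features(xc_test))
    report = {
        "accuracy": float(accuracy_score(xc_test["true_class"], y_pred)),
        "sensitivity": {
            cls: float(s) for cls, s in zip(
                class_model.classes_,
                recall_score(xc_test["true_class"], y_pred,
                             labels=class_model.classes_, average=None,
                             zero_division=0.0))
        },
        "viability_accuracy": float(accuracy_score(
            xv_test["true_viable"].astype(bool),
            viability.predict(_features(xv_test)).astype(bool))),
        "n_train": int(len(xc_train)),
        "n_test": int(len(xc_test)),
    }
    return CellClassifier(class_model, viability, list(class_model.classes_),
                          report)


def classify_and_gate(
    cells: pd.DataFrame,
    classifier: CellClassifier | None = None,
    use_truth: bool = False,
) -> pd.DataFrame:
    """Assign a class to every cell and retain only viable-called cells.

    With ``use_truth`` the simulator's labels bypass the classifier (identity
    on labels); otherwise a trained :class:`CellClassifier` is required.
    """
    if cells.empty:
        out = cells.copy()
        out["cell_class"] = pd.Series(dtype=object)
        return out
    if use_truth:
        gated = cells[cells["true_viable"].astype(bool)].copy()
        gated["cell_class"] = gated["true_class"]
        return gated
    if classifier is None:
        raise ValueError("classifier required unless use_truth=True")
    viable = classifier.predict_viable(cells)
    gated = cells[viable].copy()
    gated["cell_class"] = classifier.predict_class(gated)
    return gated


# ---------------------------------------------------------------------------
# well summaries
# ---------------------------------------------------------------------------

def marker_thresholds(
    gated: pd.DataFrame,
    policy: str = "t_vs_target_midpoint",
) -> pd.Series:
    """Per-patient oncogenic-positivity threshold.

    Default policy: geometric midpoint between the median oncogenic intensity
    of T-cells (in-sample negative reference) and of HSPC+monocyte cells,
    both taken over vehicle-control wells.
    """
    if policy != "t_vs_target_midpoint":
        raise ValueError(f"unknown threshold policy {policy!r}")
    controls = gated[gated["role"].isin(CONTROL_ROLES)]
    if controls.empty:  # no control wells at all: fall back to all wells
        controls = gated
    out = {}
    for pid, sub in controls.groupby("patient_id", sort=True):
        t_med = sub.loc[sub["cell_class"] == "T-cell", "oncogenic"].median()
        tgt = sub.loc[sub["cell_class"].isin(["HSPC", "monocyte"]),
                      "oncogenic"].median()
        if not (np.isfinite(t_med) and np.isfinite(tgt)):
            out[pid] = float(sub["oncogenic"].median())
        else:
            out[pid] = float(np.exp((np.log(t_med) + np.log(tgt)) / 2.0))
    return pd.Series(out, name="marker_threshold")


def summarize_wells(
    gated: pd.DataFrame,
    positivity_threshold_policy: str = "t_vs_target_midpoint",
    all_cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-well class fractions, marker-positive fraction and mean intensities.

    Input must be classified, viability-gated cells. Passing the pre-gating
    table as ``all_cells`` lets wells whose every cell was gated out appear as
    flagged rows (``valid=False``, NaN fractions) instead of vanishing. Mean
    channel intensities are additionally reported after per-patient z-scoring
    across that patient's cells.
    """
    if gated.empty:
        return pd.DataFrame(columns=["patient_id", "well", "drug",
                                     "concentration", "role", "n_viable",
                                     "valid"])
    thresholds = marker_thresholds(gated, positivity_threshold_policy)
    df = gated.copy()
    df["marker_threshold"] = df["patient_id"].map(thresholds)
    df["marker_pos"] = df["oncogenic"] > df["marker_threshold"]
    for ch in ("oncogenic", "lineage", "cd34"):
        grp = df.groupby("patient_id")[ch]
        mean, sd = grp.transform("mean"), grp.transform("std")
        df[f"z_{ch}"] = (df[ch] - mean) / sd.replace(0.0, np.nan)

    rows = []
    for (pid, well), sub in df.groupby(["patient_id", "well"], sort=True):
        row = {
            "patient_id": pid,
            "well": well,
            "drug": sub["drug"].iloc[0],
            "concentration": sub["concentration"].iloc[0],
            "role": sub["role"].iloc[0],
            "n_viable": int(len(sub)),
            "valid": len(sub) > 0,
            "marker_threshold": float(thresholds.get(pid, np.nan)),
        }
        for cls in CELL_CLASSES:
            row[f"frac_{cls}"] = float((sub["cell_class"] == cls).mean())
        row["pos_frac"] = float(sub["marker_pos"].mean())
        row["mean_oncogenic"] = float(sub["oncogenic"].mean())
        row["sum_oncogenic"] = float(sub["oncogenic"].sum())
        for cls in CELL_CLASSES:
            vals = sub.loc[sub["cell_class"] == cls, "oncogenic"]
            row[f"mean_oncogenic_{cls}"] = (float(vals.mean())
                                            if len(vals) else np.nan)
        for ch in ("oncogenic", "lineage", "cd34"):
            row[f"z_{ch}"] = float(sub[f"z_{ch}"].mean())
        rows.append(row)
    summaries = pd.DataFrame(rows)
    if all_cells is not None:
        seen = set(zip(summaries["patient_id"], summaries["well"]))
        flagged = []
        well_meta = all_cells.drop_duplicates(["patient_id", "well"])
        for rec in well_meta.itertuples():
            if (rec.patient_id, rec.well) in seen:
                continue
            flagged.append({"patient_id": rec.patient_id, "well": rec.well,
                            "drug": rec.drug, "concentration": rec.concentration,
                            "role": rec.role, "n_viable": 0, "valid": False})
        if flagged:
            summaries = pd.concat([summaries, pd.DataFrame(flagged)],
                                  ignore_index=True)
    return summaries


# ---------------------------------------------------------------------------
# patient QC
# ---------------------------------------------------------------------------

def qc_patients(
    summaries: pd.DataFrame,
    min_hspc_fraction: float = 0.003,
) -> tuple[list[str], pd.DataFrame]:
    """Include a patient iff the mean HSPC fraction over its DMSO vehicle
    wells is >= ``min_hspc_fraction`` (boundary closed at the threshold)."""
    report_rows = []
    included = []
    for pid, sub in summaries.groupby("patient_id", sort=True):
        vehicle = sub[(sub["role"] == "DMSO") & sub["valid"]]
        if vehicle.empty:
            raise ValueError(f"patient {pid!r} has no DMSO control wells")
        frac = float(vehicle["frac_HSPC"].mean())
        ok = frac >= min_hspc_fraction
        report_rows.append({"patient_id": pid, "control_hspc_fraction": frac,
                            "included": ok})
        if ok:
            included.append(pid)
    return included, pd.DataFrame(report_rows)


# ---------------------------------------------------------------------------
# drug scoring
# ---------------------------------------------------------------------------

def _readout_column(readout: str) -> str:
    if readout == "HSPC":
        return "frac_HSPC"
    if readout == "oncogenic":
        return "pos_frac"
    if readout in CELL_CLASSES:
        return f"frac_{readout}"
    return readout  # arbitrary gated-population column


def _pooled_t_p(drug_vals: np.ndarray, ctrl_vals: np.ndarray) -> float:
    """Two-sided pooled-variance Student's t-test p on well-level values."""
    if np.var(drug_vals) == 0.0 and np.var(ctrl_vals) == 0.0:
        return (DEGENERATE_P_EQUAL if np.mean(drug_vals) == np.mean(ctrl_vals)
                else DEGENERATE_P_DIFFERENT)
    p = stats.ttest_ind(drug_vals, ctrl_vals, equal_var=True).pvalue
    return float(min(max(p, DEGENERATE_P_DIFFERENT), 1.0))


def signed_significance(relative_change: float, p_value: float) -> float:
    """sign(r) * (-log10 p): positive = on-target depletion."""
    if not np.isfinite(relative_change) or relative_change == 0.0:
        return 0.0
    return float(math.copysign(-math.log10(p_value), relative_change))


def classify_response(
    relative_change: float,
    p_value: float,
    alpha: float = 0.05,
    resistant_requires_significance: bool = True,
) -> str:
    """responder = significant on-target depletion; resistant = off-target
    increase (significant by default); otherwise non-responder."""
    if not np.isfinite(relative_change):
        return "invalid"
    if p_value < alpha and relative_change > 0:
        return "responder"
    if relative_change < 0 and (p_value < alpha
                                or not resistant_requires_significance):
        return "resistant"
    return "non-responder"


def score_drug(
    summaries: pd.DataFrame,
    patient: str,
    drug: str,
    readout: str,
    control_role: str = "DMSO",
    alpha: float = 0.05,
    concentration: float | None = None,
) -> dict:
    """Score one patient x drug x readout against its matched controls.

    Pools all replicates and concentrations unless ``concentration`` is given.
    Returns a dict row (relative change, p, signed significance, class).
    """
    col = _readout_column(readout)
    sub = summaries[(summaries["patient_id"] == patient) & summaries["valid"]]
    drug_wells = sub[sub["drug"] == drug]
    if concentration is not None:
        drug_wells = drug_wells[drug_wells["concentration"] == concentration]
    ctrl_wells = sub[sub["role"] == control_role]
    if len(drug_wells) < 1 or len(ctrl_wells) < 2:
        raise ValueError(
            f"patient {patient!r}, drug {drug!r}: need >=1 drug well and "
            f">=2 {control_role} control wells "
            f"(got {len(drug_wells)}/{len(ctrl_wells)})")
    dv = drug_wells[col].to_numpy(float)
    cv = ctrl_wells[col].to_numpy(float)
    ctrl_mean = float(np.mean(cv))
    if ctrl_mean == 0.0:
        r, p, sig, valid = np.nan, np.nan, np.nan, False
        cls = "invalid"
    else:
        r = float(1.0 - np.mean(dv) / ctrl_mean)
        p = _pooled_t_p(dv, cv)
        sig = signed_significance(r, p)
        cls = classify_response(r, p, alpha)
        valid = True
    return {"patient_id": patient, "drug": drug, "readout": readout,
            "relative_change": r, "p_value": p, "signed_sig": sig,
            "response_class": cls, "n_drug_wells": int(len(drug_wells)),
            "n_control_wells": int(len(ctrl_wells)), "valid": valid}


def score_all(
    summaries: pd.DataFrame,
    layout: pd.DataFrame,
    readouts: tuple[str, ...] = ("HSPC", "oncogenic"),
    alpha: float = 0.05,
    per_concentration: bool = False,
) -> pd.DataFrame:
    """Score every patient x drug x readout; layout supplies control types."""
    control_of = dict(zip(layout["drug"], layout["control_type"]))
    rows = []
    for pid in summaries["patient_id"].unique():
        sub = summaries[summaries["patient_id"] == pid]
        for drug in sub.loc[sub["role"] == "drug", "drug"].unique():
            ctrl = control_of.get(drug, "DMSO")
            for readout in readouts:
                rows.append(score_drug(summaries, pid, drug, readout,
                                       control_role=ctrl, alpha=alpha))
                if per_concentration:
                    concs = sub.loc[sub["drug"] == drug,
                                    "concentration"].unique()
                    for conc in concs:
                        row = score_drug(summaries, pid, drug, readout,
                                         control_role=ctrl, alpha=alpha,
                                         concentration=conc)
                        row["concentration"] = conc
                        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(
    responses: pd.DataFrame,
    clinical: pd.DataFrame,
    stratify_by: str = "driver",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per drug x stratum: mean signed significance per readout and the
    fraction of patients with a significant on-target effect averaged across
    the readouts."""
    merged = responses.merge(
        clinical[["patient_id", stratify_by]], on="patient_id", how="left")
    merged = merged[merged["valid"]]
    readouts = sorted(merged["readout"].unique())
    rows = []
    for (drug, stratum), sub in merged.groupby(["drug", stratify_by],
                                               sort=True):
        if sub.empty:
            continue
        row = {"drug": drug, stratify_by: stratum,
               "n_patients": int(sub["patient_id"].nunique())}
        sig_fracs = []
        for readout in readouts:
            r_sub = sub[sub["readout"] == readout]
            if r_sub.empty:
                warnings.warn(f"no {readout} responses for {drug}/{stratum}")
                continue
            row[f"mean_signed_sig_{readout}"] = float(
                r_sub["signed_sig"].mean())
            sig_fracs.append(float(((r_sub["p_value"] < alpha)
                                    & (r_sub["relative_change"] > 0)).mean()))
        row["frac_significant_on_target"] = float(np.mean(sig_fracs))
        rows.append(row)
    return pd.DataFrame(rows)
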