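"""Pharmacoscopy plate simulation: single-cell tables with planted drug effects.

One 384-well-style plate per patient: vehicle-control wells (DMSO for small
molecules, PBS for biologics, isotype for antibodies) and, per drug, the
configured replicates at each concentration. Each well seeds ~``cells_per_well``
cells; each cell gets a class (HSPC/T-cell/monocyte/other) from the patient's
composition, a viability state, an oncogenic-marker state, and lognormal
channel intensities with class-specific modes (lineage CD3/CD14 high in
T-cells and monocytes, CD34 high in HSPCs, oncogenic marker high in
marker-positive HSPCs/monocytes and low in T-cells). Planted drug effects
convert targeted viable cells to dead with probability 1 - survival, so the
downstream relative-reduction score has a known expectation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pharmotype._rng import stream
from pharmotype.synth.config import (
    CELL_CLASSES,
    DrugEffect,
    SimulationConfig,
)

# log-scale channel means per (class, state); sigma from config
_LINEAGE_MU = {"HSPC": 3.4, "T-cell": 6.0, "monocyte": 5.0, "other": 3.4}
_CD34_MU = {"HSPC": 5.7, "T-cell": 3.4, "monocyte": 3.4, "other": 3.4}
_AREA_MU = {"HSPC": 85.0, "T-cell": 70.0, "monocyte": 110.0, "other": 75.0}
_ONC_MU_NEG = 3.9
_ONC_MU_POS = 6.0
_NUC_MU_VIABLE = 6.2
_NUC_MU_DEAD = 6.6   # condensed apoptotic nuclei stain brighter
_DEBRIS_MU = 3.6
_AREA_SD = 12.0
_AREA_DEAD = (35.0, 8.0)

#: truth threshold for marker positivity: geometric midpoint between the
#: T-cell (negative) and HSPC/monocyte (positive) intensity modes
MARKER_THRESHOLD = float(np.exp((_ONC_MU_NEG + _ONC_MU_POS) / 2.0))


def _matches_filter(row: pd.Series, patient_filter: str | None) -> bool:
    if patient_filter is None:
        return True
    if patient_filter == "homozygous-CALR":
        return bool(row["driver"] == "CALR" and row["cohort"] == "MF"
                    and row["homozygous"])
    kind, _, value = patient_filter.partition(":")
    if kind in ("driver", "cohort", "group") and value:
        return bool(row[kind] == value)
    raise ValueError(f"unknown patient_filter {patient_filter!r}")


def _resolve_survival(
    effects: tuple[DrugEffect, ...],
    clinical: pd.DataFrame,
    anchor_latents: dict[str, pd.Series] | None,
) -> pd.DataFrame:
    """Per patient x drug x readout planted survival multiplier (1 = null)."""
    rows = []
    for _, patient in clinical.iterrows():
        for eff in effects:
            if not _matches_filter(patient, eff.patient_filter):
                s = 1.0
            elif eff.scale_with is not None:
                if not anchor_latents or eff.scale_with not in anchor_latents:
                    raise ValueError(
                        f"drug effect on {eff.drug!r} scales with unknown "
                        f"proteome block {eff.scale_with!r}; pass the proteome "
                        "ground truth to simulate_pharmacoscopy")
                z = float(anchor_latents[eff.scale_with].get(
                    patient["patient_id"], 0.0))
                s = float(np.clip(eff.survival - eff.scale_coef * z, 0.02, 1.0))
            else:
                s = eff.survival
            rows.append({"patient_id": patient["patient_id"], "drug": eff.drug,
                         "readout": eff.readout, "survival": s})
    return pd.DataFrame(rows, columns=["patient_id", "drug", "readout",
                                       "survival"])


def simulate_pharmacoscopy(
    clinical: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
    proteome_truth: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate single-cell plates for every patient in ``clinical``.

    Returns ``(cells, layout, truth)``: the single-cell table, the drug-library
    layout, and the ground-truth record (per-patient compositions, planted
    survival multipliers, the marker-positivity threshold).
    """
    config.validate()
    if not config.drugs:
        raise ValueError("config.drugs is empty")
    rng = stream(seed, "plates")
    patients = clinical["patient_id"].tolist()
    n_pat = len(patients)

    # per-patient composition over (HSPC, T-cell, monocyte, other)
    hspc_frac = np.clip(
        rng.lognormal(np.log(config.hspc_fraction_mean),
                      config.hspc_fraction_sigma, n_pat), 0.005, 0.3)
    if config.low_hspc_patients:
        low_idx = rng.choice(n_pat, size=config.low_hspc_patients, replace=False)
        hspc_frac[low_idx] = rng.uniform(0.0005, 0.002,
                                         config.low_hspc_patients)
    rest = rng.dirichlet((22.5, 9.0, 18.5), size=n_pat)  # T, mono, other
    composition = np.column_stack([hspc_frac, rest * (1 - hspc_frac)[:, None]])

    vaf = clinical.set_index("patient_id")["vaf"].reindex(patients).to_numpy(float)
    pos_rate = np.clip(config.marker_positive_base
                       + config.marker_positive_vaf_coef * vaf, 0.0, 0.95)

    anchor_latents = (proteome_truth or {}).get("anchor_latents")
    survival = _resolve_survival(config.drug_effects, clinical, anchor_latents)
    surv_lookup: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for _, row in survival.iterrows():
        surv_lookup.setdefault((row["patient_id"], row["drug"]), []).append(
            (row["readout"], row["survival"]))

    control_types = sorted({d.control_type for d in config.drugs} | {"DMSO"})
    sigma = config.intensity_sigma
    plate = config.plate

    cols: dict[str, list[np.ndarray]] = {k: [] for k in (
        "patient_id", "plate", "well", "image", "drug", "concentration",
        "role", "nuclear_stain", "lineage", "cd34", "oncogenic",
        "nuclear_area", "true_class", "true_viable", "true_marker_pos")}

    for pi, pid in enumerate(patients):
        comp = composition[pi]
        p_pos = np.array([pos_rate[pi], 0.01, pos_rate[pi], 0.01])  # per class
        wells: list[tuple[str, str, float, str]] = []  # (well, drug, conc, role)
        w = 0
        for ctype in control_types:
            for _ in range(plate.n_control_wells.get(ctype, 0)):
                w += 1
                wells.append((f"W{w:03d}", "", np.nan, ctype))
        for drug in config.drugs:
            for conc in drug.concentrations:
                for _ in range(drug.replicates):
                    w += 1
                    wells.append((f"W{w:03d}", drug.name, conc, "drug"))

        for well, drug_name, conc, role in wells:
            n = int(rng.poisson(plate.cells_per_well))
            if n == 0:
                continue
            cls = rng.choice(4, size=n, p=comp)
            viable = rng.random(n) < plate.viable_fraction
            marker = rng.random(n) < p_pos[cls]
            if role == "drug":
                for readout, s in surv_lookup.get((pid, drug_name), []):
                    if s >= 1.0:
                        continue
                    if readout == "oncogenic":
                        targeted = viable & marker
                    elif readout in CELL_CLASSES:
                        targeted = viable & (cls == CELL_CLASSES.index(readout))
                    else:
                        raise ValueError(f"unknown effect readout {readout!r}")
                    kill = targeted & (rng.random(n) >= s)
                    viable &= ~kill

            lineage_mu = np.array([_LINEAGE_MU[c] for c in CELL_CLASSES])[cls]
            cd34_mu = np.array([_CD34_MU[c] for c in CELL_CLASSES])[cls]
            onc_mu = np.where(marker, _ONC_MU_POS, _ONC_MU_NEG)
            area_mu = np.array([_AREA_MU[c] for c in CELL_CLASSES])[cls]

            lineage = np.exp(np.where(viable, lineage_mu, _DEBRIS_MU)
                             + sigma * rng.standard_normal(n))
            cd34 = np.exp(np.where(viable, cd34_mu, _DEBRIS_MU)
                          + sigma * rng.standard_normal(n))
            onc = np.exp(np.where(viable, onc_mu, _DEBRIS_MU)
                         + sigma * rng.standard_normal(n))
            nuc = np.exp(np.where(viable, _NUC_MU_VIABLE, _NUC_MU_DEAD)
                         + sigma * rng.standard_normal(n))
            area = np.where(
                viable,
                area_mu + _AREA_SD * rng.standard_normal(n),
                _AREA_DEAD[0] + _AREA_DEAD[1] * rng.standard_normal(n))
            area = np.clip(area, 5.0, None)

            cols["patient_id"].append(np.repeat(pid, n))
            cols["plate"].append(np.repeat(pid, n))
            cols["well"].append(np.repeat(well, n))
            cols["image"].append(rng.integers(1, plate.n_images_per_well + 1,
                                              n))
            cols["drug"].append(np.repeat(drug_name, n))
            cols["concentration"].append(np.repeat(conc, n))
            cols["role"].append(np.repeat(role, n))
            cols["nuclear_stain"].append(nuc)
            cols["lineage"].append(lineage)
            cols["cd34"].append(cd34)
            cols["oncogenic"].append(onc)
            cols["nuclear_area"].append(area)
            cols["true_class"].append(np.array(CELL_CLASSES)[cls])
            cols["true_viable"].append(viable)
            cols["true_marker_pos"].append(onc > MARKER_THRESHOLD)

    cells = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    layout = pd.DataFrame([
        {"drug": d.name, "drug_class": d.drug_class,
         "control_type": d.control_type,
         "concentrations": ",".join(str(c) for c in d.concentrations),
         "replicates": d.replicates}
        for d in config.drugs])
    truth = {
        "composition": pd.DataFrame(composition, index=patients,
                                    columns=list(CELL_CLASSES)),
        "survival": survival,
        "marker_threshold": MARKER_THRESHOLD,
        "marker_positive_rate": pd.Series(pos_rate, index=patients),
    }
    return cells, layout, truth
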