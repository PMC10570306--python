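"""Proteome matrix simulation with planted, recoverable structure.

For each isolated cell type (granulocyte, HSPC, T-cell) a log2 intensity
matrix (proteins x patients) is built as

    x[p, s] = baseline_p + sum(block effects) + delta_p * h_s + N(0, sigma)

where block effects are group shifts, VAF-scaled slopes, or loadings on a
per-patient latent shared across cell types (anchor-coregulated blocks), and
h_s is a latent per-sample hemoglobin contamination factor that loads with
coefficient 1 on HBA/HBB/HBD and with configurable coefficients on bystander
proteins. Values below a per-protein detection-limit quantile are censored to
missing; additional values are removed completely at random. Every planted
quantity is returned in a ground-truth record.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pharmotype._rng import stream
from pharmotype.synth.config import (
    CELL_TYPES,
    HEMOGLOBIN_PROTEINS,
    SimulationConfig,
)


def simulate_proteomes(
    clinical: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Simulate one matrix per cell type plus the ground-truth record."""
    config.validate()
    if clinical.empty:
        raise ValueError("clinical table is empty")
    proteins = list(config.protein_universe)
    protein_index = {p: i for i, p in enumerate(proteins)}
    patients = clinical["patient_id"].tolist()
    n_p, n_s = len(proteins), len(patients)

    rng = stream(seed, "proteome")
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_p)

    # per-patient latents for anchor-coregulated blocks, shared across cell types
    anchor_latents: dict[str, pd.Series] = {}
    for block in config.blocks:
        if block.kind == "anchor_coregulated":
            anchor_latents[block.name] = pd.Series(
                rng.standard_normal(n_s), index=patients, name=block.name)

    group = clinical.set_index("patient_id")["group"].reindex(patients)
    driver = clinical.set_index("patient_id")["driver"].reindex(patients)
    vaf = clinical.set_index("patient_id")["vaf"].reindex(patients).to_numpy(float)

    # deterministic per-protein block contributions (sample-shaped)
    planted = np.zeros((n_p, n_s))
    for block in config.blocks:
        if block.kind == "group_discriminative":
            shift = group.map(lambda g: block.group_shifts.get(g, 0.0)).to_numpy(float)
            for member in block.members:
                planted[protein_index[member]] += shift
        elif block.kind == "vaf_scaled":
            mask = np.ones(n_s) if block.driver is None else (
                (driver == block.driver).to_numpy(float))
            contrib = block.slope * vaf * mask
            for member in block.members:
                planted[protein_index[member]] += contrib
        elif block.kind == "anchor_coregulated":
            z = anchor_latents[block.name].to_numpy()
            for member in block.members:
                planted[protein_index[member]] += block.loading_of(member) * z

    # contamination loadings (delta_p)
    delta = np.zeros(n_p)
    for hb in HEMOGLOBIN_PROTEINS:
        delta[protein_index[hb]] = 1.0
    for block in config.blocks:
        if block.kind == "contaminant_loading":
            for member in block.members:
                delta[protein_index[member]] = block.loading_of(member)

    matrices: dict[str, pd.DataFrame] = {}
    contamination: dict[str, pd.Series] = {}
    censored_fraction: dict[str, float] = {}
    for ct in CELL_TYPES:
        ct_rng = stream(seed, "proteome", CELL_TYPES.index(ct) + 1)
        if config.contamination_sd > 0:
            h = ct_rng.lognormal(0.0, config.contamination_sd, n_s)
        else:
            h = np.zeros(n_s)
        x = (baselines[:, None] + planted + delta[:, None] * h[None, :]
             + (ct_rng.normal(0.0, config.proteome_sd, (n_p, n_s))
                if config.proteome_sd > 0 else 0.0))

        # left censoring at the per-protein empirical detection-limit quantile
        n_censored = 0
        if config.detection_quantile > 0:
            limits = np.quantile(x, config.detection_quantile, axis=1)
            censor = x < limits[:, None]
            n_censored = int(censor.sum())
            x = np.where(censor, np.nan, x)
        # additional missingness completely at random
        if config.mcar_rate > 0:
            mcar = ct_rng.random((n_p, n_s)) < config.mcar_rate
            x = np.where(mcar, np.nan, x)
        matrices[ct] = pd.DataFrame(x, index=proteins, columns=patients)
        contamination[ct] = pd.Series(h, index=patients)
        censored_fraction[ct] = n_censored / (n_p * n_s)

    truth = {
        "baselines": pd.Series(baselines, index=proteins),
        "anchor_latents": anchor_latents,
        "contamination": contamination,
        "censored_fraction": censored_fraction,
        "blocks": {b.name: {"kind": b.kind, "members": list(b.members),
                            "slope": b.slope, "driver": b.driver,
                            "anchors": list(b.anchors)}
                   for b in config.blocks},
    }
    return matrices, truth
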