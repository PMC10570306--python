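"""Named study conditions used for end-to-end validation.

Each scenario fixes one synthetic study design with planted ground truth so
that a downstream property (type-I error, effect recovery, QC rule, signature
recovery, replicative-block recovery, homozygous-specific drug differential)
can be measured against a known answer. Plate cell counts are kept in the
hundreds-to-thousands so a scenario runs in minutes on one CPU; the plate
design structure (duplicates at two concentrations for small molecules,
control-well counts) follows the package's default study layout.
"""

from __future__ import annotations

from pharmotype.synth.config import (
    GROUPS,
    DrugEffect,
    DrugSpec,
    EffectBlock,
    PlateDesign,
    SimulationConfig,
    default_blocks,
)


def _small_molecules(n: int, prefix: str = "drug") -> tuple[DrugSpec, ...]:
    return tuple(DrugSpec(f"{prefix}_{i:02d}") for i in range(1, n + 1))


def null_screen(n_patients: int = 40, n_drugs: int = 20,
                cells_per_well: int = 300) -> SimulationConfig:
    """A cohort with no planted drug effects: every significant call is a
    false positive, so the observed p<0.05 rate measures the type-I error."""
    half = n_patients // 2
    return SimulationConfig(
        n_patients_per_group={"MF-CALR": half, "MF-JAK2": n_patients - half},
        n_proteins=50,
        drugs=_small_molecules(n_drugs),
        drug_effects=(),
        plate=PlateDesign(cells_per_well=cells_per_well),
    )


def effect_recovery(survival: float = 0.5, n_patients: int = 20,
                    cells_per_well: int = 1000) -> SimulationConfig:
    """One drug with a planted HSPC survival multiplier among null drugs."""
    half = n_patients // 2
    return SimulationConfig(
        n_patients_per_group={"MF-CALR": half, "MF-JAK2": n_patients - half},
        n_proteins=50,
        drugs=_small_molecules(6),
        drug_effects=(DrugEffect("drug_01", "HSPC", survival),),
        plate=PlateDesign(cells_per_well=cells_per_well),
    )


def qc_scenario(n_patients: int = 43, n_low: int = 3,
                cells_per_well: int = 3000) -> SimulationConfig:
    """``n_low`` patients planted below the 0.3% control-HSPC inclusion bar."""
    half = n_patients // 2
    return SimulationConfig(
        n_patients_per_group={"MF-CALR": half, "MF-JAK2": n_patients - half},
        n_proteins=50,
        drugs=_small_molecules(1),
        low_hspc_patients=n_low,
        plate=PlateDesign(cells_per_well=cells_per_well),
    )


def signature_scenario(n_per_class: int = 20,
                       n_proteins: int = 500) -> SimulationConfig:
    """Five balanced classes separated by the planted 15-protein structure;
    all other proteins are noise. Complete matrix (no missingness) so the
    selection loop sees exactly the planted signal."""
    blocks = tuple(b for b in default_blocks() if b.name.startswith("sig_"))
    return SimulationConfig(
        n_patients_per_group={g: n_per_class for g in GROUPS},
        n_proteins=n_proteins,
        blocks=blocks,
        detection_quantile=0.0,
        mcar_rate=0.0,
    )


def replicative_scenario(n_per_class: int = 10,
                         n_proteins: int = 800) -> SimulationConfig:
    """A 50-protein MCM4/MCM7-anchored co-regulated block sharing one latent
    per-patient score across the three cell types."""
    blocks = tuple(b for b in default_blocks()
                   if b.name in ("replicative",))
    return SimulationConfig(
        n_patients_per_group={g: n_per_class for g in GROUPS},
        n_proteins=n_proteins,
        blocks=blocks,
    )


def homozygous_scenario(cells_per_well: int = 500) -> SimulationConfig:
    """One drug whose oncogenic-readout kill is planted only in homozygous
    (VAF >= 75) CALR MF patients, among otherwise null drugs."""
    return SimulationConfig(
        n_patients_per_group={"MF-CALR": 12, "MF-JAK2": 10},
        n_proteins=50,
        drugs=_small_molecules(8),
        drug_effects=(DrugEffect("drug_03", "oncogenic", 0.4,
                                 patient_filter="homozygous-CALR"),),
        homozygous_fraction=0.5,
        plate=PlateDesign(cells_per_well=cells_per_well),
    )


def proteome_cohort(n_proteins: int = 4000) -> SimulationConfig:
    """The 113-sample five-group proteotyping cohort shape with the default
    planted blocks and hemoglobin contamination switched on; no plates."""
    return SimulationConfig(
        n_proteins=n_proteins,
        blocks=default_blocks(),
        contamination_sd=0.5,
    )
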