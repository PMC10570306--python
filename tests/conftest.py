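import warnings

import pytest

from pharmotype.synth import (
    GROUPS,
    DrugEffect,
    DrugSpec,
    PlateDesign,
    SimulationConfig,
    default_blocks,
    simulate_all,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def five_group_sim():
    """Small five-group cohort with the full default planted structure:
    proteomes with discriminative/replicative/VAF blocks and contamination,
    plus a tiny drug screen."""
    cfg = SimulationConfig(
        n_patients_per_group={g: 10 for g in GROUPS},
        n_proteins=500,
        blocks=default_blocks(),
        drugs=tuple(DrugSpec(f"drug_{i:02d}") for i in range(1, 4)),
        drug_effects=(DrugEffect("drug_01", "HSPC", 0.5),),
        contamination_sd=0.5,
        plate=PlateDesign(cells_per_well=200),
    )
    return simulate_all(cfg, seed=101)


@pytest.fixture(scope="session")
def mf_screen():
    """MF-only screen with graded planted HSPC kills (survival 0.8/0.5/0.2)
    on three of six drugs."""
    cfg = SimulationConfig(
        n_patients_per_group={"MF-CALR": 6, "MF-JAK2": 6},
        n_proteins=30,
        drugs=tuple(DrugSpec(f"drug_{i:02d}") for i in range(1, 7)),
        drug_effects=(
            DrugEffect("drug_01", "HSPC", 0.8),
            DrugEffect("drug_02", "HSPC", 0.5),
            DrugEffect("drug_03", "HSPC", 0.2),
        ),
        plate=PlateDesign(cells_per_well=600),
        hspc_fraction_mean=0.05,
    )
    return simulate_all(cfg, seed=202)
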