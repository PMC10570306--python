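"""Simulate a small synthetic MPN cohort with planted ground truth.

Builds a five-group clinical table (healthy donors, ET and MF patients split
by CALR/JAK2 driver), proteome matrices for three isolated cell types with
planted effect blocks, pharmacoscopy plates, gene sets and interaction edges,
then prints what was planted where.
"""

from pharmotype.synth import (
    GROUPS,
    DrugEffect,
    DrugSpec,
    PlateDesign,
    SimulationConfig,
    default_blocks,
    simulate_all,
)

config = SimulationConfig(
    n_patients_per_group={g: 6 for g in GROUPS},
    n_proteins=400,
    blocks=default_blocks(),
    drugs=tuple(DrugSpec(f"drug_{i:02d}") for i in range(1, 5)),
    drug_effects=(DrugEffect("drug_01", "HSPC", 0.5),),
    contamination_sd=0.5,
    plate=PlateDesign(cells_per_well=300),
)
result = simulate_all(config, seed=42)

clinical = result["clinical"]
print(f"cohort: {len(clinical)} patients")
print(clinical.groupby("group")[["vaf", "pb_blasts"]].mean().round(1))
print(f"\nhomozygous CALR (VAF >= 75): "
      f"{clinical['homozygous'].sum()} patients")

for ct, matrix in result["proteomes"].items():
    missing = matrix.isna().to_numpy().mean()
    print(f"proteome[{ct}]: {matrix.shape[0]} proteins x "
          f"{matrix.shape[1]} samples, {missing:.1%} missing")

cells = result["cells"]
print(f"\nsingle cells: {len(cells):,} rows, "
      f"{cells['well'].nunique()} wells/patient")
print("planted drug effects (per patient x drug survival multipliers):")
print(result["truth"]["plates"]["survival"]
      .query("survival < 1").head().to_string(index=False))
print(f"\ngene sets: {len(result['genesets'])} "
      f"(planted: {result['truth']['planted_sets']})")
# The survival column is the ground truth the scoring stage must recover:
# survival 0.5 on the HSPC readout should surface as relative reduction ~0.5.
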