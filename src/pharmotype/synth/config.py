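"""Simulation configuration: cohort shape, planted effects, plate design.

The defaults encode the study conditions the package is designed around: a
five-group clinical cohort (healthy donors plus essential-thrombocythemia and
myelofibrosis patients split by CALR/JAK2 driver mutation), a ~4000-protein
proteome per isolated cell type, and 384-well pharmacoscopy plates in which
small molecules run in duplicate at 1 and 10 uM and biologics/antibodies in
triplicate at 0.1, 1 and 10 ug/ml, scored against DMSO, PBS or isotype
control wells respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

GROUPS = ("HD", "ET-CALR", "ET-JAK2", "MF-CALR", "MF-JAK2")
CELL_TYPES = ("granulocyte", "HSPC", "T-cell")
CELL_CLASSES = ("HSPC", "T-cell", "monocyte", "other")
CONTROL_FOR_CLASS = {
    "small_molecule": "DMSO",
    "biologic": "PBS",
    "antibody": "isotype",
}
HEMOGLOBIN_PROTEINS = ("HBA", "HBB", "HBD")


@dataclass(frozen=True)
class DrugSpec:
    """One library entry: compound name, modality class and test design."""

    name: str
    drug_class: str = "small_molecule"  # small_molecule | biologic | antibody
    concentrations: tuple[float, ...] = (1.0, 10.0)
    replicates: int = 2
    control: str | None = None  # derived from drug_class when None

    @property
    def control_type(self) -> str:
        if self.control is not None:
            return self.control
        try:
            return CONTROL_FOR_CLASS[self.drug_class]
        except KeyError:
            raise ValueError(
                f"drug {self.name!r}: unknown class {self.drug_class!r} "
                "and no explicit control type"
            ) from None


@dataclass(frozen=True)
class DrugEffect:
    """A planted drug effect: survival multiplier on the targeted population.

    ``survival`` = 1 is a null drug; 0.5 halves the viable targeted cells.
    ``readout`` selects the population: ``"HSPC"`` kills viable CD34+ cells,
    ``"oncogenic"`` kills viable marker-positive cells, any cell-class name
    kills that class. ``patient_filter`` restricts the effect
    (``"homozygous-CALR"``, ``"driver:JAK2"``, ``"cohort:MF"`` or None = all).
    ``scale_with`` names an anchor-coregulated proteome block whose per-patient
    latent score modulates the kill: survival_i = clip(survival -
    scale_coef * latent_i, 0.02, 1), so high-latent patients are killed more
    when ``scale_coef`` > 0.
    """

    drug: str
    readout: str = "HSPC"
    survival: float = 1.0
    patient_filter: str | None = None
    scale_with: str | None = None
    scale_coef: float = 0.0


@dataclass(frozen=True)
class EffectBlock:
    """A planted proteome structure.

    kinds:
      group_discriminative -- log2 shift per clinical group (``group_shifts``)
      vaf_scaled           -- log2 slope per percent VAF (``slope``), optionally
                              restricted to one ``driver``
      anchor_coregulated   -- members load on one latent per-patient score
                              shared across cell types (``loadings``; anchors
                              listed in ``anchors`` are members too)
      contaminant_loading  -- bystander proteins that co-load on the latent
                              hemoglobin contamination factor
    """

    name: str
    kind: str
    members: tuple[str, ...]
    group_shifts: dict[str, float] | None = None
    slope: float = 0.0
    driver: str | None = None
    loadings: float | dict[str, float] = 1.0
    anchors: tuple[str, ...] = ()

    def loading_of(self, protein: str) -> float:
        if isinstance(self.loadings, dict):
            return float(self.loadings.get(protein, 0.0))
        return float(self.loadings)

    def validate(self) -> None:
        kinds = {"group_discriminative", "vaf_scaled", "anchor_coregulated",
                 "contaminant_loading"}
        if self.kind not in kinds:
            raise ValueError(f"block {self.name!r}: unknown kind {self.kind!r}")
        if self.kind != "contaminant_loading":
            clash = set(self.members) & set(HEMOGLOBIN_PROTEINS)
            if clash:
                raise ValueError(
                    f"block {self.name!r}: hemoglobin proteins {sorted(clash)} "
                    "may only appear in contaminant_loading blocks"
                )
        if self.kind == "group_discriminative":
            if not self.group_shifts:
                raise ValueError(f"block {self.name!r}: group_shifts required")
            unknown = set(self.group_shifts) - set(GROUPS)
            if unknown:
                raise ValueError(f"block {self.name!r}: unknown groups {unknown}")
        if self.kind == "anchor_coregulated":
            missing = set(self.anchors) - set(self.members)
            if missing:
                raise ValueError(
                    f"block {self.name!r}: anchors {sorted(missing)} not in members"
                )
        for value in ([self.slope]
                      + ([*self.loadings.values()] if isinstance(self.loadings, dict)
                         else [self.loadings])
                      + list((self.group_shifts or {}).values())):
            if not _finite(value):
                raise ValueError(f"block {self.name!r}: non-finite effect size")


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass(frozen=True)
class PlateDesign:
    """Per-patient plate: control wells per control type, cells per well."""

    cells_per_well: int = 10_000
    n_control_wells: dict[str, int] = field(
        default_factory=lambda: {"DMSO": 12, "PBS": 6, "isotype": 6}
    )
    n_images_per_well: int = 25
    viable_fraction: float = 0.85


@dataclass(frozen=True)
class SimulationConfig:
    n_patients_per_group: dict[str, int] = field(
        default_factory=lambda: {"HD": 31, "ET-CALR": 21, "ET-JAK2": 21,
                                 "MF-CALR": 20, "MF-JAK2": 20}
    )
    n_proteins: int = 4000
    blocks: tuple[EffectBlock, ...] = ()
    drugs: tuple[DrugSpec, ...] = ()
    drug_effects: tuple[DrugEffect, ...] = ()
    plate: PlateDesign = field(default_factory=PlateDesign)

    # proteome noise / missingness
    proteome_sd: float = 0.25          # residual log2 sd
    baseline_mean: float = 20.0        # mean log2 baseline intensity
    baseline_sd: float = 1.5
    contamination_sd: float = 0.0      # lognormal sd of hemoglobin latent; 0 = off
    detection_quantile: float = 0.05   # per-protein left-censoring quantile
    mcar_rate: float = 0.02

    # clinical shape
    homozygous_fraction: float = 0.2   # MF-CALR patients with VAF >= 75

    # pharmacoscopy shape
    intensity_sigma: float = 0.4       # log-scale sd of channel intensities
    hspc_fraction_mean: float = 0.04   # geometric mean of per-patient HSPC fraction
    hspc_fraction_sigma: float = 0.5
    low_hspc_patients: int = 0         # patients forced below the 0.3% QC bar
    marker_positive_base: float = 0.05
    marker_positive_vaf_coef: float = 0.007  # positive fraction ~ base + coef*VAF

    def validate(self) -> None:
        if set(self.n_patients_per_group) - set(GROUPS):
            raise ValueError(f"unknown groups in n_patients_per_group; "
                             f"allowed: {GROUPS}")
        if any(n <= 0 for n in self.n_patients_per_group.values()):
            raise ValueError("all group sizes must be > 0")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be > 0")
        for rate in (self.detection_quantile, self.mcar_rate,
                     self.homozygous_fraction, self.plate.viable_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        names = [d.name for d in self.drugs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate drug names in library")
        for drug in self.drugs:
            ctrl = drug.control_type  # raises if underivable
            if self.plate.n_control_wells.get(ctrl, 0) < 2:
                raise ValueError(
                    f"drug {drug.name!r} needs >= 2 {ctrl} control wells"
                )
        known_drugs = set(names)
        for eff in self.drug_effects:
            if eff.drug not in known_drugs:
                raise ValueError(f"drug effect for unknown drug {eff.drug!r}")
        block_names = [b.name for b in self.blocks]
        if len(block_names) != len(set(block_names)):
            raise ValueError("duplicate block names")
        for block in self.blocks:
            block.validate()

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    @property
    def n_patients(self) -> int:
        return sum(self.n_patients_per_group.values())

    @property
    def protein_universe(self) -> tuple[str, ...]:
        """Deterministic protein naming: special (block/contaminant) names
        first, then numbered fillers up to ``n_proteins``."""
        special: list[str] = list(HEMOGLOBIN_PROTEINS)
        for block in self.blocks:
            for member in block.members:
                if member not in special:
                    special.append(member)
        if len(special) > self.n_proteins:
            raise ValueError(
                f"{len(special)} named proteins exceed n_proteins={self.n_proteins}"
            )
        n_fill = self.n_proteins - len(special)
        fillers = [f"P{i:04d}" for i in range(1, n_fill + 1)]
        return tuple(special + fillers)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw["blocks"] = tuple(EffectBlock(**b) for b in raw.get("blocks", []))
        raw["drugs"] = tuple(DrugSpec(**d) for d in raw.get("drugs", []))
        raw["drug_effects"] = tuple(
            DrugEffect(**e) for e in raw.get("drug_effects", []))
        if "plate" in raw:
            raw["plate"] = PlateDesign(**raw["plate"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def default_drug_library(n_small: int = 71, n_biologic: int = 4,
                         n_antibody: int = 4) -> tuple[DrugSpec, ...]:
    """A 79-entry stand-in library with the study's test design."""
    drugs = [DrugSpec(f"drug_{i:02d}") for i in range(1, n_small + 1)]
    drugs += [DrugSpec(f"biologic_{i:02d}", "biologic",
                       (0.1, 1.0, 10.0), 3) for i in range(1, n_biologic + 1)]
    drugs += [DrugSpec(f"antibody_{i:02d}", "antibody",
                       (0.1, 1.0, 10.0), 3) for i in range(1, n_antibody + 1)]
    return tuple(drugs)


def default_blocks() -> tuple[EffectBlock, ...]:
    """Planted proteome structure mirroring the study's findings: a 15-protein
    disease/mutation-discriminative signature, a 50-protein MCM-anchored
    replicative block shared across cell types, a CALR-VAF-scaled ER-stress
    block, a negatively VAF-scaled glycoprotein block, and hemoglobin-loading
    bystanders."""
    sig = tuple(f"SIG{i:02d}" for i in range(1, 16))
    # distinct shift pattern per group so all five classes are separable
    patterns = {
        "HD": (0, 0, 0), "ET-CALR": (1, 0, 0), "ET-JAK2": (0, 1, 0),
        "MF-CALR": (1, 0, 1), "MF-JAK2": (0, 1, 1),
    }
    blocks = []
    for j, protein in enumerate(sig):
        axis = j % 3
        shift = {g: 1.2 * patterns[g][axis] * (1 if j % 2 == 0 else -1)
                 for g in GROUPS}
        blocks.append(EffectBlock(f"sig_{protein}", "group_discriminative",
                                  (protein,), group_shifts=shift))
    replicative = ("MCM4", "MCM7") + tuple(f"REP{i:02d}" for i in range(1, 49))
    blocks.append(EffectBlock(
        "replicative", "anchor_coregulated", replicative,
        loadings=0.8, anchors=("MCM4", "MCM7")))
    er = ("HSPA5", "CALX") + tuple(f"ER{i:02d}" for i in range(1, 19))
    blocks.append(EffectBlock("er_stress", "vaf_scaled", er,
                              slope=0.03, driver="CALR"))
    glyco = ("MPO", "EPX") + tuple(f"GLY{i:02d}" for i in range(1, 9))
    blocks.append(EffectBlock("glycoprotein", "vaf_scaled", glyco,
                              slope=-0.02, driver="CALR"))
    blocks.append(EffectBlock("rbc_bystander", "contaminant_loading",
                              tuple(f"RBC{i:02d}" for i in range(1, 6)),
                              loadings=0.5))
    return tuple(blocks)


def default_config() -> SimulationConfig:
    """Full study-shaped configuration (cohort sizes, 79 drugs, planted
    structure, contamination on)."""
    cfg = SimulationConfig(
        blocks=default_blocks(),
        drugs=default_drug_library(),
        drug_effects=(
            DrugEffect("drug_01", "HSPC", 0.5, patient_filter="driver:JAK2"),
            DrugEffect("drug_02", "HSPC", 0.9, scale_with="replicative",
                       scale_coef=0.25),
            DrugEffect("drug_03", "oncogenic", 0.4,
                       patient_filter="homozygous-CALR"),
        ),
        contamination_sd=0.5,
    )
    cfg.validate()
    return cfg
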