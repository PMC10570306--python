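"""Clinical cohort simulation.

One row per patient with cohort (HD/ET/MF), driver mutation, variant allele
frequency (VAF, percent), peripheral-blood blast percentage, demographics and
a treatment flag. Healthy donors carry no driver and VAF 0; heterozygous
patients draw VAF ~ U(20, 60); a configured fraction of MF-CALR patients is
homozygous with VAF ~ U(75, 100). VAF >= 75% defines the homozygous class.
"""

from __future__ import annotations

import pandas as pd

from pharmotype._rng import stream
from pharmotype.synth.config import GROUPS, SimulationConfig

HOMOZYGOUS_VAF = 75.0


def simulate_cohort(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Simulate the clinical annotation table.

    Deterministic given ``seed``; group sizes exactly as configured.
    """
    config.validate()
    rng = stream(seed, "cohort")
    rows = []
    for group in GROUPS:  # fixed order => reproducible
        n = config.n_patients_per_group.get(group, 0)
        cohort, _, driver = group.partition("-")
        for i in range(n):
            pid = f"{group}_{i + 1:03d}"
            if cohort == "HD":
                vaf = 0.0
                drv = "none"
            else:
                drv = driver
                homozygous = (group == "MF-CALR"
                              and rng.random() < config.homozygous_fraction)
                if homozygous:
                    vaf = rng.uniform(HOMOZYGOUS_VAF, 100.0)
                else:
                    vaf = rng.uniform(20.0, 60.0)
            blasts = {"HD": 0.0, "ET": 0.2, "MF": 1.5}[cohort]
            rows.append({
                "patient_id": pid,
                "group": group,
                "cohort": cohort,
                "driver": drv,
                "vaf": round(float(vaf), 2),
                "homozygous": bool(vaf >= HOMOZYGOUS_VAF),
                "pb_blasts": round(float(rng.gamma(2.0, blasts / 2.0))
                                   if blasts else 0.0, 2),
                "age": int(rng.integers(40, 86)),
                "sex": "F" if rng.random() < 0.5 else "M",
                "treated": bool(cohort != "HD" and rng.random() < 0.5),
            })
    return pd.DataFrame(rows)
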