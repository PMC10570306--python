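"""End-to-end simulation convenience: one call, all artifacts, one truth file."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from pharmotype import io
from pharmotype.synth.cohort import simulate_cohort
from pharmotype.synth.config import SimulationConfig
from pharmotype.synth.plates import simulate_pharmacoscopy
from pharmotype.synth.proteome import simulate_proteomes
from pharmotype.synth.resources import simulate_genesets, simulate_interactions


def simulate_all(config: SimulationConfig, seed: int,
                 out_dir: str | Path | None = None) -> dict:
    """Run every generator under one root seed; optionally write all files.

    Returns a dict with keys ``clinical``, ``proteomes`` (cell type ->
    matrix), ``cells``, ``layout``, ``genesets``, ``edges`` and ``truth``.
    """
    clinical = simulate_cohort(config, seed)
    proteomes, prot_truth = simulate_proteomes(clinical, config, seed)
    if config.drugs:
        cells, layout, plate_truth = simulate_pharmacoscopy(
            clinical, config, seed, proteome_truth=prot_truth)
    else:  # proteome-only study design
        cells, layout, plate_truth = pd.DataFrame(), pd.DataFrame(), {}
    genesets, planted_sets = simulate_genesets(config, seed)
    edges, planted_edges = simulate_interactions(config, seed)

    truth = {
        "proteome": prot_truth,
        "plates": plate_truth,
        "planted_sets": planted_sets,
        "planted_edges": planted_edges,
    }
    result = {"clinical": clinical, "proteomes": proteomes, "cells": cells,
              "layout": layout, "genesets": genesets, "edges": edges,
              "truth": truth}
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(result["clinical"], out / "clinical.tsv")
    for ct, matrix in result["proteomes"].items():
        io.write_matrix(matrix, out / f"proteome_{ct.replace('-', '_')}.tsv")
    io.write_table(result["cells"], out / "cells.tsv")
    io.write_table(result["layout"], out / "plate_layout.tsv")
    io.write_gmt(result["genesets"], out / "sets.gmt")
    io.write_table(result["edges"], out / "edges.tsv")
    io.write_json(_truth_jsonable(result["truth"]), out / "truth.json")


def _truth_jsonable(truth: dict):
    def convert(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="list") | (
                {"_index": obj.index.tolist()}
                if not isinstance(obj.index, pd.RangeIndex) else {})
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj
    return convert(truth)
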