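"""Gene-set and interaction-edge simulation.

Planted gene sets are the effect-block memberships (so enrichment of a planted
set is the recoverable signal); decoy sets of matched sizes are drawn without
replacement from non-block proteins. Planted interaction edges (score > 0.7)
connect members within co-regulated blocks, emulating a physical-interaction
database at its conventional high-confidence cutoff; decoy edges elsewhere
carry low scores.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from pharmotype._rng import stream
from pharmotype.synth.config import SimulationConfig

PLANTED_EDGE_SCORE = (0.75, 0.99)
DECOY_EDGE_SCORE = (0.10, 0.65)
_COREGULATED_KINDS = {"anchor_coregulated", "vaf_scaled"}


def simulate_genesets(
    config: SimulationConfig,
    seed: int,
    n_decoys: int = 20,
    min_set_size: int = 5,
) -> tuple[dict[str, list[str]], list[str]]:
    """Return ``(sets, planted_names)``: block-member sets plus size-matched
    decoys drawn without replacement from non-block proteins."""
    rng = stream(seed, "genesets")
    universe = list(config.protein_universe)
    block_proteins = {m for b in config.blocks for m in b.members}
    pool = [p for p in universe if p not in block_proteins]

    sets: dict[str, list[str]] = {}
    planted: list[str] = []
    sizes: list[int] = []
    for block in config.blocks:
        if len(block.members) < min_set_size:
            continue
        name = f"SET_{block.name}"
        sets[name] = list(block.members)
        planted.append(name)
        sizes.append(len(block.members))
    if not sizes:
        sizes = [10]
    for i in range(n_decoys):
        size = sizes[i % len(sizes)]
        members = rng.choice(len(pool), size=min(size, len(pool)),
                             replace=False)
        sets[f"DECOY_{i + 1:02d}"] = [pool[j] for j in sorted(members)]
    return sets, planted


def simulate_interactions(
    config: SimulationConfig,
    seed: int,
    n_decoy_edges: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return ``(edges, planted_edges)`` score tables; planted edges connect
    members within co-regulated blocks with scores above 0.7."""
    rng = stream(seed, "interactions")
    universe = list(config.protein_universe)
    rows = []
    planted_pairs: set[tuple[str, str]] = set()
    block_members: set[str] = set()
    for block in config.blocks:
        if block.kind not in _COREGULATED_KINDS:
            continue
        block_members.update(block.members)
        for a, b in itertools.combinations(sorted(block.members), 2):
            planted_pairs.add((a, b))
            rows.append({"protein_a": a, "protein_b": b,
                         "score": float(rng.uniform(*PLANTED_EDGE_SCORE))})
    n_added = 0
    while n_added < n_decoy_edges:
        i, j = rng.choice(len(universe), size=2, replace=False)
        a, b = sorted((universe[i], universe[j]))
        if (a, b) in planted_pairs or (a in block_members and b in block_members):
            continue
        rows.append({"protein_a": a, "protein_b": b,
                     "score": float(rng.uniform(*DECOY_EDGE_SCORE))})
        n_added += 1
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])
    planted = edges[[tuple(sorted((r.protein_a, r.protein_b))) in planted_pairs
                     for r in edges.itertuples()]]
    return edges, planted.reset_index(drop=True)
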