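"""Seed-stream derivation.

All randomness in the package flows from one root integer seed. Independent
stages draw from named streams derived via ``numpy.random.SeedSequence`` spawn
keys, so adding a stage or reordering calls never perturbs another stage's
draws, and a fixed root seed reproduces every output byte for byte.
"""

from __future__ import annotations

import numpy as np

# stable stream ids; never renumber, only append
STREAMS = {
    "cohort": 0,
    "proteome": 1,
    "plates": 2,
    "genesets": 3,
    "interactions": 4,
    "imputation": 5,
    "classifier": 6,
    "rfe": 7,
    "gsea": 8,
    "misc": 9,
}


def stream(seed: int, name: str, *subkeys: int) -> np.random.Generator:
    """Return the generator for named stream ``name`` under root ``seed``.

    Extra integer ``subkeys`` create sub-streams (e.g. one per RFE run).
    """
    if name not in STREAMS:
        raise KeyError(f"unknown RNG stream {name!r}; known: {sorted(STREAMS)}")
    key = (STREAMS[name], *subkeys)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def child_seed(seed: int, name: str, *subkeys: int) -> int:
    """A plain integer seed (< 2**31) derived from a named stream."""
    return int(stream(seed, name, *subkeys).integers(0, 2**31 - 1))
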