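"""Seed handling.

All stochastic routines take one integer seed and derive independent
streams from it with :class:`numpy.random.SeedSequence`, so module-level
reruns reproduce exactly what a full pipeline run produced.
"""

from __future__ import annotations

import numpy as np

# Fixed child indices per generator, so e.g. regenerating only the count
# matrix from the same master seed yields the same matrix the pipeline saw.
_STREAMS = {
    "network": 0,
    "factors": 1,
    "counts": 2,
    "fractions": 3,
    "psm": 4,
    "gene_sets": 5,
    "elispot": 6,
    "gsea": 7,
    "misc": 8,
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of a master seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown RNG stream {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[name],))
    return np.random.Generator(np.random.PCG64(ss))
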