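"""Counter-based random streams.

Every stochastic element of a build or a simulation (connection sampling,
synapse placement, Poisson spike generation) draws from a Philox
counter-based generator keyed by a small tuple of integers — typically
``(seed, tag, edge_type_id, source_gid, target_gid)`` or ``(seed, tag,
gid)``.  The draw for any entity is therefore a pure function of the seed
and the entity's identity: results do not depend on iteration order,
chunking, or the number of logical ranks a simulation is partitioned into.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pair_stream", "TAG_EDGE", "TAG_PLACEMENT", "TAG_POISSON"]

# Stream namespaces: keep draws for different purposes statistically
# independent even when the remaining key components coincide.
TAG_EDGE = 1
TAG_PLACEMENT = 2
TAG_POISSON = 3


def pair_stream(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator uniquely determined by ``(seed, *key)``.

    Parameters
    ----------
    seed:
        Global seed (goes into the Philox key).
    *key:
        Up to four non-negative integers identifying the entity
        (tag, type id, gids ...); they form the Philox counter block.
    """
    if len(key) > 4:
        raise ValueError("at most four key components supported")
    counter = np.zeros(4, dtype=np.uint64)
    for i, k in enumerate(key):
        counter[i] = np.uint64(int(k) & 0xFFFFFFFFFFFFFFFF)
    philox = np.random.Philox(
        key=np.array([int(seed) & 0xFFFFFFFFFFFFFFFF, 0], dtype=np.uint64),
        counter=counter,
    )
    return np.random.Generator(philox)
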