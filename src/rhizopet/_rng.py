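"""Counter-based random streams.

Every stochastic stage of the pipeline draws from its own child stream,
derived from the single per-plant integer seed plus a small integer path
(stage, session, frame ...).  Stages can therefore be re-run independently
and in any order without perturbing each other's draws.
"""

from __future__ import annotations

import numpy as np

# stage tags for stream paths
PHANTOM = 0
KINETICS = 1
ACQUISITION = 2


def stream(seed: int, *path: int) -> np.random.Generator:
    """Return an independent Generator for ``(seed, *path)``.

    Uses ``SeedSequence`` spawn keys, so distinct paths give statistically
    independent streams and identical paths give bit-identical ones.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(p) for p in path)))
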