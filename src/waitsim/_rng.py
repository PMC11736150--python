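"""Counter-based random streams.

Every stochastic quantity in the pipeline is drawn from a Philox generator
keyed by a tuple of integers (seed, replicate, week, purpose). Streams are
therefore independent of iteration order and identical across scenarios that
share a seed, which is what makes common-random-number comparisons work.
"""

from __future__ import annotations

import numpy as np

# Purpose tags keep independent uses of the same (seed, replicate) apart.
EVENTS = 0
COHORT = 1
ASSIGN = 2


def generator(*key: int) -> np.random.Generator:
    """Return a Generator keyed deterministically by a tuple of integers."""
    ss = np.random.SeedSequence(entropy=list(key))
    return np.random.Generator(np.random.Philox(ss))


def event_uniforms(seed: int, replicate: int, week: int, n: int) -> np.ndarray:
    """Uniform(0,1) draws of shape (n, 3) for one simulated week.

    Columns: 0 = death trial, 1 = hospitalization trial, 2 = urgent
    conversion trial. Keyed by week so the stream does not depend on how
    many weeks a particular scenario runs.
    """
    return generator(seed, replicate, week, EVENTS).random((n, 3))
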