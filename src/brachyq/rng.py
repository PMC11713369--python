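"""Counter-based random numbers for reproducible Monte Carlo transport.

Every photon history owns an independent stream addressed by
``(seed, history_index, draw_counter)``.  The n-th random number of a
history is a pure function of that triple, so tallies are bit-identical
regardless of vector chunking or execution order, and paired runs that
share a seed consume identical numbers wherever their geometries agree
(common random numbers / correlated sampling).

The generator is a SplitMix64-style avalanche hash applied twice: once to
mix (seed, history) into a stream key, once to mix in the draw counter.
SplitMix64 passes BigCrush and is a standard seeding primitive; it is
amply random for photon transport while being trivially vectorizable
with NumPy uint64 arithmetic.
"""

from __future__ import annotations

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


def _splitmix64(x: np.ndarray) -> np.ndarray:
    # uint64 arithmetic is modular by design; silence overflow chatter
    with np.errstate(over="ignore"):
        x = (np.asarray(x, dtype=np.uint64) + _GOLDEN).astype(np.uint64)
        x = x ^ (x >> _U64(30))
        x = x * _MIX1
        x = x ^ (x >> _U64(27))
        x = x * _MIX2
        x = x ^ (x >> _U64(31))
    return x


class CounterRng:
    """Stateless per-history random stream family for one run seed."""

    def __init__(self, seed: int):
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.seed = int(seed)
        with np.errstate(over="ignore"):
            self._base = _splitmix64(np.asarray(self.seed, dtype=np.uint64) * _GOLDEN)

    def uniform(self, history: np.ndarray, counter: np.ndarray) -> np.ndarray:
        """Uniform(0, 1) double for each (history, counter) pair.

        ``counter`` is the per-history draw index; callers are responsible
        for advancing it after each consumed draw.
        """
        h = np.asarray(history, dtype=np.uint64)
        c = np.asarray(counter, dtype=np.uint64)
        with np.errstate(over="ignore"):
            key = _splitmix64(self._base ^ (h * _MIX1))
            bits = _splitmix64(key + c * _GOLDEN)
        # 53 high bits -> double in [0, 1); offset by half an ulp to avoid 0
        return ((bits >> _U64(11)).astype(np.float64) + 0.5) * _INV_2_53

    def normal(self, history: np.ndarray, counter: np.ndarray) -> np.ndarray:
        """Standard normal via Box-Muller; consumes two counters per value."""
        u1 = self.uniform(history, counter)
        u2 = self.uniform(history, np.asarray(counter, dtype=np.uint64) + _U64(1))
        return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
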