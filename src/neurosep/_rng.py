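"""Named, reproducible RNG substreams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np

# Fixed name -> spawn-key registry so that adding a stream never perturbs the
# draws of existing ones.
_STREAMS = {
    "sources": 0,
    "mixing": 1,
    "noise": 2,
    "counts": 3,
    "trace": 4,
    "cultures": 5,
}


def substream(seed: int | None, name: str) -> np.random.Generator:
    """Generator for the named substream of ``seed``.

    Unregistered names hash (stably) to a spawn key, so ad-hoc streams are
    allowed but the core simulator streams are insulated from each other.
    """
    key = _STREAMS.get(name)
    if key is None:
        key = 64 + zlib.crc32(name.encode())
    if seed is None:
        return np.random.default_rng()
    ss = np.random.SeedSequence(int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def culture_seeds(seed: int, n_cultures: int) -> list[int]:
    """Independent per-culture master seeds (< 2**31) from one run seed."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(_STREAMS["cultures"],))
    return [int(s) for s in ss.generate_state(n_cultures) % (2**31 - 1)]
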