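"""Shared helpers: seeding and millisecond/sample conversions.

All randomness in the package flows through :func:`as_rng`; a single user
seed is fanned out to independent per-component streams with
:func:`child_seed` so that, e.g., paradigm generation and noise synthesis
do not share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["as_rng", "child_seed", "ms_to_sample"]


def as_rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    """Return a numpy Generator from a seed, an existing Generator, or None."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic per-component child seed below 2**31.

    The derivation hashes the component name (CRC32) together with the master
    seed through a SeedSequence, so distinct names give independent streams
    and the same (seed, name) pair always maps to the same child.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def ms_to_sample(ms: float, sampling_rate: float) -> int:
    """Map a millisecond offset to a sample index, truncating toward zero.

    This is the single conversion used everywhere: epoch windows, baseline
    windows and feature intervals all go through it so that boundary
    conventions cannot drift between modules.
    """
    return int(ms * sampling_rate / 1000.0)
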