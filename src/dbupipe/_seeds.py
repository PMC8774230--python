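"""Deterministic derivation of per-stage random seeds from one master seed.

Every stochastic stage of the pipeline draws its randomness from a
``numpy.random.Generator`` created by :func:`stage_rng`.  A stage is
identified by a short string key; the key is hashed with CRC-32 and used as
the ``spawn_key`` of a :class:`numpy.random.SeedSequence` rooted at the
master seed.  Re-running a single stage with the same master seed therefore
reproduces exactly the stream it saw inside a full pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed_sequence", "stage_rng", "stage_int_seed"]


def stage_seed_sequence(master_seed: int, stage: str) -> np.random.SeedSequence:
    """SeedSequence for a named stage, derived from the master seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage."""
    return np.random.default_rng(stage_seed_sequence(master_seed, stage))


def stage_int_seed(master_seed: int, stage: str) -> int:
    """A 31-bit integer seed for libraries that take plain ``random_state`` ints."""
    return int(stage_seed_sequence(master_seed, stage).generate_state(1)[0] % (2**31 - 1))
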