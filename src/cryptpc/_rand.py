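"""Deterministic random-stream splitting.

All stochastic code in the package draws from generators obtained through
:func:`child_rng`, which derives an independent stream from a single integer
seed plus a tuple of string/integer tags.  Because the stream is keyed by the
tags rather than by call order, adding or reordering simulation steps cannot
silently change the random numbers another step sees.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng"]


def child_rng(seed: int, *tags) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a stable tag tuple.

    Tags are converted to bytes and used as the ``spawn_key`` of a
    :class:`numpy.random.SeedSequence`, so ``child_rng(7, "calls", "popA")``
    always yields the same stream regardless of what was drawn before.
    """
    key = tuple(int(b) for tag in tags for b in (str(tag).encode() + b"\x1f"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
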