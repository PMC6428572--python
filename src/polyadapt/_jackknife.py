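"""Delete-one-block jackknife helpers shared across modules.

Blocks are contiguous runs in genomic order.  With ``n`` observations and
``b`` blocks, the first ``n mod b`` blocks hold ``ceil(n / b)`` observations
and the rest ``floor(n / b)``, so remainder observations are absorbed one per
block from the front.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError


def block_offsets(n: int, b: int) -> np.ndarray:
    """Start offsets of the ``b`` contiguous blocks (length ``b + 1`` fence)."""
    if b < 2:
        raise ParameterError("need at least 2 jackknife blocks")
    if n < b:
        raise ParameterError(f"cannot split {n} observations into {b} blocks")
    sizes = np.full(b, n // b, dtype=int)
    sizes[: n % b] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def jackknife_se(loo: np.ndarray) -> tuple[float, float]:
    """Jackknife standard error from delete-one-block estimates.

    Returns ``(se, mean)`` where ``se^2 = (b - 1) / b * sum((loo - mean)^2)``.
    """
    loo = np.asarray(loo, dtype=float)
    b = loo.size
    mean = float(loo.mean())
    var = (b - 1) / b * float(((loo - mean) ** 2).sum())
    return float(np.sqrt(var)), mean


def block_sums(values: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Per-block sums of ``values`` (last axis partitioned by ``offsets``)."""
    return np.add.reduceat(values, offsets[:-1], axis=-1)
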