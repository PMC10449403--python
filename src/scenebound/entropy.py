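"""Shannon entropy over discrete probability vectors.

Both the visual metrics (color-histogram entropy, gist entropy) and the
lexical entropy of pooled description tokens reduce to the same primitive:
``H = -sum_i p_i log2 p_i`` over a normalized histogram, with the usual
convention that ``0 * log2(0) = 0``.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike


class InvalidDistributionError(ValueError):
    """Raised when a vector is not a valid discrete probability distribution."""


def validate_probability_vector(p: ArrayLike, tol: float = 1e-9) -> np.ndarray:
    """Validate and return ``p`` as a 1-D float array summing to 1.

    Parameters
    ----------
    p
        Candidate probability vector (any array-like of non-negative reals).
    tol
        Maximum allowed deviation of ``sum(p)`` from 1.

    Raises
    ------
    InvalidDistributionError
        If any entry is negative or the sum deviates from 1 beyond ``tol``.
    """
    arr = np.asarray(p, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidDistributionError("empty probability vector")
    if np.any(arr < 0):
        raise InvalidDistributionError("probability vector has negative entries")
    total = arr.sum()
    if abs(total - 1.0) > tol:
        raise InvalidDistributionError(
            f"probability vector sums to {total!r}, expected 1 within {tol}"
        )
    return arr


def shannon_entropy(p: ArrayLike, tol: float = 1e-9) -> float:
    """Shannon entropy of a discrete distribution, in bits.

    Zero-probability bins contribute nothing (0 log 0 := 0).  The result
    lies in ``[0, log2(n)]`` for a length-``n`` vector.
    """
    arr = validate_probability_vector(p, tol=tol)
    nz = arr[arr > 0]
    return float(-np.sum(nz * np.log2(nz))) + 0.0  # avoid -0.0


def counts_to_probabilities(counts: ArrayLike) -> np.ndarray:
    """Normalize a non-negative count histogram into a probability vector."""
    arr = np.asarray(counts, dtype=float).ravel()
    if np.any(arr < 0):
        raise InvalidDistributionError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise InvalidDistributionError("counts sum to zero; nothing to normalize")
    return arr / total
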