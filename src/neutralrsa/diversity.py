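"""Hill's effective-species-number diversity indices (orders 1 and 2)."""

from __future__ import annotations

import numpy as np

__all__ = ["frequencies", "hill_1", "hill_2"]


def frequencies(counts) -> np.ndarray:
    """Species frequencies p_i = n_i / sum(n_j) from an abundance vector."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty abundance vector")
    if np.any(arr <= 0):
        raise ValueError("all abundances must be positive")
    return arr / arr.sum()


def _validate(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(arr <= 0):
        raise ValueError("frequencies must be strictly positive")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {arr.sum()!r}")
    return arr


def hill_1(p) -> float:
    """First-order Hill number, exp of the Shannon entropy.

    Ranges from 1 (all individuals in one species) to N (all N species
    equally abundant).
    """
    arr = _validate(p)
    return float(np.exp(-np.sum(arr * np.log(arr))))


def hill_2(p) -> float:
    """Second-order Hill number, the inverse Simpson concentration 1/sum(p_i^2)."""
    arr = _validate(p)
    return float(1.0 / np.sum(arr**2))
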