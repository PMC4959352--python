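"""Empirical relative species abundance: rare-OTU filtering and Preston binning."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceVector",
    "PrestonHistogram",
    "as_abundances",
    "remove_rare",
    "preston_bin",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_histogram_tsv",
    "write_histogram_tsv",
]

#: per-species integer abundances (all entries >= 1)
AbundanceVector = np.ndarray


def as_abundances(counts) -> AbundanceVector:
    """Validate and coerce per-species counts to an integer abundance vector."""
    arr = np.asarray(counts)
    if arr.size == 0:
        return arr.astype(np.int64)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise ValueError("abundances must be integers")
        arr = rounded
    arr = arr.astype(np.int64)
    if np.any(arr < 1):
        raise ValueError("abundances must be positive integers")
    return arr


def remove_rare(abundances, level: int = 1, mode: str = "decrement") -> AbundanceVector:
    """Filter rare OTUs, the standard guard against sequencing artefacts.

    With ``mode="decrement"`` (default) every abundance is reduced by
    ``level`` and species whose count drops to zero or below are removed:
    level 1 removes singletons and turns doubletons into singletons,
    tripletons into doubletons, and so on.  This mirrors removing one read
    per OTU.  With ``mode="drop"`` species with abundance <= level are
    discarded but surviving counts are left untouched.

    ``level=0`` returns the input unchanged.
    """
    if level < 0:
        raise ValueError(f"filter level must be non-negative, got {level}")
    if mode not in ("decrement", "drop"):
        raise ValueError(f"mode must be 'decrement' or 'drop', got {mode!r}")
    arr = as_abundances(abundances)
    if level == 0:
        return arr
    if mode == "decrement":
        out = arr - level
        return out[out > 0]
    return arr[arr > level]


@dataclasses.dataclass(frozen=True)
class PrestonHistogram:
    """Species counts over log2-octave abundance bins.

    Bin ``k`` covers the integer abundances ``[2^k, 2^{k+1})``; e.g. bin 2
    holds the species with 4, 5, 6 or 7 individuals.
    """

    species_count: np.ndarray  # one entry per octave k = 0..K

    def __post_init__(self) -> None:
        counts = np.asarray(self.species_count, dtype=np.int64)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("species_count must be a non-empty 1-d array")
        if np.any(counts < 0):
            raise ValueError("species counts must be non-negative")
        object.__setattr__(self, "species_count", counts)

    @property
    def n_bins(self) -> int:
        return int(self.species_count.size)

    @property
    def bin_index(self) -> np.ndarray:
        return np.arange(self.n_bins)

    @property
    def bin_min(self) -> np.ndarray:
        return 2 ** self.bin_index

    @property
    def bin_max(self) -> np.ndarray:
        """Largest integer abundance in each octave (inclusive)."""
        return 2 ** (self.bin_index + 1) - 1

    @property
    def n_obs_total(self) -> int:
        return int(self.species_count.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": self.bin_index,
                "bin_min": self.bin_min,
                "bin_max": self.bin_max,
                "species_count": self.species_count,
            }
        )


def preston_bin(abundances) -> PrestonHistogram:
    """Bin abundances into log2 octaves: species with n individuals lands in
    bin floor(log2(n)).

    The number of bins is ``floor(log2(max abundance)) + 1`` and the bin
    counts sum to the number of species.
    """
    arr = as_abundances(abundances)
    if arr.size == 0:
        raise ValueError("cannot bin an empty abundance vector")
    # exact integer log2 (floats round 2^k - eps wrongly for large k)
    bins = np.array([int(n).bit_length() - 1 for n in arr])
    counts = np.bincount(bins)
    return PrestonHistogram(species_count=counts)


# --- plain-text interchange -------------------------------------------------

def read_abundance_tsv(path) -> AbundanceVector:
    """Read a two-column (otu_id, count) TSV into an abundance vector."""
    df = pd.read_csv(path, sep="\t")
    col = "count" if "count" in df.columns else df.columns[-1]
    return as_abundances(df[col].to_numpy())


def write_abundance_tsv(abundances, path, ids=None) -> None:
    arr = as_abundances(abundances)
    if ids is None:
        ids = [f"otu{i}" for i in range(arr.size)]
    pd.DataFrame({"otu_id": ids, "count": arr}).to_csv(path, sep="\t", index=False)


def read_histogram_tsv(path) -> PrestonHistogram:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("bin_index")
    counts = np.zeros(int(df["bin_index"].max()) + 1, dtype=np.int64)
    counts[df["bin_index"].to_numpy()] = df["species_count"].to_numpy()
    return PrestonHistogram(species_count=counts)


def write_histogram_tsv(hist: PrestonHistogram, path) -> None:
    hist.to_frame().to_csv(Path(path), sep="\t", index=False)
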