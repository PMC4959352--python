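"""Seeded generators for every input the pipeline consumes.

Three generators live here:

* :func:`sample_truncated_nb` — species abundances drawn i.i.d. from the
  model's stationary Negative Binomial conditioned on n >= 1 (what an
  observed community looks like if the neutral model is exactly true);
* :func:`gillespie_occupancy` — the *dynamical* route to the same law: an
  exact event-driven simulation of the birth–death–influx master equation,
  sampled at fixed time intervals;
* :func:`generate_community_fasta` — 16S-like read communities with planted
  OTU structure (controlled within- and between-OTU divergence), so the
  clustering stage can be tested against a known truth at each similarity
  threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numba
import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .model import BirthDeathParams, nb_pmf
from .rsa import AbundanceVector, as_abundances

__all__ = [
    "SequenceCommunityConfig",
    "sample_truncated_nb",
    "gillespie_occupancy",
    "generate_community_fasta",
    "write_community",
    "write_occupancy_tsv",
]

_TAIL_MASS = 1e-12


def _pmf_table(ratio_bd: float, ratio_Sb: float) -> np.ndarray:
    """Tabulate the stationary pmf over n = 1..n_max with tail mass < 1e-12."""
    x, r = ratio_bd, ratio_Sb
    n_max = 1024
    while True:
        pmf = nb_pmf(np.arange(1, n_max + 1), x, r)
        # the ratio P_{n+1}/P_n = x(n+r)/(n+1) is bounded by rho below
        rho = max(x, x * (n_max + r) / (n_max + 1.0))
        if rho < 1.0 and pmf[-1] * rho / (1.0 - rho) < _TAIL_MASS * pmf.sum():
            return pmf
        if n_max > 100_000_000:
            raise RuntimeError("pmf table would be unreasonably large")
        n_max *= 2


def sample_truncated_nb(
    n_species: int, params: BirthDeathParams, seed: int
) -> AbundanceVector:
    """Draw per-species abundances from the zero-truncated stationary law.

    Inverse-CDF sampling on a tabulated pmf (log-gamma computed, truncated
    where the remaining tail mass falls below 1e-12), which stays unbiased
    even at b/d close to 1.

    Returns ``n_species`` integers, each >= 1.
    """
    if n_species < 1:
        raise ValueError(f"n_species must be >= 1, got {n_species}")
    pmf = _pmf_table(params.ratio_bd, params.ratio_Sb)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    draws = np.searchsorted(cdf, rng.random(n_species), side="left") + 1
    return as_abundances(draws)


@numba.njit(cache=True)
def _gillespie_kernel(b, d, ups, burn_in, n_samples, interval, seed, max_n):  # pragma: no cover
    np.random.seed(seed)
    counts = np.zeros(max_n + 1, dtype=np.int64)
    n = 0
    t = 0.0
    next_sample = burn_in
    collected = 0
    overflow = 0
    while collected < n_samples:
        rate_birth = b * (n + ups)
        rate_death = d * n
        total = rate_birth + rate_death
        t_next = t + np.random.exponential(1.0 / total)
        while next_sample <= t_next and collected < n_samples:
            if n <= max_n:
                counts[n] += 1
            else:
                overflow += 1
            collected += 1
            next_sample += interval
        if np.random.random() * total < rate_birth:
            n += 1
        else:
            n -= 1
        t = t_next
    return counts, overflow


def gillespie_occupancy(
    params: BirthDeathParams,
    burn_in: float,
    n_samples: int,
    sample_interval: float,
    seed: int,
) -> np.ndarray:
    """Empirical occupancy distribution of one species' abundance.

    Simulates the two reactions (birth at rate ``b*(n + S/b)``, death at rate
    ``d*n``) with exact exponential waiting times, starting from n = 0, and
    records the state at fixed time intervals after the burn-in — interval
    sampling avoids the event-frequency bias a per-event tally would have.

    Returns normalised frequencies indexed by abundance n = 0, 1, 2, ...
    """
    if burn_in <= 0 or sample_interval <= 0:
        raise ValueError("burn_in and sample_interval must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mean = params.mean_abundance
    var = mean / (1.0 - params.ratio_bd)
    max_n = int(mean + 40.0 * np.sqrt(var) + 100)
    counts, overflow = _gillespie_kernel(
        params.b,
        params.d,
        params.upsilon,
        float(burn_in),
        int(n_samples),
        float(sample_interval),
        int(seed) % (2**32),
        max_n,
    )
    if overflow:
        raise RuntimeError(f"{overflow} samples exceeded the tally bound {max_n}")
    freqs = counts / counts.sum()
    last = np.nonzero(counts)[0][-1]
    return freqs[: last + 1]


@dataclasses.dataclass(frozen=True)
class SequenceCommunityConfig:
    """Planted-cluster community: abundances plus divergence structure.

    ``otu_divergence`` is the expected pairwise distance between two OTU
    ancestor sequences; ``read_divergence`` the expected per-base distance
    of a read from its OTU ancestor.  Separation of within- from between-OTU
    identity requires read_divergence < otu_divergence.
    """

    abundances: Sequence[int]
    otu_divergence: float
    read_divergence: float
    seq_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundances", as_abundances(self.abundances))
        if not (0.0 <= self.read_divergence < self.otu_divergence <= 1.0):
            raise ValueError(
                "need 0 <= read_divergence < otu_divergence <= 1, got "
                f"read={self.read_divergence}, otu={self.otu_divergence}"
            )
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")

    @property
    def n_otus(self) -> int:
        return int(len(self.abundances))


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_community_fasta(
    config: SequenceCommunityConfig,
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Generate reads with planted OTU structure and the truth assignment.

    One ancestor per OTU is mutated from a common random root with a
    Poisson-distributed substitution count of mean ``seq_length *
    otu_divergence / 2``, so two ancestors sit at expected pairwise
    divergence ~ otu_divergence (no-back-mutation approximation).  Each OTU
    then emits ``abundances[i]`` reads mutated from its ancestor at per-base
    substitution rate ``read_divergence`` (substitutions only; uniform over
    the 3 alternative bases).  Deterministic given ``config.seed``.

    Returns the reads (in OTU order) and a read_id -> otu_id truth table.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    root = rng.integers(0, 4, size=L)
    records: list[SeqRecord] = []
    truth: dict[str, str] = {}
    read_no = 0
    for i, abundance in enumerate(config.abundances):
        otu_id = f"otu{i:04d}"
        ancestor = root.copy()
        n_sub = min(int(rng.poisson(L * config.otu_divergence / 2.0)), L)
        if n_sub:
            pos = rng.choice(L, size=n_sub, replace=False)
            ancestor[pos] = (ancestor[pos] + rng.integers(1, 4, size=n_sub)) % 4
        for _ in range(int(abundance)):
            read = ancestor.copy()
            mask = rng.random(L) < config.read_divergence
            k = int(mask.sum())
            if k:
                read[mask] = (read[mask] + rng.integers(1, 4, size=k)) % 4
            read_id = f"read{read_no:06d}"
            read_no += 1
            records.append(SeqRecord(Seq(_to_str(read)), id=read_id, description=""))
            truth[read_id] = otu_id
    return records, truth


def write_community(records, truth, fasta_path, truth_path) -> None:
    """Write the community as 80-column-wrapped FASTA plus a truth TSV."""
    with open(fasta_path, "w") as handle:
        FastaWriter(handle, wrap=80).write_file(records)
    with open(truth_path, "w") as handle:
        handle.write("read_id\totu_id\n")
        for read_id, otu_id in truth.items():
            handle.write(f"{read_id}\t{otu_id}\n")


def write_occupancy_tsv(freqs: np.ndarray, path) -> None:
    with open(path, "w") as handle:
        handle.write("n\tfrequency\n")
        for n, f in enumerate(freqs):
            handle.write(f"{n}\t{f:.10g}\n")
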