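"""Greedy seed-based OTU clustering at a similarity threshold.

The procedure is order-sensitive and incremental: the first input sequence
becomes the first seed; every later sequence is globally aligned against the
existing seeds and joins the first cluster whose seed it matches at or above
the threshold, otherwise it founds a new cluster.  Identity is the fraction
of alignment columns carrying identical letters — gap columns (terminal ones
included) count against identity.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from .rsa import AbundanceVector

__all__ = [
    "SequenceRecord",
    "ClusterResult",
    "global_identity",
    "greedy_cluster",
    "cluster_abundances",
    "sort_for_clustering",
    "read_fasta",
    "write_cluster_tsv",
]

_ALPHABET = set("ACGT")


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if not set(self.sequence) <= _ALPHABET:
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise ValueError(f"record {self.id!r} has non-ACGT letters: {bad}")


# Needleman–Wunsch, end-to-end; scoring pinned for reproducibility:
# match +1, mismatch -1, gap open -2, gap extend -1 (a length-g gap costs
# 2 + (g-1)).  Terminal gaps are penalised like internal ones.
_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -2.0
_aligner.extend_gap_score = -1.0


def global_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of global-alignment columns with identical letters.

    Both matched mismatching letters and gap columns count as
    non-identical, so identity = identities / (identities + mismatches +
    gap columns).  Among co-optimal alignments the first one reported by
    the aligner is used.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if seq_a == seq_b:
        return 1.0
    alignment = _aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


@dataclasses.dataclass
class ClusterResult:
    """Seeds in creation order, the read -> seed assignment, and the threshold."""

    seeds: list[str]
    assignment: dict[str, str]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.seeds)


def _duplicate_counts(records: Sequence[SequenceRecord]) -> dict[str, int]:
    return Counter(r.sequence for r in records)


def sort_for_clustering(
    records: Sequence[SequenceRecord], keep_input_order: bool = False
) -> list[SequenceRecord]:
    """Order records so the best-supported sequences lead the greedy pass.

    Quality scores are unavailable for synthetic reads, so the default rank
    is: longer sequences first, then sequences with more exact duplicates,
    then lexicographic id — fully deterministic.
    """
    if keep_input_order:
        return list(records)
    dup = _duplicate_counts(records)
    return sorted(records, key=lambda r: (-len(r.sequence), -dup[r.sequence], r.id))


def greedy_cluster(
    records: Sequence[SequenceRecord],
    threshold: float,
    assign: str = "first",
) -> ClusterResult:
    """Cluster pre-ordered records greedily at a similarity threshold.

    ``assign="first"`` (default) joins the earliest-created qualifying seed;
    ``assign="best"`` scans all seeds and joins the highest-identity one
    (earliest seed wins ties).  Empty input yields an empty result.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if assign not in ("first", "best"):
        raise ValueError(f"assign must be 'first' or 'best', got {assign!r}")
    seeds: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for record in records:
        target = None
        if assign == "first":
            for seed in seeds:
                if global_identity(record.sequence, seed.sequence) >= threshold:
                    target = seed
                    break
        else:
            best_identity = -1.0
            for seed in seeds:
                identity = global_identity(record.sequence, seed.sequence)
                if identity >= threshold and identity > best_identity:
                    best_identity = identity
                    target = seed
        if target is None:
            seeds.append(record)
            target = record
        assignment[record.id] = target.id
    return ClusterResult(
        seeds=[s.id for s in seeds], assignment=assignment, threshold=threshold
    )


def cluster_abundances(result: ClusterResult) -> AbundanceVector:
    """Reads per cluster, in seed-creation order; sums to the read count."""
    tally = Counter(result.assignment.values())
    return np.array([tally[seed] for seed in result.seeds], dtype=np.int64)


def read_fasta(path) -> list[SequenceRecord]:
    """Load FASTA into validated records (uppercased; wrapping-insensitive)."""
    return [
        SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_cluster_tsv(result: ClusterResult, out_dir) -> None:
    """Write the assignment (read_id, seed_id) and abundance (otu_id, count) TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"read_id": list(result.assignment), "seed_id": list(result.assignment.values())}
    ).to_csv(out / "assignment.tsv", sep="\t", index=False)
    counts = cluster_abundances(result)
    pd.DataFrame({"otu_id": result.seeds, "count": counts}).to_csv(
        out / "abundance.tsv", sep="\t", index=False
    )
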