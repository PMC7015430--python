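"""Rank over-represented footprint sequences for rRNA depletion probes.

RNase footprinting produces a handful of rRNA fragments that commercial
depletion kits miss; a few such fragments can account for the bulk of a
library.  This module counts exact sequences in trimmed FASTQ files,
keeps those over-represented within each sample, merges sequences that
are exact substrings of one another across samples (the longest sequence
represents the group), and emits a rank-ordered candidate list for probe
design.  Deciding which candidates are actually rRNA is left to the user.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_sequences(path):
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # +
            fh.readline()  # qualities
            yield seq


def overrepresented(
    fastq, min_fraction: float = 0.001, min_len: int = 17
) -> dict[str, int]:
    """Exact-sequence counts for reads over-represented in one library.

    A sequence is retained when count / total_reads >= ``min_fraction``
    (inclusive) and its length is at least ``min_len``.
    """
    counter: Counter = Counter()
    total = 0
    for seq in iter_fastq_sequences(fastq):
        total += 1
        counter[seq] += 1
    if total == 0:
        logger.warning("empty FASTQ: %s", fastq)
        return {}
    return {
        seq: n
        for seq, n in counter.items()
        if len(seq) >= min_len and n / total >= min_fraction
    }


@dataclass
class ProbeCandidate:
    sequence: str
    per_sample_counts: dict[str, int] = field(default_factory=dict)
    rank: int = 0

    @property
    def total_count(self) -> int:
        return sum(self.per_sample_counts.values())

    @property
    def n_samples(self) -> int:
        return len(self.per_sample_counts)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_conserved(
    per_sample_maps: dict[str, dict[str, int]]
) -> list[ProbeCandidate]:
    """Merge sequences conserved across samples into probe candidates.

    Two sequences merge when one is an exact substring of the other; the
    relation is closed transitively and each group is represented by its
    longest member (ties: lexicographically smallest).  Counts accumulate
    per sample, so the result is independent of sample order.
    """
    sequences = sorted({s for m in per_sample_maps.values() for s in m})
    uf = _UnionFind(len(sequences))
    by_index = {s: i for i, s in enumerate(sequences)}
    for i, a in enumerate(sequences):
        for j in range(i + 1, len(sequences)):
            b = sequences[j]
            if a in b or b in a:
                uf.union(i, j)
    groups: dict[int, list[str]] = {}
    for s, i in by_index.items():
        groups.setdefault(uf.find(i), []).append(s)
    candidates = []
    for members in groups.values():
        rep = min(members, key=lambda s: (-len(s), s))
        counts: dict[str, int] = {}
        for sample, mapping in per_sample_maps.items():
            sub = sum(mapping.get(s, 0) for s in members)
            if sub:
                counts[sample] = counts.get(sample, 0) + sub
        candidates.append(ProbeCandidate(rep, counts))
    return candidates


def rank_probes(candidates: list[ProbeCandidate]) -> list[ProbeCandidate]:
    """Order by total count desc, then samples desc, then sequence."""
    ordered = sorted(
        candidates,
        key=lambda c: (-c.total_count, -c.n_samples, c.sequence),
    )
    for rank, cand in enumerate(ordered, start=1):
        cand.rank = rank
    return ordered


def probe_table(candidates: list[ProbeCandidate]) -> pd.DataFrame:
    samples = sorted({s for c in candidates for s in c.per_sample_counts})
    rows = []
    for c in candidates:
        row = {
            "rank": c.rank,
            "sequence": c.sequence,
            "total_count": c.total_count,
            "n_samples": c.n_samples,
        }
        for s in samples:
            row[s] = c.per_sample_counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def design_probes(
    fastq_paths: list,
    min_fraction: float = 0.001,
    min_len: int = 17,
) -> pd.DataFrame:
    """End-to-end: count, merge across samples, rank; returns the table."""
    per_sample = {
        str(path): overrepresented(path, min_fraction, min_len)
        for path in fastq_paths
    }
    return probe_table(rank_probes(merge_conserved(per_sample)))
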