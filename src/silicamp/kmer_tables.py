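"""Phase 2 — tile region reads into a ladder of kMer count tables and denoise.

Short kMers (32-mers) are plentiful but more often shared between organisms;
long kMers are specific but scarce, especially near the trimmed region
boundaries.  The ladder keeps count tables at k = 32, 40, 48, ... up to the
dominant (modal) trimmed-read length, so the extender can escalate to longer
kMers only when the 32-mer table is ambiguous.

Denoising removes kMers attributable to sequencing error: those below a
minimum count, and — at the base k only — those dominated by a much more
abundant Hamming-distance-1 neighbour (the standard kMer-spectrum
error-variant heuristic; the neighbour rule is redundant at larger k once
the 32-mer table is clean, and enumerating neighbours there is costly).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

logger = logging.getLogger(__name__)

DEFAULT_K_MIN = 32
DEFAULT_K_STEP = 8
DEFAULT_MIN_COUNT = 2
DEFAULT_VARIANT_RATIO = 20

_BASES = "ACGT"


def k_values(read_length: int, k_min: int = DEFAULT_K_MIN,
             k_step: int = DEFAULT_K_STEP) -> list[int]:
    """The ladder's k values: k_min, k_min+k_step, ... <= read_length.

    Empty when ``read_length`` < ``k_min`` (100 bp reads give the nine
    values 32..96).
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    return list(range(k_min, read_length + 1, k_step))


@dataclass
class KmerTable:
    """Counts of length-k words tiled from the region reads."""

    k: int
    counts: Counter = field(default_factory=Counter)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def count(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def total(self) -> int:
        return sum(self.counts.values())


def build_table(reads: Iterable[str], k: int) -> KmerTable:
    """Count every N-free k-window of every read (reads shorter than k skip)."""
    counts: Counter = Counter()
    for bases in reads:
        for i in range(len(bases) - k + 1):
            w = bases[i:i + k]
            if "N" not in w:
                counts[w] += 1
    return KmerTable(k, counts)


def _hamming1_neighbours(kmer: str) -> Iterable[str]:
    for i, c in enumerate(kmer):
        for b in _BASES:
            if b != c:
                yield kmer[:i] + b + kmer[i + 1:]


def denoise(table: KmerTable, min_count: int = DEFAULT_MIN_COUNT,
            variant_ratio: int = DEFAULT_VARIANT_RATIO,
            check_variants: bool = True) -> KmerTable:
    """Drop dubious kMers; the result is a subset of the input table.

    A kMer is removed when its count is below ``min_count``, or (with
    ``check_variants``) when some Hamming-distance-1 neighbour present in the
    table is at least ``variant_ratio`` times more abundant — the signature
    of an error variant of an abundant kMer.  A neighbour at less than the
    ratio (e.g. 100 vs 50) leaves both in place, preserving legitimate
    strain variants.  Idempotent: surviving kMers keep their counts, and a
    kMer kept once can only lose potential dominators on a second pass.
    """
    kept: Counter = Counter()
    for kmer, c in table.counts.items():
        if c < min_count:
            continue
        if check_variants:
            threshold = variant_ratio * c
            if any(table.counts.get(nb, 0) >= threshold
                   for nb in _hamming1_neighbours(kmer)):
                continue
        kept[kmer] = c
    return KmerTable(table.k, kept)


@dataclass
class KmerTableLadder:
    """Ordered count tables at strictly increasing k."""

    tables: list[KmerTable]

    def __post_init__(self) -> None:
        ks = [t.k for t in self.tables]
        if ks != sorted(set(ks)):
            raise ValueError(f"ladder k values must strictly increase, got {ks}")

    @property
    def ks(self) -> list[int]:
        return [t.k for t in self.tables]

    @property
    def k_min(self) -> int:
        return self.tables[0].k

    @property
    def k_max(self) -> int:
        return self.tables[-1].k

    def table(self, k: int) -> KmerTable:
        for t in self.tables:
            if t.k == k:
                return t
        raise KeyError(f"no kMer table at k={k} (ladder has {self.ks})")

    def count(self, k: int, kmer: str) -> int:
        return self.table(k).count(kmer)

    def size_report(self) -> list[tuple[int, int, int]]:
        """(k, distinct kMers, total count) per table, for debugging dumps."""
        return [(t.k, len(t), t.total()) for t in self.tables]


def build_ladder(region_reads: Iterable, ks: list[int]) -> KmerTableLadder:
    """Tile the region reads repeatedly for each k of the ladder."""
    reads = [r.bases if hasattr(r, "bases") else str(r) for r in region_reads]
    return KmerTableLadder([build_table(reads, k) for k in ks])


def denoise_ladder(ladder: KmerTableLadder,
                   min_count: int = DEFAULT_MIN_COUNT,
                   variant_ratio: int = DEFAULT_VARIANT_RATIO) -> KmerTableLadder:
    """Denoise every table; the Hamming-1 variant rule applies at k_min only."""
    out = []
    for t in ladder.tables:
        cleaned = denoise(t, min_count=min_count, variant_ratio=variant_ratio,
                          check_variants=(t.k == ladder.k_min))
        logger.debug("denoise k=%d: %d -> %d kMers", t.k, len(t), len(cleaned))
        out.append(cleaned)
    return KmerTableLadder(out)


def modal_read_length(region_reads: Iterable) -> int:
    """Most common trimmed-read length (ties: the longer), 0 when empty."""
    lengths = Counter(len(r) for r in region_reads)
    if not lengths:
        return 0
    top = max(lengths.values())
    return max(L for L, n in lengths.items() if n == top)


def dump_sizes_tsv(ladder: KmerTableLadder, path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tdistinct\ttotal\n")
        for k, d, t in ladder.size_report():
            fh.write(f"{k}\t{d}\t{t}\n")
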