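"""Phase 1 — select the reads that cover the primer-defined region.

An iteratively grown hash set of 32-mers ("inter-primer filter") is seeded
from reads containing a primer site and expanded by repeatedly admitting any
read whose first 32-mer is already in the filter, until no pass adds a new
kMer.  The read pool is then re-scanned against the final filter and the
surviving reads are oriented onto the forward-primer strand, trimmed at the
primer sites, and marked as "starting" when they expose the first bases of
the inter-primer region.

Orientation convention: the assembled amplicon reads
``forward-primer site + region + RC(reverse primer) site`` along the
extension strand.  WGS reads are unstranded, so every read is tested in both
orientations and canonicalised into extension orientation when it matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TySequence

from .seqcore import PrimerPairContext, Sequence, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_K = 32
MAX_GROW_ROUNDS = 100


@dataclass
class InterPrimerFilter:
    """The region-selecting set of k-length words (k = 32 by default)."""

    k: int = DEFAULT_K
    kmers: set[str] = field(default_factory=set)
    rounds: int = 0

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers


@dataclass(frozen=True)
class RegionRead:
    """A retained read, oriented onto the extension strand and primer-trimmed.

    ``bases`` of a starting read begin at the first base after the forward
    primer; a read containing the finishing site keeps the site's bases (the
    extender needs them in kMer space to detect termination) but nothing
    beyond them.
    """

    bases: str
    is_starting: bool
    had_finishing_primer: bool
    source_id: str

    def __len__(self) -> int:
        return len(self.bases)


def _windows(bases: str, k: int) -> Iterable[str]:
    """All N-free k-length windows of ``bases``."""
    for i in range(len(bases) - k + 1):
        w = bases[i:i + k]
        if "N" not in w:
            yield w


def _orient_on_primers(bases: str, ctx: PrimerPairContext):
    """Locate primer sites in either orientation of a read.

    Returns ``(oriented_bases, start_off, end_off)`` for the first
    orientation (forward, then reverse complement) containing the forward
    primer or the finishing site, else ``None``.  ``end_off`` is searched at
    or after the end of the forward-primer match so a site embedded in the
    primer itself cannot shadow the real one.
    """
    start_scan = ctx.start_scanner()
    end_scan = ctx.end_scanner()
    for oriented in (bases, reverse_complement(bases)):
        s = start_scan.find_first(oriented)
        search_from = s + len(ctx.start_site) if s is not None else 0
        e = end_scan.find_first(oriented, search_from)
        if s is not None or e is not None:
            return oriented, s, e
    return None


def _canonical_fragment(bases: str, ctx: PrimerPairContext):
    """Trim an oriented primer-bearing read per the trimming convention.

    Returns ``(fragment, is_starting, had_finishing)`` or ``None`` when the
    read carries no primer site in either orientation.
    """
    located = _orient_on_primers(bases, ctx)
    if located is None:
        return None
    oriented, s, e = located
    if s is not None:
        frag = oriented[s + len(ctx.start_site):]
        if e is not None:
            frag = oriented[s + len(ctx.start_site): e + len(ctx.end_site)]
        return frag, True, e is not None
    frag = oriented[: e + len(ctx.end_site)]
    return frag, False, True


def seed_filter(reads: TySequence[Sequence], ctx: PrimerPairContext,
                k: int = DEFAULT_K) -> tuple[InterPrimerFilter, list[RegionRead]]:
    """Build the initial inter-primer filter from primer-bearing reads.

    Every read containing (in either orientation) the forward primer or the
    finishing site contributes the k-length windows of its in-region portion:
    the bases after the forward primer, or the bases up to and including the
    finishing site.  Returns the filter and the starting reads found.

    An empty filter with no starting reads is the distinct "no primer found"
    signal; the pipeline then emits zero amplicons rather than crashing.
    """
    filt = InterPrimerFilter(k=k)
    starting: list[RegionRead] = []
    for read in reads:
        res = _canonical_fragment(read.bases, ctx)
        if res is None:
            continue
        frag, is_starting, had_end = res
        filt.kmers.update(_windows(frag, k))
        if is_starting:
            starting.append(RegionRead(frag, True, had_end, read.id))
    if not starting and not filt.kmers:
        logger.warning("no read contains a starting primer; empty filter")
    return filt, starting


def grow_filter(reads: TySequence[Sequence], filt: InterPrimerFilter,
                ctx: PrimerPairContext,
                max_rounds: int = MAX_GROW_ROUNDS) -> InterPrimerFilter:
    """Expand the filter to a fixed point.

    Each pass admits any read (in either orientation) whose first k-mer is
    already in the filter; admitted reads contribute all their k-length
    windows, truncated at the finishing site so no kMer past a terminating
    primer enters the filter.  Passes repeat until one adds no new kMer
    (which subsumes "the entire inter-primer region has been covered") or the
    round cap is hit.
    """
    k = filt.k
    end_scan = ctx.end_scanner()

    def truncated(oriented: str) -> str:
        e = end_scan.find_first(oriented)
        return oriented if e is None else oriented[: e + len(ctx.end_site)]

    # precompute both orientations once
    pool = []
    for read in reads:
        if len(read.bases) < k:
            continue
        rc = reverse_complement(read.bases)
        pool.append((read.bases, rc))
    contributed = [False] * len(pool)

    rounds = 0
    while rounds < max_rounds:
        before = len(filt.kmers)
        matched = 0
        for i, (fwd, rc) in enumerate(pool):
            if contributed[i]:
                continue
            for oriented in (fwd, rc):
                first = oriented[:k]
                if "N" not in first and first in filt.kmers:
                    filt.kmers.update(_windows(truncated(oriented), k))
                    contributed[i] = True
                    matched += 1
                    break
        rounds += 1
        added = len(filt.kmers) - before
        logger.debug("filter round %d: %d reads matched, %d kMers added",
                     rounds, matched, added)
        if added == 0:
            break
    else:
        logger.warning("inter-primer filter did not reach a fixed point "
                       "within %d rounds", max_rounds)
    filt.rounds = rounds
    return filt


def select_and_trim(reads: TySequence[Sequence], filt: InterPrimerFilter,
                    ctx: PrimerPairContext) -> list[RegionRead]:
    """Final pass: retain, orient and trim the region-covering reads.

    A read is retained when it carries a primer site (either orientation) or
    when its first k-mer in either orientation is in the filter.  Starting
    reads shorter than k after trimming are kept only if they carry a
    finishing site (they are already complete amplicons).
    """
    k = filt.k
    out: list[RegionRead] = []
    for read in reads:
        res = _canonical_fragment(read.bases, ctx)
        if res is not None:
            frag, is_starting, had_end = res
            if len(frag) < k and not had_end:
                continue
            out.append(RegionRead(frag, is_starting, had_end, read.id))
            continue
        if len(read.bases) < k:
            continue
        for oriented in (read.bases, reverse_complement(read.bases)):
            first = oriented[:k]
            if "N" not in first and first in filt.kmers:
                out.append(RegionRead(oriented, False, False, read.id))
                break
    return out


def build_region_reads(reads: TySequence[Sequence], ctx: PrimerPairContext,
                       k: int = DEFAULT_K) -> tuple[InterPrimerFilter, list[RegionRead]]:
    """Run the full Phase 1: seed, grow to fixed point, select and trim."""
    reads = list(reads)
    filt, _ = seed_filter(reads, ctx, k=k)
    grow_filter(reads, filt, ctx)
    region_reads = select_and_trim(reads, filt, ctx)
    n_start = sum(r.is_starting for r in region_reads)
    logger.info("phase 1: %d kMers in filter after %d rounds; "
                "%d region reads retained (%d starting)",
                len(filt), filt.rounds, len(region_reads), n_start)
    return filt, region_reads
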