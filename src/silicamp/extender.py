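"""Phase 3 — extend each starting read one base at a time to a full amplicon.

Every iteration appends the single base whose terminal kMer is supported by
the WGS-derived tables.  Ambiguity at k = 32 escalates through the ladder of
longer kMers; ambiguity that survives the whole ladder triggers a recursive
lookahead that asks which candidate branches can still reach the finishing
primer.  When several can — the signature of co-occurring strains — one is
drawn at random in proportion to the repetition depth of the terminal
32-mers, so minor strain variants stay represented in the output at roughly
their true abundance instead of being subsumed by the major variant.

Extension stops successfully when the assembled sequence ends in the
finishing-primer site, and is abandoned on a dead end (a coverage gap or
denoised-away support), on a tandem-repeat loop, or at the length cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kmer_tables import KmerTableLadder
from .region_filter import RegionRead
from .seqcore import PrimerPairContext

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class ExtensionConfig:
    """Caps and seeding for the extension loop.

    max_amplicon_length bounds runaway extension (bases, pre-trim);
    lookahead_budget bounds how many further bases a recursive branch may
    explore; max_loop_visits bounds revisits of one terminal 32-mer within a
    single read's extension (tandem-repeat guard).
    """

    max_amplicon_length: int = 5000
    lookahead_budget: int = 500
    max_loop_visits: int = 4
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("max_amplicon_length", "lookahead_budget",
                     "max_loop_visits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DecisionStats:
    """Per-run decision counters, one row per way a next base got chosen."""

    extension_checks: int = 0
    single_choice_at_k: dict[int, int] = field(default_factory=dict)
    single_kmer_choice: int = 0
    looked_downstream: int = 0
    single_good_downstream: int = 0
    chose_in_proportion: int = 0
    chose_longest_downstream: int = 0
    starting_reads: int = 0
    abandoned: int = 0
    fully_extended: int = 0

    def record_single(self, k: int) -> None:
        self.single_choice_at_k[k] = self.single_choice_at_k.get(k, 0) + 1
        self.single_kmer_choice += 1

    def check_invariants(self) -> None:
        assert self.single_kmer_choice == sum(self.single_choice_at_k.values())
        assert self.fully_extended + self.abandoned == self.starting_reads

    def as_rows(self) -> list[tuple[str, int, str]]:
        """(counter, value, percent) rows in the per-run report layout."""
        def pct(n: int, denom: int) -> str:
            return f"{100.0 * n / denom:.1f}%" if denom else ""

        rows: list[tuple[str, int, str]] = [
            ("read extension checks", self.extension_checks, ""),
        ]
        for k in sorted(self.single_choice_at_k):
            n = self.single_choice_at_k[k]
            rows.append((f"single choice at k = {k}", n,
                         pct(n, self.extension_checks)))
        rows += [
            ("single kMer choice", self.single_kmer_choice,
             pct(self.single_kmer_choice, self.extension_checks)),
            ("looked downstream", self.looked_downstream,
             pct(self.looked_downstream, self.extension_checks)),
            ("single good downstream", self.single_good_downstream,
             pct(self.single_good_downstream, self.extension_checks)),
            ("chose in proportion by depth", self.chose_in_proportion,
             pct(self.chose_in_proportion, self.extension_checks)),
            ("chose longest downstream", self.chose_longest_downstream,
             pct(self.chose_longest_downstream, self.extension_checks)),
            ("# of starting reads", self.starting_reads, ""),
            ("# of reads abandoned", self.abandoned,
             pct(self.abandoned, self.starting_reads)),
            ("# of fully extended reads", self.fully_extended,
             pct(self.fully_extended, self.starting_reads)),
        ]
        return rows

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("counter\tvalue\tpercent\n")
            for name, value, pct in self.as_rows():
                fh.write(f"{name}\t{value}\t{pct}\n")


@dataclass(frozen=True)
class ExtensionResult:
    """One starting read's fate.

    ``sequence`` is the inter-primer sequence (finishing site trimmed; the
    forward primer was already trimmed in Phase 1).  ``full_sequence`` keeps
    the terminal site, so its 32-mer support can be audited.  Only
    terminated results are written out.
    """

    sequence: str
    terminated: bool
    bases_added: int
    source_id: str
    full_sequence: str = ""


def viable_extensions(seq: str, ladder: KmerTableLadder, k: int) -> set[str]:
    """Bases b for which seq[-(k-1):] + b is a key of the table at k."""
    table = ladder.table(k)  # raises KeyError when the ladder lacks k
    if len(seq) < k - 1:
        raise ValueError(f"sequence of length {len(seq)} too short for k={k}")
    tail = seq[-(k - 1):]
    return {b for b in _BASES if tail + b in table}


def choose_next_base(seq: str, ladder: KmerTableLadder):
    """Pick the next base from the ladder, escalating k on ambiguity.

    Returns ``(base, ("single", k))`` when some k leaves exactly one
    survivor; ``(frozenset(candidates), "needs_downstream")`` when ambiguity
    survives every usable k; ``(None, "dead_end")`` when nothing is viable
    at k_min.  A base survives escalation only while its terminal kMer
    exists at every checked k; if all candidates vanish at the next k the
    decision falls back to the survivors of the previous one.
    """
    ks = ladder.ks
    k_min = ks[0]
    if len(seq) < k_min - 1:
        return None, "dead_end"
    cands = sorted(viable_extensions(seq, ladder, k_min))
    if not cands:
        return None, "dead_end"
    if len(cands) == 1:
        return cands[0], ("single", k_min)
    for k in ks[1:]:
        if len(seq) < k - 1:
            break
        tail = seq[-(k - 1):]
        table = ladder.table(k)
        surv = [b for b in cands if tail + b in table]
        if len(surv) == 1:
            return surv[0], ("single", k)
        if not surv:
            break
        cands = surv
    return frozenset(cands), "needs_downstream"


def choose_in_proportion(candidates, depths: dict[str, int],
                         rng: np.random.Generator) -> str:
    """Sample a base with probability depth_b / sum(depths).

    ``depths`` are the terminal 32-mer counts of each candidate branch, so
    e.g. depths {A: 90, T: 10} pick A 90% of the time.
    """
    cands = sorted(candidates)
    if not cands:
        raise ValueError("no candidates to choose from")
    if len(cands) == 1:
        return cands[0]
    weights = [depths[b] for b in cands]
    total = float(sum(weights))
    if total <= 0:
        raise ValueError(f"depths must be positive, got {depths}")
    u = rng.random() * total
    acc = 0.0
    for b, w in zip(cands, weights):
        acc += w
        if u < acc:
            return b
    return cands[-1]


def _lookahead(seq: str, budget: int, ladder: KmerTableLadder,
               end_scan, dead_memo: set[str]) -> tuple[bool, int]:
    """Can ``seq`` still reach the finishing site within ``budget`` bases?

    Depth-first recursive exploration mirroring the main loop, without
    proportional sampling (every branch of an ambiguity is tried).  Dead-end
    terminal words are memoised within one starting read's extension to keep
    the recursion bounded.  Returns (reached, bases gained along the deepest
    path explored).
    """
    k_min = ladder.k_min
    gained = 0
    while True:
        if end_scan.matches_at_end(seq):
            return True, gained
        if budget <= 0:
            return False, gained
        key = seq[-(k_min - 1):] if len(seq) >= k_min - 1 else seq
        if key in dead_memo:
            return False, gained
        choice, label = choose_next_base(seq, ladder)
        if label == "dead_end":
            dead_memo.add(key)
            return False, gained
        if label == "needs_downstream":
            best_gain = 0
            for b in sorted(choice):
                reached, g = _lookahead(seq + b, budget - 1, ladder,
                                        end_scan, dead_memo)
                if reached:
                    return True, gained + 1 + g
                best_gain = max(best_gain, 1 + g)
            return False, gained + best_gain
        seq += choice
        budget -= 1
        gained += 1


def extend_read(start: RegionRead, ladder: KmerTableLadder,
                ctx: PrimerPairContext, cfg: ExtensionConfig,
                stats: DecisionStats,
                rng: np.random.Generator) -> ExtensionResult:
    """Extend one starting read until the finishing primer or abandonment."""
    k_min = ladder.k_min
    end_scan = ctx.end_scanner()
    seq = start.bases
    src = start.source_id

    def abandoned() -> ExtensionResult:
        stats.abandoned += 1
        return ExtensionResult("", False, len(seq) - len(start.bases),
                               src, seq)

    # The loop below only ever inspects terminal windows, so vet the read's
    # own kMers up front: an unsupported (error) window anywhere in the
    # starting read would otherwise propagate straight into the output.
    table_min = ladder.table(k_min)
    if len(seq) >= k_min:
        for i in range(len(seq) - k_min + 1):
            if seq[i:i + k_min] not in table_min:
                return abandoned()
    elif not start.had_finishing_primer:
        return abandoned()

    dead_memo: set[str] = set()
    visits: dict[str, int] = {}

    while True:
        if end_scan.matches_at_end(seq):
            stats.fully_extended += 1
            trimmed = seq[:-len(ctx.end_site)]
            return ExtensionResult(trimmed, True,
                                   len(seq) - len(start.bases), src, seq)
        if len(seq) >= cfg.max_amplicon_length:
            return abandoned()
        stats.extension_checks += 1
        choice, label = choose_next_base(seq, ladder)
        if label == "dead_end":
            return abandoned()
        if label == "needs_downstream":
            stats.looked_downstream += 1
            outcomes = {
                b: _lookahead(seq + b, cfg.lookahead_budget, ladder,
                              end_scan, dead_memo)
                for b in sorted(choice)
            }
            good = [b for b in sorted(choice) if outcomes[b][0]]
            tail = seq[-(k_min - 1):]
            depths = {b: ladder.count(k_min, tail + b) for b in sorted(choice)}
            if len(good) == 1:
                stats.single_good_downstream += 1
                base = good[0]
            elif good:
                stats.chose_in_proportion += 1
                base = choose_in_proportion(good, depths, rng)
            else:
                stats.chose_longest_downstream += 1
                best = max(outcomes[b][1] for b in outcomes)
                longest = [b for b in sorted(choice)
                           if outcomes[b][1] == best]
                base = (longest[0] if len(longest) == 1
                        else choose_in_proportion(longest, depths, rng))
        else:
            base = choice
        seq += base
        terminal = seq[-k_min:]
        visits[terminal] = visits.get(terminal, 0) + 1
        if visits[terminal] > cfg.max_loop_visits:
            return abandoned()


def extend_all(starting_reads, ladder: KmerTableLadder,
               ctx: PrimerPairContext,
               cfg: ExtensionConfig | None = None
               ) -> tuple[list[ExtensionResult], DecisionStats]:
    """Extend every starting read in order; deterministic given the seed.

    One RNG drives every proportional draw, consumed in read order, so an
    identical input order and seed reproduce the output byte for byte.
    """
    cfg = cfg or ExtensionConfig()
    stats = DecisionStats()
    rng = np.random.default_rng(cfg.rng_seed)
    results: list[ExtensionResult] = []
    for start in starting_reads:
        stats.starting_reads += 1
        results.append(extend_read(start, ladder, ctx, cfg, stats, rng))
    stats.check_invariants()
    logger.info("phase 3: %d starting reads, %d fully extended, %d abandoned",
                stats.starting_reads, stats.fully_extended, stats.abandoned)
    return results, stats
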