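"""Mock communities with ground truth, a WGS read simulator, and the
precision/recall evaluator.

The generator emulates the situation the assembler faces after the usual
marker-gene pre-filtering of a shotgun dataset: a pool of short unstranded
reads drawn from a community of reference "genes", each gene carrying
conserved primer sites flanking a variable inter-primer region.  The primer
sites are concrete instantiations of the degenerate primers and are shared
by every member, as they would be in a real marker gene; the flanks and
regions are random and screened so no spurious primer site occurs anywhere
in a reference (on either strand).

Evaluation follows the known-community logic: a distinct output sequence is
a true positive when it equals a truth amplicon exactly (optionally at a
97%-identity threshold, the OTU-clustering convention); recall can be
restricted to members whose region is fully covered by the simulated reads,
since no assembler can reconstruct a region with a coverage gap.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TySequence

import numpy as np

from .seqcore import (DegeneratePrimer, IUPAC_SETS, PrimerPairContext,
                      Sequence, reverse_complement, scan_for_primer,
                      write_fasta)

logger = logging.getLogger(__name__)

#: Earth Microbiome Project 16S rRNA V4 primer pair (515F / 806R)
EMP_V4_FORWARD = "GTGYCAGCMGCCGCGGTAA"
EMP_V4_REVERSE = "GGACTACNVGGGTWTCTAAT"

_BASES = "ACGT"


@dataclass(frozen=True)
class CommunityMember:
    """One reference gene: flanks, shared primer sites, variable region."""

    name: str
    flank5: str
    fwd_site: str
    region: str
    end_site: str
    flank3: str
    abundance: float

    @property
    def reference(self) -> str:
        return self.flank5 + self.fwd_site + self.region + self.end_site + self.flank3

    @property
    def truth(self) -> str:
        """The ground-truth amplicon: the inter-primer region, primers excluded."""
        return self.region

    @property
    def region_offset(self) -> int:
        """Offset of the region's first base within the reference."""
        return len(self.flank5) + len(self.fwd_site)


@dataclass
class SyntheticCommunity:
    members: list[CommunityMember]
    read_length: int
    depth: float
    error_rate: float
    rng_seed: int
    forward_primer: str = EMP_V4_FORWARD
    reverse_primer: str = EMP_V4_REVERSE

    @property
    def truth_set(self) -> set[str]:
        return {m.truth for m in self.members}

    def context(self, max_mismatches: int = 0) -> PrimerPairContext:
        return PrimerPairContext.from_strings(
            self.forward_primer, self.reverse_primer, max_mismatches)


def _realize(pattern: str, rng: np.random.Generator) -> str:
    """One concrete ACGT instantiation of a degenerate IUPAC string."""
    out = []
    for c in pattern:
        opts = sorted(IUPAC_SETS[c])
        out.append(opts[rng.integers(len(opts))])
    return "".join(out)


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _identity(a: str, b: str) -> float:
    """Positionwise identity over the shorter length (a cheap screen for
    the divergence constraint; members have near-equal lengths)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    same = sum(x == y for x, y in zip(a, b))
    return same / n


def make_community(n_members: int = 15,
                   region_length: "int | tuple[int, int]" = 250,
                   divergence: float = 10.0,
                   abundances: "str | TySequence[float]" = "uniform",
                   seed: int = 0,
                   read_length: int = 100,
                   depth: float = 30.0,
                   error_rate: float = 0.0,
                   forward_primer: str = EMP_V4_FORWARD,
                   reverse_primer: str = EMP_V4_REVERSE,
                   flank: int = 60) -> SyntheticCommunity:
    """Generate a mock community of primer-flanked reference genes.

    Every member shares one concrete instantiation of each primer site
    (conserved sites, as in a real marker gene); variable regions are random
    and pairwise at most (100 - divergence)% identical.  References are
    regenerated until no spurious (degenerate) primer site occurs anywhere
    on either strand, so primer-bearing reads delimit the region exactly.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if not 0.0 < divergence <= 100.0:
        raise ValueError("divergence must be in (0, 100]")
    rng = np.random.default_rng(seed)
    fwd = DegeneratePrimer(forward_primer, "forward")
    rev = DegeneratePrimer(reverse_primer, "reverse")
    fwd_site = _realize(fwd.seq, rng)
    end_site = reverse_complement(_realize(rev.seq, rng))
    site_patterns = [fwd.seq, reverse_complement(rev.seq)]

    if isinstance(region_length, int):
        lo = hi = region_length
    else:
        lo, hi = region_length
    if isinstance(abundances, str):
        if abundances != "uniform":
            raise ValueError(f"unknown abundance model {abundances!r}")
        abnd = [1.0 / n_members] * n_members
    else:
        abnd = [float(a) for a in abundances]
        if len(abnd) != n_members:
            raise ValueError("abundances length != n_members")
        total = sum(abnd)
        abnd = [a / total for a in abnd]

    max_identity = 1.0 - divergence / 100.0
    members: list[CommunityMember] = []
    regions: list[str] = []
    for i in range(n_members):
        for attempt in range(200):
            L = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            region = _random_bases(L, rng)
            f5 = _random_bases(flank, rng)
            f3 = _random_bases(flank, rng)
            member = CommunityMember(f"member{i:02d}", f5, fwd_site, region,
                                     end_site, f3, abnd[i])
            if any(_identity(region, r) > max_identity for r in regions):
                continue
            # exactly one fwd site and one end site on the forward strand,
            # and nothing spurious on the reverse strand
            ref = member.reference
            fwd_hits = scan_for_primer(ref, {"f": fwd.seq})
            end_hits = scan_for_primer(ref, {"e": reverse_complement(rev.seq)})
            if len(fwd_hits) == 1 and len(end_hits) == 1 and \
                    fwd_hits[0][0] == len(f5) and not _extra_rc_sites(ref, site_patterns):
                members.append(member)
                regions.append(region)
                break
        else:
            raise RuntimeError(
                f"could not satisfy divergence constraint for member {i} "
                f"(divergence={divergence}%)")
    return SyntheticCommunity(members, read_length, depth, error_rate, seed,
                              forward_primer, reverse_primer)


def _extra_rc_sites(reference: str, patterns: list) -> bool:
    """Spurious primer-site patterns on the reverse strand.

    The genuine sites only match the extension-strand patterns in forward
    orientation, so any hit on the reverse strand is spurious (it would make
    a wrong-orientation read look primer-bearing).
    """
    rc = reverse_complement(reference)
    hits = scan_for_primer(rc, {"f": patterns[0], "e": patterns[1]})
    return len(hits) > 0


def make_strain_pair(region_length: int = 250,
                     snps: int = 1,
                     snp_positions: "TySequence[int] | None" = None,
                     abundances: tuple[float, float] = (0.9, 0.1),
                     seed: int = 0,
                     read_length: int = 100,
                     depth: float = 30.0,
                     error_rate: float = 0.0,
                     forward_primer: str = EMP_V4_FORWARD,
                     reverse_primer: str = EMP_V4_REVERSE,
                     flank: int = 60) -> SyntheticCommunity:
    """Two strains sharing primers and flanks, differing by ``snps`` bases.

    ``snp_positions`` pins the differing region positions (0-based);
    otherwise they are drawn at random away from the region edges.
    """
    base = make_community(1, region_length, divergence=1.0,
                          abundances=[1.0], seed=seed,
                          read_length=read_length, depth=depth,
                          error_rate=error_rate,
                          forward_primer=forward_primer,
                          reverse_primer=reverse_primer, flank=flank)
    rng = np.random.default_rng(seed + 101)
    a = base.members[0]
    region = list(a.region)
    if snp_positions is None:
        snp_positions = sorted(
            rng.choice(np.arange(32, len(region) - 32), size=snps,
                       replace=False).tolist())
    for pos in snp_positions:
        alts = [b for b in _BASES if b != region[pos]]
        region[pos] = alts[rng.integers(3)]
    variant = "".join(region)
    members = [
        CommunityMember("strainA", a.flank5, a.fwd_site, a.region,
                        a.end_site, a.flank3, abundances[0]),
        CommunityMember("strainB", a.flank5, a.fwd_site, variant,
                        a.end_site, a.flank3, abundances[1]),
    ]
    total = sum(abundances)
    members = [CommunityMember(m.name, m.flank5, m.fwd_site, m.region,
                               m.end_site, m.flank3, m.abundance / total)
               for m in members]
    return SyntheticCommunity(members, read_length, depth, error_rate, seed,
                              forward_primer, reverse_primer)


def simulate_reads(community: SyntheticCommunity,
                   coverage_gap: "tuple[int, int, int] | None" = None
                   ) -> list[Sequence]:
    """Draw unstranded error-prone reads along each member's reference.

    Member i receives ``depth * abundance_i * n_members`` fold coverage
    (so the community mean per-member coverage equals ``depth``), with read
    start positions uniform and strand random.  Substitution errors are
    i.i.d. at ``error_rate`` per base.  ``coverage_gap = (member_index,
    region_start, width)`` excludes all reads overlapping that window of the
    member's inter-primer region — a deliberately unassemblable member.
    """
    rng = np.random.default_rng(community.rng_seed + 1)
    n = len(community.members)
    rl = community.read_length
    reads: list[Sequence] = []
    for mi, member in enumerate(community.members):
        ref = member.reference
        if len(ref) < rl:
            raise ValueError(
                f"{member.name}: reference ({len(ref)} bp) shorter than "
                f"read length ({rl})")
        member_depth = community.depth * member.abundance * n
        n_reads = int(round(member_depth * len(ref) / rl))
        gap_window = None
        if coverage_gap is not None and coverage_gap[0] == mi:
            gstart = member.region_offset + coverage_gap[1]
            gap_window = (gstart, gstart + coverage_gap[2])
        for j in range(n_reads):
            for _ in range(1000):
                start = int(rng.integers(0, len(ref) - rl + 1))
                if gap_window is None or not (start < gap_window[1]
                                              and start + rl > gap_window[0]):
                    break
            else:
                continue  # window too wide to avoid; drop the read
            bases = ref[start:start + rl]
            if community.error_rate > 0:
                arr = list(bases)
                errs = np.nonzero(rng.random(rl) < community.error_rate)[0]
                for pos in errs:
                    alts = [b for b in _BASES if b != arr[pos]]
                    arr[pos] = alts[rng.integers(3)]
                bases = "".join(arr)
            if rng.integers(2):
                bases = reverse_complement(bases)
            reads.append(Sequence(f"{member.name}_r{j:05d}", bases))
    logger.info("simulated %d reads (%d members, %.0fx mean depth)",
                len(reads), n, community.depth)
    return reads


def uncovered_members(community: SyntheticCommunity,
                      reads: Iterable[Sequence],
                      k: int = 32, min_count: int = 2) -> set[str]:
    """Members with some region 32-mer below ``min_count`` in the read pool.

    Counts windows of ``fwd_site + region + end_site`` over both strands of
    the reads — a necessary-coverage screen mirroring the read-mapping check
    used to exclude unassemblable members from recall.
    """
    counts: Counter = Counter()
    for r in reads:
        for bases in (r.bases, reverse_complement(r.bases)):
            for i in range(len(bases) - k + 1):
                counts[bases[i:i + k]] += 1
    out = set()
    for m in community.members:
        target = m.fwd_site + m.region + m.end_site
        if any(counts[target[i:i + k]] < min_count
               for i in range(len(target) - k + 1)):
            out.add(m.name)
    return out


@dataclass
class EvalReport:
    """Precision/recall of assembled amplicons against the known community."""

    true_positives: int
    false_positives: int
    false_negatives: int
    per_member: dict[str, dict] = field(default_factory=dict)

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return 100.0 * self.true_positives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return 100.0 * self.true_positives / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
            "per_member": self.per_member,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _matches_truth(seq: str, truth: str, min_identity: float | None) -> bool:
    if min_identity is None:
        return seq == truth
    if seq == truth:
        return True
    import edlib
    res = edlib.align(seq, truth, task="distance")
    dist = res["editDistance"]
    return 1.0 - dist / max(len(seq), len(truth)) >= min_identity


def evaluate(outputs: Iterable, community: SyntheticCommunity,
             min_identity: float | None = None,
             exclude_members: Iterable[str] = ()) -> EvalReport:
    """Score distinct output sequences against the truth amplicons.

    A truth is recovered (TP) when some output matches it — exactly by
    default, or at ``min_identity`` (e.g. 0.97, the OTU convention).
    Outputs matching no truth are FPs; unrecovered truths are FNs.
    ``exclude_members`` removes members (e.g. those with engineered
    incomplete coverage) from the FN side, mirroring the exclusion of
    organisms whose region never made it into the read pool.
    """
    excluded = set(exclude_members)
    seqs: list[str] = [o.bases if isinstance(o, Sequence) else str(o)
                       for o in outputs]
    distinct = sorted(set(seqs))
    read_counts = Counter(seqs)

    tp = fn = 0
    matched_outputs: set[str] = set()
    per_member: dict[str, dict] = {}
    for m in community.members:
        hits = [s for s in distinct
                if _matches_truth(s, m.truth, min_identity)]
        found = bool(hits)
        n_reads = sum(read_counts[s] for s in hits)
        per_member[m.name] = {"found": found, "output_reads": n_reads,
                              "excluded": m.name in excluded}
        matched_outputs.update(hits)
        if m.name in excluded:
            continue
        if found:
            tp += 1
        else:
            fn += 1
    fp = len([s for s in distinct if s not in matched_outputs])
    return EvalReport(tp, fp, fn, per_member)


def write_fixture(community: SyntheticCommunity, reads: TySequence[Sequence],
                  outdir) -> dict[str, Path]:
    """Write reads FASTA + truth FASTA + a TSV manifest for a community."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.fasta",
        "truth": outdir / "truth.fasta",
        "manifest": outdir / "manifest.tsv",
    }
    write_fasta(reads, paths["reads"])
    write_fasta([(m.name, m.truth) for m in community.members], paths["truth"])
    with open(paths["manifest"], "w") as fh:
        fh.write("member\tabundance\ttruth_length\n")
        for m in community.members:
            fh.write(f"{m.name}\t{m.abundance:.6f}\t{len(m.truth)}\n")
    return paths
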