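# Methods

## The model

`silicamp` performs targeted assembly by greedy single-base extension over
a kMer spectrum. Its premise is statistical: over a pool of reads drawn
from one genomic locus, the set of distinct 32-mers is an almost-perfect
de-Bruijn-like map of that locus, because random 32-mer collisions between
unrelated sequences are vanishingly rare (4^32 ≈ 1.8·10^19 possible
words). Extension therefore reduces to repeated table lookups, with two
escape hatches for the cases where a single table cannot decide:
escalation to longer kMers (more specific, but scarcer) and recursive
lookahead to the terminating primer (expensive, but rarely needed — on
realistic pools ≥ 96% of decisions resolve at k = 32).

Orientation convention: the assembled amplicon reads, 5'→3' on the
forward-primer strand,

```
[forward primer site F] [inter-primer region] [site rc(R)]
```

where R is the reverse primer as conventionally written (annealing
orientation), so the region's 3' boundary on this strand is R's reverse
complement. WGS reads are unstranded; every read is examined in both
orientations and canonicalised onto this strand. The two "starting primer"
patterns scanned for, F and rc(R), find every primer-bearing read in one
orientation or the other.

## Phase details and the choices behind them

**Region filter (phase 1).** The seed set contains the 32-mers of the
in-region portion of every primer-bearing read: bases after F for
F-bearing reads, bases up to and *including* the rc(R) site for
finish-bearing reads. Growth admits a read when its first 32-mer (either
orientation) is already known, and never admits kMers beyond a finishing
site, so the filter cannot leak past the region's 3' boundary. The
stated stopping condition for growth — the whole region covered and
finishing-primer reads being selected — is not directly observable, so
growth runs to a fixed point (a full pass adding no kMer), which subsumes
it; a 100-round cap guards pathological inputs. Trimming keeps the
finishing site on finish-bearing reads because the extender must be able
to *assemble into* that site in kMer space before it can recognise
termination; the site is removed again from the final output, so emitted
amplicons are primer-free on both ends.

**Table ladder (phase 2).** k runs from `k_min` = 32 in steps of
`k_step` = 8 up to the modal trimmed-read length (nine tables for 100 bp
reads). Reads shorter than a given k simply skip that table. Denoising
applies two rules:

* *min_count* (default 2): kMers seen once are far more likely error than
  signal at any realistic coverage. Pools at 1x coverage (e.g. one
  reference, tiled once) need `--min-count 1`.
* *Hamming-1 dominance* (default ratio 20, k = 32 only): a kMer whose
  count is ≤ 1/20 of some single-substitution neighbour is treated as an
  error variant of that neighbour. Substitution errors occur at well under
  1% per base, so genuine error variants sit at ≪ 1/20 of their source
  kMer's depth and are still removed, while strain variants down to ~10%
  relative abundance are preserved. A tighter ratio of 10 would put the
  removal threshold exactly at the mean depth ratio of a 90 : 10 strain
  mixture, deleting minor-strain kMers on a coin flip — and keeping minor
  strains represented is precisely what the proportional tie-breaker is
  for. The rule is skipped at larger k where neighbour enumeration is
  costly and the 32-mer table has already absorbed the errors.

**Extension (phase 3).** Per appended base: check whether the sequence now
ends in the finishing site (a degenerate-pattern match over the last
|site| bases); otherwise look up the four candidate extensions at k = 32.
One survivor → append. Several → escalate: at each larger usable k
(len(s) ≥ k−1), keep only candidates whose terminal kMer exists there; a
single survivor decides, an empty survivor set falls back to the previous
k's set, and ambiguity after the top of the ladder triggers lookahead.
Lookahead recursively extends each candidate branch (budget 500 bases,
dead-end terminal words memoised per starting read) and classifies the
outcome: exactly one branch reaches a finishing site → take it; several →
draw in proportion to the candidates' terminal 32-mer counts; none → take
the branch that got furthest (ties broken by the same proportional draw).
Upfront, every 32-mer of the starting read itself is validated against the
denoised table — the loop only ever inspects terminal windows, and without
this check an uncorrected error in the middle of a starting read would
pass straight into the output.

Abandonment (counted, never fatal): no viable extension; the same terminal
32-mer visited more than 4 times (tandem-repeat guard); or 5,000 assembled
bases (both configurable). The per-run counters satisfy two conservation
laws by construction: `fully_extended + abandoned = starting_reads`, and
`single_kmer_choice = Σ_k single_choice_at_k`. Lookahead-internal
decisions are deliberately not counted — the report describes the main
extension loop.

**Determinism.** One seeded generator (numpy PCG64) serves all
proportional draws, consumed in starting-read order; identical inputs and
seed give byte-identical output FASTA. Candidate sets are iterated in
alphabetical base order everywhere.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `max_mismatches` | 0 | bases | mismatches tolerated in a primer-site match; degenerate codes already absorb designed variability, and 0 is reproducible |
| `k_min` | 32 | bp | filter word size and base table |
| `k_step` | 8 | bp | ladder spacing |
| `min_count` | 2 | — | denoising floor |
| `variant_ratio` | 20 | — | Hamming-1 dominance ratio |
| `max_amplicon_length` | 5000 | bp | extension cap |
| `lookahead_budget` | 500 | bp | recursion depth per branch |
| `max_loop_visits` | 4 | — | terminal-32-mer revisit cap |
| `rng_seed` | 1 | — | proportional-draw seed |

## The synthetic communities

The generator emulates a *pre-filtered* WGS pool: a community of reference
genes, each `flank + F-site + variable region + rc(R)-site + flank`, with

* one concrete instantiation of each degenerate primer site shared by all
  members (conserved sites, as in a real marker gene);
* random variable regions, pairwise ≤ (100 − divergence)% identical, and
  references screened so no spurious primer-site pattern occurs anywhere
  on either strand;
* unstranded 75–150 bp reads, uniform start positions, member chosen so
  that member i receives `depth · abundance_i · n` fold coverage (mean
  per-member coverage = `depth`); i.i.d. substitution errors at
  `error_rate`; optional read-free windows for coverage-gap experiments.

Default study conditions used by the acceptance script and the heavier
tests: 15 members, 250 bp regions (the 16S V4 scale), 100 bp reads at 30x
depth, error-free, EMP V4 primers — small enough to run end to end in
seconds, deep enough that every 32-mer window is covered ≥ 2x with
overwhelming probability. The two-strain fixture uses abundances 90 : 10
at 500x mean depth (so several hundred starting reads exist for a stable
ratio) and places its single SNP at region position 34: the ambiguous
decision then arises while the assembled sequence is still shorter than
39 bases, where only the 32-mer table is usable, exercising the
downstream/proportional path directly. (With a mid-region SNP,
k-escalation resolves the fork instead — legitimately, but then the draw
under test never happens; at desk-scale depths the minor strain's 88- and
96-mers also hover at the `min_count` floor, which would bias that route.)

What the generator does **not** emulate — hence what passing tests do not
show: indels and quality-correlated errors, GC- and fragment-length bias,
chimeric reads, paired-end structure (mates are treated as independent
reads throughout), real phylogenetic sequence structure (regions are
i.i.d. random, so inter-member kMer sharing is rarer than among real 16S
genes), and primer-site mutations (real organisms can mismatch the
primers; `--mismatches` exists but defaults to 0).

## Evaluation

A distinct output sequence is a true positive when it exactly equals a
member's inter-primer truth; precision = 100·TP/(TP+FP) over distinct
output sequences, recall = 100·TP/(TP+FN) over members. Exact matching is
deliberately stricter than classification-based scoring — the truth is
known here. An optional ≥ 97% identity mode (edit distance via edlib)
mirrors the OTU-clustering convention. Members whose region the read pool
demonstrably fails to cover (some 32-mer of `F-site + region + rc(R)-site`
below `min_count`) can be excluded from the FN side, mirroring how
organisms absent from a read set are excluded from assembler evaluations;
no assembler can reconstruct a gap.

## Known limitations

* Complete read coverage of the region is required; members below roughly
  12x coverage start dropping out in practice — an inherent property of
  assembly, not a recoverable failure.
* Each output originates in a single starting read, so abundances in the
  output are read-level, not organism-level, estimates.
* A repeat longer than the read length inside the region defeats the
  ladder and ends in abandonment via the loop guard.
* The denoiser assumes substitution-dominated errors; heavy indel noise
  (long-read data) would need different rules.
* Primer-site matching at `max_mismatches = 0` misses organisms whose
  binding sites deviate from the degenerate pattern, exactly as the
  corresponding real PCR would.
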