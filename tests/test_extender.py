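"""Phase 3: base choice, k-escalation, lookahead, proportional tie-breaks."""

from collections import Counter

import numpy as np
import pytest

from silicamp.extender import (DecisionStats, ExtensionConfig,
                               choose_in_proportion, choose_next_base,
                               extend_all, extend_read, viable_extensions)
from silicamp.kmer_tables import (KmerTable, KmerTableLadder, build_ladder,
                                  denoise_ladder, k_values,
                                  modal_read_length)
from silicamp.region_filter import RegionRead, build_region_reads
from silicamp.seqcore import PrimerPairContext
from silicamp.synthetic import make_community, simulate_reads


def toy_ladder(*tables):
    """Ladder from {k: {kmer: count}} dicts (tests may use tiny k)."""
    return KmerTableLadder([KmerTable(k, Counter(d)) for k, d in tables])


class TestViableExtensions:
    def test_single_path(self):
        ladder = toy_ladder((4, {"ACGA": 5}))
        assert viable_extensions("TACG", ladder, 4) == {"A"}

    def test_fork(self):
        ladder = toy_ladder((4, {"ACGA": 5, "ACGT": 3}))
        assert viable_extensions("TACG", ladder, 4) == {"A", "T"}

    def test_dead_end(self):
        ladder = toy_ladder((4, {"GGGG": 5}))
        assert viable_extensions("TACG", ladder, 4) == set()

    def test_missing_table_rejected(self):
        ladder = toy_ladder((4, {"ACGA": 5}))
        with pytest.raises(KeyError):
            viable_extensions("TACG", ladder, 6)


class TestChooseNextBase:
    def test_unique_at_k_min(self):
        ladder = toy_ladder((4, {"ACGA": 5}))
        assert choose_next_base("TACG", ladder) == ("A", ("single", 4))

    def test_fork_resolved_by_escalation(self):
        # two references share the 3-mer context; the 6-mer disambiguates
        ladder = toy_ladder((4, {"ACGA": 3, "ACGT": 1}),
                            (6, {"TTACGA": 2}))
        assert choose_next_base("TTACG", ladder) == ("A", ("single", 6))

    def test_escalation_requires_long_enough_sequence(self):
        ladder = toy_ladder((4, {"ACGA": 3, "ACGT": 1}),
                            (6, {"TTACGA": 2}))
        # len(seq) == 4 < 6-1: the k=6 table is unusable, ambiguity stands
        base, label = choose_next_base("TACG", ladder)
        assert label == "needs_downstream" and base == frozenset("AT")

    def test_all_candidates_vanishing_falls_back(self):
        ladder = toy_ladder((4, {"ACGA": 3, "ACGT": 1}), (6, {}))
        base, label = choose_next_base("TTACG", ladder)
        assert label == "needs_downstream" and base == frozenset("AT")

    def test_dead_end(self):
        ladder = toy_ladder((4, {"GGGG": 1}))
        assert choose_next_base("TACG", ladder) == (None, "dead_end")

    def test_persistent_ambiguity_needs_downstream(self):
        ladder = toy_ladder((4, {"ACGA": 3, "ACGT": 1}),
                            (6, {"TTACGA": 2, "TTACGT": 1}))
        base, label = choose_next_base("TTACG", ladder)
        assert label == "needs_downstream" and base == frozenset("AT")


class TestChooseInProportion:
    def test_90_10_frequency(self):
        rng = np.random.default_rng(12345)
        depths = {"A": 90, "T": 10}
        n = 100_000
        hits = sum(choose_in_proportion("AT", depths, rng) == "A"
                   for _ in range(n))
        assert abs(hits / n - 0.9) < 0.01

    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        assert choose_in_proportion("A", {"A": 7}, rng) == "A"

    def test_equal_depths_symmetric(self):
        rng = np.random.default_rng(99)
        n = 20_000
        hits = sum(choose_in_proportion("AT", {"A": 5, "T": 5}, rng) == "A"
                   for _ in range(n))
        assert abs(hits / n - 0.5) < 0.02

    def test_rejects_empty_or_zero(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            choose_in_proportion("", {}, rng)
        with pytest.raises(ValueError):
            choose_in_proportion("AT", {"A": 0, "T": 0}, rng)


def _phase12(com, reads, min_count=2):
    ctx = com.context()
    _, region_reads = build_region_reads(reads, ctx)
    starting = [r for r in region_reads if r.is_starting]
    ladder = build_ladder(region_reads,
                          k_values(modal_read_length(region_reads)))
    return ctx, starting, denoise_ladder(ladder, min_count=min_count)


class TestExtendRead:
    def test_single_reference_recovered_exactly(self):
        com = make_community(1, 250, seed=3, depth=30.0)
        reads = simulate_reads(com)
        ctx, starting, ladder = _phase12(com, reads)
        stats = DecisionStats()
        rng = np.random.default_rng(1)
        cfg = ExtensionConfig()
        res = extend_read(starting[0], ladder, ctx, cfg, stats, rng)
        assert res.terminated
        assert res.sequence == com.members[0].truth

    def test_start_already_containing_finishing_site(self):
        # region shorter than the read: the trimmed starting read is a
        # complete amplicon and terminates without any extension iteration
        com = make_community(1, 50, seed=4, depth=30.0, flank=80)
        reads = simulate_reads(com)
        ctx, starting, ladder = _phase12(com, reads)
        complete = [s for s in starting if s.had_finishing_primer]
        assert complete
        stats = DecisionStats()
        res = extend_read(complete[0], ladder, ctx, ExtensionConfig(),
                          stats, np.random.default_rng(1))
        assert res.terminated and res.bases_added == 0
        assert stats.extension_checks == 0
        assert res.sequence == com.members[0].truth

    def test_coverage_gap_abandons_member(self):
        com = make_community(2, 200, seed=5, depth=25.0)
        reads = simulate_reads(com, coverage_gap=(0, 80, 40))
        ctx, starting, ladder = _phase12(com, reads)
        results, stats = extend_all(starting, ladder, ctx,
                                    ExtensionConfig(rng_seed=1))
        outs = {r.sequence for r in results if r.terminated}
        assert com.members[0].truth not in outs
        assert outs == {com.members[1].truth}
        assert stats.abandoned > 0

    def test_tandem_repeat_loop_guard_abandons(self):
        ctx = PrimerPairContext.from_strings("GGGG", "GGGG")  # end site CCCC
        ladder = toy_ladder((4, {"AAAA": 5}))
        start = RegionRead("AAAA", True, False, "loop")
        stats = DecisionStats()
        res = extend_read(start, ladder, ctx, ExtensionConfig(),
                          stats, np.random.default_rng(1))
        assert not res.terminated
        assert res.bases_added <= ExtensionConfig().max_loop_visits + 1

    def test_unsupported_starting_read_abandoned(self):
        # a starting read whose own windows are absent from the table (an
        # uncorrected error) must not seed an output
        ladder = toy_ladder((4, {"GGGG": 5}))
        ctx = PrimerPairContext.from_strings("GGGG", "GGGG")
        start = RegionRead("ACGTACGT", True, False, "bad")
        stats = DecisionStats()
        res = extend_read(start, ladder, ctx, ExtensionConfig(),
                          stats, np.random.default_rng(1))
        assert not res.terminated
        assert stats.abandoned == 1


class TestExtendAll:
    def test_full_coverage_extends_every_start(self, perfect_run):
        _, _, arts = perfect_run
        stats = arts["stats"]
        assert stats.abandoned == 0
        assert stats.fully_extended == stats.starting_reads > 0

    def test_counter_conservation(self, perfect_run, strain_run):
        for _, _, arts in (perfect_run, strain_run):
            s = arts["stats"]
            assert s.fully_extended + s.abandoned == s.starting_reads
            assert s.single_kmer_choice == sum(s.single_choice_at_k.values())
            assert s.looked_downstream == (s.single_good_downstream +
                                           s.chose_in_proportion +
                                           s.chose_longest_downstream)

    def test_support_invariant(self, perfect_run):
        """Every 32-mer of every assembled sequence (finishing site
        included) exists in the denoised 32-mer table."""
        _, _, arts = perfect_run
        table = arts["ladder"].table(32)
        for r in arts["results"]:
            if not r.terminated:
                continue
            full = r.full_sequence
            assert all(full[i:i + 32] in table
                       for i in range(len(full) - 31))

    def test_deterministic_given_seed(self, strain_run):
        com, _, arts = strain_run
        ctx = arts["ctx"]
        rerun, _ = extend_all(arts["starting"], arts["ladder"], ctx,
                              ExtensionConfig(rng_seed=1))
        assert [r.sequence for r in rerun] == \
            [r.sequence for r in arts["results"]]

    def test_zero_starting_reads(self):
        ladder = toy_ladder((4, {"ACGA": 5}))
        ctx = PrimerPairContext.from_strings("GGGG", "GGGG")
        results, stats = extend_all([], ladder, ctx, ExtensionConfig())
        assert results == [] and stats.starting_reads == 0

    def test_stats_report_rows(self, perfect_run, tmp_path):
        _, _, arts = perfect_run
        path = tmp_path / "stats.tsv"
        arts["stats"].write_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "counter\tvalue\tpercent"
        names = [l.split("\t")[0] for l in lines[1:]]
        assert "read extension checks" in names
        assert "# of fully extended reads" in names
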