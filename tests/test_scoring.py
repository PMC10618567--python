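import numpy as np
import pytest

from conftest import MB, build_profile, random_lesion_plan
from hrdscar.scoring import (
    ScoreParams,
    Segment,
    SegmentProfile,
    arm_event_density,
    normalize_profile,
    score_gi,
    score_loh,
    score_lst,
    score_tai,
)
from hrdscar.simulate import simulate_profile

PARAMS = ScoreParams()


class TestNormalize:
    def test_same_state_neighbours_merge(self):
        prof = SegmentProfile("A", {"1": [Segment(0, 10, 2, 1), Segment(10, 20, 2, 1)]})
        norm = normalize_profile(prof)
        assert norm.segments["1"] == [Segment(0, 20, 2, 1)]

    def test_different_states_stay_separate(self):
        prof = SegmentProfile("A", {"1": [Segment(0, 10, 2, 1), Segment(10, 20, 3, 1)]})
        assert len(normalize_profile(prof).segments["1"]) == 2

    def test_bridge_gap_merges_across_small_gap(self):
        prof = SegmentProfile(
            "A",
            {"1": [Segment(0, 20 * MB, 1, 0), Segment(20 * MB + 1000, 40 * MB, 1, 0)]},
        )
        norm = normalize_profile(prof, bridge_gap_bp=3 * MB)
        assert norm.segments["1"] == [Segment(0, 40 * MB, 1, 0)]

    def test_overlap_rejected(self):
        prof = SegmentProfile("A", {"1": [Segment(0, 10, 2, 1), Segment(5, 20, 2, 1)]})
        with pytest.raises(ValueError, match="overlapping"):
            normalize_profile(prof)


class TestLOH:
    def test_diploid_genome_scores_zero(self, genome, make_profile):
        assert score_loh(make_profile([]), genome, PARAMS) == (0, [])

    def test_interstitial_20mb_counts_once(self, genome, make_profile):
        prof = make_profile([("1", 30 * MB, 50 * MB, 1, 0)])
        n, events = score_loh(prof, genome, PARAMS)
        assert n == 1
        assert (events[0].start, events[0].end) == (30 * MB, 50 * MB)

    def test_exactly_15mb_excluded_by_strict_threshold(self, genome, make_profile):
        assert score_loh(make_profile([("1", 30 * MB, 45 * MB, 1, 0)]), genome, PARAMS)[0] == 0
        # one base-pair-scale increment over the threshold counts
        assert score_loh(make_profile([("1", 30 * MB, int(45.1 * MB), 1, 0)]), genome, PARAMS)[0] == 1

    def test_whole_chromosome_loh_excluded(self, genome, make_profile):
        length = genome.chromosome("5").length
        assert score_loh(make_profile([("5", 0, length, 2, 0)]), genome, PARAMS)[0] == 0

    def test_homozygous_deletion_not_loh(self, genome, make_profile):
        assert score_loh(make_profile([("1", 30 * MB, 50 * MB, 0, 0)]), genome, PARAMS)[0] == 0

    def test_mixed_minor_zero_states_form_one_region(self, genome, make_profile):
        prof = make_profile([("1", 30 * MB, 40 * MB, 1, 0), ("1", 40 * MB, 50 * MB, 2, 0)])
        assert score_loh(prof, genome, PARAMS)[0] == 1


class TestTAI:
    def test_balanced_genome_scores_zero(self, genome, make_profile):
        assert score_tai(make_profile([]), genome, PARAMS)[0] == 0

    def test_telomeric_12mb_gain_counts(self, genome, make_profile):
        n, events = score_tai(make_profile([("1", 0, 12 * MB, 3, 1)]), genome, PARAMS)
        assert n == 1
        assert events[0].arm == "p"

    def test_q_telomere_also_counts(self, genome, make_profile):
        length = genome.chromosome("1").length
        assert score_tai(make_profile([("1", length - 12 * MB, length, 3, 1)]), genome, PARAMS)[0] == 1

    def test_exactly_11mb_excluded(self, genome, make_profile):
        assert score_tai(make_profile([("1", 0, 11 * MB, 3, 1)]), genome, PARAMS)[0] == 0

    def test_interstitial_imbalance_not_tai(self, genome, make_profile):
        assert score_tai(make_profile([("1", 30 * MB, 50 * MB, 3, 1)]), genome, PARAMS)[0] == 0

    def test_centromere_crossing_region_excluded(self, genome, make_profile):
        # telomere-anchored but spans both arms of chr1 (cen 121.5-124.5 Mb)
        assert score_tai(make_profile([("1", 0, 130 * MB, 3, 1)]), genome, PARAMS)[0] == 0


class TestLST:
    def test_uniform_arm_scores_zero(self, genome, make_profile):
        assert score_lst(make_profile([]), genome, PARAMS)[0] == 0

    def test_single_transition_between_large_regions(self, genome, make_profile):
        # p-arm of chr1 = 12 Mb (2,1) then 109.5 Mb (3,1); one qualifying breakpoint
        cen_start = genome.chromosome("1").cen_start
        prof = make_profile([("1", 12 * MB, cen_start, 3, 1)])
        n, events = score_lst(prof, genome, PARAMS)
        assert n == 1
        assert (events[0].arm, events[0].start) == ("p", 12 * MB)

    def test_short_fragment_smoothed_away(self, genome, make_profile):
        # 12 Mb (2,1) | 2 Mb fragment | (3,1) to the centromere: fragment removed,
        # single breakpoint across the 2 Mb gap
        cen_start = genome.chromosome("1").cen_start
        prof = make_profile(
            [("1", 12 * MB, 14 * MB, 4, 2), ("1", 14 * MB, cen_start, 3, 1)]
        )
        assert score_lst(prof, genome, PARAMS)[0] == 1

    def test_gap_wider_than_3mb_disqualifies(self, genome, make_profile):
        # two smoothed 2 Mb fragments leave a 4 Mb gap > max_gap
        cen_start = genome.chromosome("1").cen_start
        prof = make_profile(
            [
                ("1", 12 * MB, 14 * MB, 4, 2),
                ("1", 14 * MB, 16 * MB, 4, 1),
                ("1", 16 * MB, cen_start, 3, 1),
            ]
        )
        assert score_lst(prof, genome, PARAMS)[0] == 0

    def test_flank_of_exactly_10mb_excluded(self, genome, make_profile):
        cen_start = genome.chromosome("1").cen_start
        assert score_lst(make_profile([("1", 0, 10 * MB, 3, 1)]), genome, PARAMS)[0] == 0
        assert score_lst(make_profile([("1", 0, int(10.1 * MB), 3, 1)]), genome, PARAMS)[0] == 1

    def test_nine_plus_twenty_only_counts_the_large_junction(self, genome, make_profile):
        # 9 Mb flank never qualifies; the 20 Mb / remaining-arm junction does
        prof = make_profile([("1", 0, 9 * MB, 3, 1), ("1", 9 * MB, 29 * MB, 4, 1)])
        assert score_lst(prof, genome, PARAMS)[0] == 1

    def test_centromere_is_a_hard_boundary(self, genome, make_profile):
        # state change exactly at the centromere: clipped per arm, no breakpoint
        cm = genome.chromosome("1")
        prof = make_profile([("1", 0, cm.cen_start, 3, 1), ("1", cm.cen_start, cm.length, 2, 1)])
        assert score_lst(prof, genome, PARAMS)[0] == 0


class TestGIScore:
    def test_diploid_genome_is_zero(self, genome, make_profile):
        res = score_gi(make_profile([]), genome, PARAMS)
        assert (res.loh, res.tai, res.lst, res.gi_score) == (0, 0, 0, 0)

    def test_gi_is_component_sum_with_cross_talk(self, genome, make_profile):
        # interstitial deletion LOH also creates two LSTs
        res = score_gi(make_profile([("1", 30 * MB, 50 * MB, 1, 0)]), genome, PARAMS)
        assert (res.loh, res.tai, res.lst) == (1, 0, 2)
        assert res.gi_score == 3

    def test_gi_always_equals_sum_on_random_profiles(self, genome):
        rng = np.random.default_rng(5)
        for _ in range(25):
            prof = simulate_profile(genome, random_lesion_plan(rng), rng)
            res = score_gi(prof, genome, PARAMS)
            assert res.gi_score == res.loh + res.tai + res.lst

    def test_split_and_order_invariance(self, genome):
        rng = np.random.default_rng(17)
        prof = simulate_profile(genome, random_lesion_plan(rng), rng)
        base = score_gi(prof, genome, PARAMS)
        for _ in range(10):
            segments = {}
            for chrom, segs in prof.segments.items():
                pieces = []
                for seg in segs:
                    if seg.length > 2 and rng.random() < 0.6:
                        cut = int(rng.integers(seg.start + 1, seg.end))
                        pieces += [
                            Segment(seg.start, cut, seg.cn_total, seg.cn_minor),
                            Segment(cut, seg.end, seg.cn_total, seg.cn_minor),
                        ]
                    else:
                        pieces.append(seg)
                rng.shuffle(pieces)
                segments[chrom] = pieces
            res = score_gi(SegmentProfile(prof.sample, segments), genome, PARAMS)
            assert (res.loh, res.tai, res.lst) == (base.loh, base.tai, base.lst)


class TestArmDensity:
    def test_empty_cohort_all_zero(self, genome):
        table = arm_event_density([], genome)
        assert int(table.to_numpy().sum()) == 0

    def test_single_17p_loh_event(self, genome, make_profile):
        prof = make_profile([("17", 0, 20 * MB, 2, 0)])
        res = score_gi(prof, genome, PARAMS)
        table = arm_event_density([res], genome)
        assert table.loc["17p", "loh"] == 1
        assert table.loc["17p", "total"] == table.loc["17p", ["loh", "tai", "lst"]].sum()

    def test_totals_match_event_counts(self, genome):
        rng = np.random.default_rng(23)
        results = [
            score_gi(simulate_profile(genome, random_lesion_plan(rng), rng), genome, PARAMS)
            for _ in range(10)
        ]
        table = arm_event_density(results, genome)
        assert table["total"].sum() == sum(len(r.events) for r in results)
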