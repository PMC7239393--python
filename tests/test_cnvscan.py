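"""Depth normalization, segmentation, breakpoints, structure, gene effects."""

import itertools

import numpy as np
import pytest

from stipper.core_io import ClipPile, DepthTrack, GeneModel, GenomicInterval, Sample
from stipper.cnvscan import (
    NormalizedTrack,
    assemble_call,
    classify_gene,
    copy_number,
    detect_breakpoints,
    infer_structure,
    normalize,
    predict_gene_effects,
    segment_track,
)
from stipper.simcohort import (
    SimConfig,
    make_truth,
    simulate_clip_piles,
    simulate_depth,
)

CONTROL = GenomicInterval("s", 1, 5_000)


def _track(values, scaffold="s", window=100, sample="b"):
    return DepthTrack(sample, scaffold, window, np.asarray(values, dtype=float))


class TestNormalize:
    def test_constant_depth_normalizes_to_one(self):
        norm = normalize(_track([30.0] * 100), CONTROL)
        np.testing.assert_allclose(norm.values, 1.0)

    def test_sevenfold_windows_normalize_to_seven(self):
        values = [30.0] * 50 + [210.0] * 20 + [30.0] * 30
        norm = normalize(_track(values), CONTROL)
        np.testing.assert_allclose(norm.values[50:70], 7.0)

    def test_hand_computed_ratios(self):
        values = [10.0, 20.0, 30.0, 40.0, 20.0, 20.0, 25.0, 15.0, 20.0, 60.0]
        norm = normalize(_track(values), GenomicInterval("s", 1, 1000))
        np.testing.assert_allclose(norm.values, np.array(values) / 20.0)

    def test_idempotent_and_control_median_exactly_one(self):
        rng = np.random.default_rng(0)
        track = _track(rng.poisson(30, 200))
        once = normalize(track, CONTROL)
        twice = normalize(once, CONTROL)
        idx = once.windows_overlapping(CONTROL)
        assert float(np.median(once.values[idx])) == 1.0
        np.testing.assert_array_equal(once.values, twice.values)

    def test_uncovered_control_rejected(self):
        with pytest.raises(ValueError, match="uncovered control"):
            normalize(_track([0.0] * 50 + [30.0] * 50), CONTROL)


class TestCopyNumber:
    def _norm(self, values):
        return NormalizedTrack("b", "s", 100, np.asarray(values, float), CONTROL)

    def test_female_median_7_02_rounds_to_7(self):
        track = self._norm([7.02] * 20)
        cn = copy_number(track, Sample("f", "Almond", "female"),
                         GenomicInterval("s", 1, 2000))
        assert cn.total == 7 and cn.per_chromosome == 7

    def test_female_median_13_9_rounds_to_14(self):
        track = self._norm([13.9] * 20)
        cn = copy_number(track, Sample("f", "Almond", "female"),
                         GenomicInterval("s", 1, 2000))
        assert cn.total == 14

    def test_male_non_cnv_region_one_per_chromosome(self):
        track = self._norm([1.0] * 20)
        cn = copy_number(track, Sample("m", "non-Almond", "male"),
                         GenomicInterval("s", 1, 2000))
        assert cn.total == 2 and cn.per_chromosome == 1

    def test_exclusion_mask_drops_spike_windows(self):
        values = [7.0] * 10 + [40.0] * 10 + [7.0] * 10  # repeat-element spike
        track = self._norm(values)
        cn = copy_number(
            track, Sample("f", "Almond", "female"), GenomicInterval("s", 1, 3000),
            exclude=[GenomicInterval("s", 1001, 2000)],
        )
        assert cn.total == 7 and cn.n_windows == 20

    def test_too_few_windows_rejected(self):
        track = self._norm([1.0] * 20)
        with pytest.raises(ValueError, match="windows"):
            copy_number(track, Sample("f", "Almond", "female"),
                        GenomicInterval("s", 1, 300))


class TestSegmentation:
    def test_flat_track_single_segment(self):
        rng = np.random.default_rng(1)
        segs = segment_track(_track(rng.poisson(30, 500) / 30.0))
        assert len(segs) == 1

    def test_noiseless_step_profile_exact_boundaries(self):
        values = [1.0] * 200 + [7.0] * 100 + [14.0] * 150 + [7.0] * 100 + [1.0] * 250
        segs = segment_track(_track(values))
        assert [(s.start, s.end) for s in segs] == [
            (0, 200), (200, 300), (300, 450), (450, 550), (550, 800)
        ]
        assert [s.level for s in segs] == [1.0, 7.0, 14.0, 7.0, 1.0]

    def test_noisy_boundaries_within_two_windows(self, default_cfg, almond_female,
                                                 canonical_truth):
        import math

        cfg = default_cfg
        w = cfg.window
        # midpoint placement rule of the generator
        expected = [
            math.ceil((cfg.outer.start - (w + 1) / 2) / w) + 1,
            math.ceil((cfg.inner.start - (w + 1) / 2) / w) + 1,
            math.ceil((cfg.inner.end + 1 - (w + 1) / 2) / w) + 1,
            math.ceil((cfg.outer.end + 1 - (w + 1) / 2) / w) + 1,
        ]
        worst = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            track = simulate_depth(almond_female, canonical_truth, cfg, rng)
            norm = normalize(track, cfg.control)
            edges = sorted(
                {s.start for s in segment_track(norm)} | {len(norm.values)}
            )
            for e in expected:
                worst = max(worst, min(abs(g - e) for g in edges))
        assert worst <= 2

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            segment_track(_track([1.0] * 5))


class TestBreakpoints:
    def test_threshold_rule(self):
        piles = [ClipPile("s", 100, 5, "left"), ClipPile("s", 300, 2, "right")]
        assert detect_breakpoints(piles, min_support=3) == [100]

    def test_background_only_empty(self):
        piles = [ClipPile("s", p, 1, "left") for p in (10, 50, 90)]
        assert detect_breakpoints(piles) == []

    def test_merge_keeps_max_count_position(self):
        piles = [
            ClipPile("s", 100, 4, "left"),
            ClipPile("s", 103, 9, "left"),
            ClipPile("s", 200, 5, "right"),
        ]
        assert detect_breakpoints(piles, merge_radius=5) == [103, 200]

    def test_simulated_breakpoints_recovered_exactly(self, canonical_truth):
        cfg = SimConfig(seed=0)
        for seed in range(20):
            piles = simulate_clip_piles(
                canonical_truth, cfg, np.random.default_rng(seed)
            )
            got = detect_breakpoints(piles)
            assert set(canonical_truth.breakpoints) <= set(got)


class TestAssembleCall:
    def _segments(self, levels_windows, window=100):
        segs = []
        start = 0
        from stipper.cnvscan import Segment

        for level, n in levels_windows:
            segs.append(Segment("s", window, start, start + n, float(level)))
            start += n
        return segs

    def test_canonical_profile_yields_7_14_call(self):
        segs = self._segments([(1, 200), (7, 100), (14, 150), (7, 100), (1, 250)])
        bps = [20_012, 30_004, 44_990, 54_996]  # near the window edges
        call = assemble_call(segs, bps)
        assert call.outer_cn == 7 and call.inner_cn == 14
        assert call.breakpoints == (20_012, 30_004, 44_990, 54_996)
        assert call.flags == ()

    def test_inner_only_duplication_flagged(self):
        segs = self._segments([(1, 200), (2, 100), (1, 300)])
        call = assemble_call(segs, [])
        assert call.outer_cn == 1 and call.inner_cn == 2
        assert "inner-only" in call.flags

    def test_wild_type_no_call(self):
        segs = self._segments([(1, 500)])
        assert assemble_call(segs, []) is None

    def test_depth_step_without_breakpoint_flagged_depth_only(self):
        segs = self._segments([(1, 200), (7, 100), (14, 150), (7, 100), (1, 250)])
        call = assemble_call(segs, [])
        assert "depth-only" in call.flags

    def test_full_pipeline_recovery_is_reliable(self, default_cfg, almond_female,
                                                canonical_truth):
        cfg = default_cfg
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            track = simulate_depth(almond_female, canonical_truth, cfg, rng)
            segs = segment_track(normalize(track, cfg.control))
            bps = detect_breakpoints(simulate_clip_piles(canonical_truth, cfg, rng))
            call = assemble_call(segs, bps)
            if (
                call is not None
                and call.outer_cn == 7
                and call.inner_cn == 14
                and call.breakpoints == canonical_truth.breakpoints
            ):
                ok += 1
        assert ok >= 95


class TestTandemStructure:
    @pytest.mark.parametrize("o,r", list(itertools.product(range(1, 11), range(1, 5))))
    def test_junction_counts_match_closed_forms(self, o, r):
        # closed forms derived from the arrangement string directly:
        # 1/2 = o, 2/2 = o(r-1), 2/3 = o, 3/1 = o-1
        s = infer_structure(o, o * r)
        assert s.junction_counts == {
            "1/2": o, "2/2": o * (r - 1), "2/3": o, "3/1": o - 1
        }
        assert len(s.arrangement) == o * (r + 2)

    def test_canonical_almond_junctions(self):
        s = infer_structure(7, 14)
        assert s.junction_counts == {"1/2": 7, "2/2": 7, "2/3": 7, "3/1": 6}

    def test_wild_type_has_no_novel_junctions(self):
        s = infer_structure(1, 1)
        assert s.arrangement == ("S1", "S2", "S3")
        assert s.junction_counts["2/2"] == 0 and s.junction_counts["3/1"] == 0

    def test_inner_only_single_extra_repeat(self):
        s = infer_structure(1, 2)
        assert s.junction_counts["2/2"] == 1 and s.junction_counts["3/1"] == 0

    def test_indivisible_configuration_suggests_alternatives(self):
        with pytest.raises(ValueError, match="14 or 21"):
            infer_structure(7, 16)


OUTER = GenomicInterval("z", 10_000, 90_000)
INNER = GenomicInterval("z", 30_000, 60_000)


def _gene(name, start, end, scaffold="z"):
    return GeneModel(name, "+", (GenomicInterval(scaffold, start, end),))


class TestGeneEffects:
    def test_gene_inside_inner_amplified_to_inner_count(self):
        s = infer_structure(7, 14)
        effects = predict_gene_effects(
            s, [_gene("Mlana", 35_000, 40_000)], outer=OUTER, inner=INNER
        )
        assert effects[0].classification == "amplified_full"
        assert effects[0].copies == 14

    def test_gene_spanning_inner_boundary_truncated(self):
        s = infer_structure(7, 14)
        (eff,) = predict_gene_effects(
            s, [_gene("Slc16a13", 55_000, 70_000)], outer=OUTER, inner=INNER
        )
        assert eff.classification == "truncated_at_junction"
        assert eff.detail == {"full_copies": 7, "truncated_copies": 7}

    def test_outer_edge_pair_fused_o_minus_1_times(self):
        s = infer_structure(7, 14)
        effects = predict_gene_effects(
            s,
            [_gene("Ermp1", 80_000, 95_000), _gene("Kiaa2026", 5_000, 15_000)],
            outer=OUTER, inner=INNER,
        )
        for eff in effects:
            assert eff.classification == "fusion_partner"
            assert eff.copies == 6

    def test_wild_type_structure_changes_nothing(self):
        s = infer_structure(1, 1)
        effects = predict_gene_effects(
            s,
            [_gene("Mlana", 35_000, 40_000), _gene("Ermp1", 80_000, 95_000),
             _gene("Ric1", 95_000, 99_000)],
            outer=OUTER, inner=INNER,
        )
        assert {e.classification for e in effects} <= {"amplified_full", "unchanged"}
        assert all(e.copies in (0, 1) or e.classification == "amplified_full"
                   for e in effects)
        # no fusion without a 3/1 junction
        assert "fusion_partner" not in {e.classification for e in effects}

    @pytest.mark.parametrize("o,r", [(1, 1), (2, 1), (3, 2), (7, 2), (10, 4)])
    def test_inside_inner_copies_equal_inner_cn_for_every_structure(self, o, r):
        s = infer_structure(o, o * r)
        (eff,) = predict_gene_effects(
            s, [_gene("g", 35_000, 40_000)], outer=OUTER, inner=INNER
        )
        assert eff.copies == o * r

    def test_gene_on_other_scaffold_is_an_error(self):
        with pytest.raises(ValueError, match="no CNV segment"):
            classify_gene(_gene("g", 1, 100, scaffold="other"), OUTER, INNER)

    def test_classifications(self):
        assert classify_gene(_gene("a", 35_000, 40_000), OUTER, INNER) == "inside_inner"
        assert classify_gene(_gene("b", 15_000, 20_000), OUTER, INNER) == "inside_outer"
        assert classify_gene(_gene("c", 55_000, 70_000), OUTER, INNER) == "spans_inner_boundary"
        assert classify_gene(_gene("d", 5_000, 15_000), OUTER, INNER) == "spans_left_outer"
        assert classify_gene(_gene("e", 85_000, 95_000), OUTER, INNER) == "spans_right_outer"
        assert classify_gene(_gene("f", 95_000, 99_000), OUTER, INNER) == "outside"
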