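import numpy as np
import pandas as pd
import pytest

from clonevo.copynumber import (
    _overlap_union,
    call_focal_events,
    call_large_scale,
    classify_cn,
    correct_segments,
    gene_alteration_fraction,
    match_events_across_regions,
    merge_undo,
    purity_correct,
    segment_track,
)


def make_segments(rows):
    cols = ["chrom", "start", "end", "n_probes", "seg_mean", "seg_sd"]
    return pd.DataFrame(rows, columns=cols)


def make_cn_segments(rows):
    cols = ["chrom", "start", "end", "n_probes", "cn_t"]
    df = pd.DataFrame(rows, columns=cols)
    df["cn_class"] = [classify_cn(c) for c in df["cn_t"]]
    return df


GENES = pd.DataFrame(
    [("chr1", 0, 50_000_000, "GeneA"), ("chr2", 0, 50_000_000, "GeneB")],
    columns=["chrom", "start", "end", "gene"],
)


class TestPurityCorrect:
    def test_zero_log_ratio_is_identity(self):
        for p in (0.2, 0.5, 1.0):
            real, cn_t = purity_correct(0.0, p)
            assert cn_t == 2
            assert real == pytest.approx(2.0)

    def test_pure_sample_doubling(self):
        _, cn_t = purity_correct(1.0, 1.0)
        assert cn_t == 4

    def test_forward_inverse_round_trip(self):
        """Exact inversion of the mixture relation over the full grid."""
        for cn_t_true in range(0, 11):
            for p in np.round(np.arange(0.2, 1.01, 0.1), 1):
                with np.errstate(divide="ignore"):  # CN 0 in a pure sample -> -inf
                    obs = np.log2((p * cn_t_true + (1 - p) * 2) / 2)
                _, cn_t = purity_correct(obs, float(p))
                assert cn_t == cn_t_true

    def test_half_pure_triploid_example(self):
        obs = np.log2(1.25)  # forward value at p=0.5, CN_T=3, CN_N=2
        real, cn_t = purity_correct(obs, 0.5)
        assert cn_t == 3
        assert real == pytest.approx(3.0)

    def test_zero_purity_uninvertible(self):
        with pytest.raises(ValueError):
            purity_correct(0.0, 0.0)


class TestSegmentTrack:
    def test_constant_signal_one_segment_per_chromosome(self, rng):
        probes = pd.DataFrame(
            {
                "chrom": np.repeat(["chr1", "chr2"], 100),
                "pos": np.tile(np.arange(100) * 10_000, 2),
                "log2ratio": rng.normal(0, 0.05, 200),
            }
        )
        segs = segment_track(probes, seed=0)
        assert len(segs) == 2
        assert segs["n_probes"].tolist() == [100, 100]

    def test_single_step_changepoint_matches_least_squares_oracle(self, rng):
        """A unit step at probe 50 is found within +/-2 probes of the
        exhaustive single-changepoint least-squares optimum."""
        x = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(1, 0.1, 50)])
        probes = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(100) * 10_000, "log2ratio": x}
        )
        # exhaustive oracle: minimize total SSE over all single splits
        sses = [
            np.sum((x[:k] - x[:k].mean()) ** 2) + np.sum((x[k:] - x[k:].mean()) ** 2)
            for k in range(1, 100)
        ]
        oracle_k = int(np.argmin(sses)) + 1
        segs = segment_track(probes, seed=1)
        assert len(segs) == 2
        found_k = segs["n_probes"].iloc[0]
        assert abs(found_k - oracle_k) <= 2
        assert abs(found_k - 50) <= 2

    def test_determinism(self, rng):
        x = np.concatenate([rng.normal(0, 0.2, 60), rng.normal(0.8, 0.2, 40)])
        probes = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(100) * 10_000, "log2ratio": x}
        )
        a = segment_track(probes, seed=3)
        b = segment_track(probes, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            segment_track(pd.DataFrame(columns=["chrom", "pos", "log2ratio"]))


class TestMergeUndo:
    def test_near_identical_means_merged(self):
        segs = make_segments(
            [("chr1", 0, 50, 50, 0.00, 0.1), ("chr1", 50, 100, 50, 0.01, 0.1)]
        )
        out = merge_undo(segs)
        assert len(out) == 1
        assert out["n_probes"].iloc[0] == 100

    def test_distinct_means_kept(self):
        segs = make_segments(
            [("chr1", 0, 50, 50, 0.0, 0.05), ("chr1", 50, 100, 50, 1.0, 0.05)]
        )
        assert len(merge_undo(segs)) == 2

    def test_idempotent(self, rng):
        rows = [
            ("chr1", i * 10, (i + 1) * 10, 10, float(m), 0.15)
            for i, m in enumerate(rng.normal(0, 0.5, 8))
        ]
        once = merge_undo(make_segments(rows))
        twice = merge_undo(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_never_merges_across_chromosomes(self):
        segs = make_segments(
            [("chr1", 0, 50, 50, 0.0, 0.1), ("chr2", 0, 50, 50, 0.0, 0.1)]
        )
        assert len(merge_undo(segs)) == 2


class TestCallFocalEvents:
    def test_qualifying_homozygous_deletion(self):
        segs = make_cn_segments([("chr2", 1_000_000, 4_000_000, 7, 0)])
        out = call_focal_events(segs, GENES)
        assert len(out) == 1
        assert out["class"].iloc[0] == "HD"
        assert out["genes"].iloc[0] == "GeneB"

    def test_cn4_gain_is_not_focal(self):
        segs = make_cn_segments([("chr1", 0, 1_000_000, 10, 4)])
        assert len(call_focal_events(segs, GENES)) == 0

    @pytest.mark.parametrize(
        "gap,n_expected", [(80_000, 1), (120_000, 2), (100_000, 2)]
    )
    def test_hundred_kb_merge_rule(self, gap, n_expected):
        segs = make_cn_segments(
            [
                ("chr1", 0, 1_000_000, 6, 0),
                ("chr1", 1_000_000 + gap, 2_000_000 + gap, 6, 0),
            ]
        )
        assert len(call_focal_events(segs, GENES)) == n_expected

    def test_filters_size_probes_autosome_genes(self):
        segs = make_cn_segments(
            [
                ("chr1", 0, 4_000_000, 10, 0),       # too large (not < 4 Mb)
                ("chr1", 0, 1_000_000, 4, 0),        # too few probes
                ("chrX", 0, 1_000_000, 10, 0),       # sex chromosome
                ("chr3", 0, 1_000_000, 10, 0),       # no gene overlap
                ("chr1", 5_000_000, 6_000_000, 10, 8),  # qualifying Amp
            ]
        )
        out = call_focal_events(segs, GENES)
        assert len(out) == 1
        assert out["class"].iloc[0] == "Amp"

    def test_order_invariance(self, rng):
        rows = [
            ("chr1", 0, 1_000_000, 6, 0),
            ("chr2", 0, 500_000, 6, 7),
            ("chr1", 2_000_000, 2_500_000, 6, 0),
        ]
        segs = make_cn_segments(rows)
        shuffled = segs.sample(frac=1, random_state=1).reset_index(drop=True)
        a = call_focal_events(segs, GENES).reset_index(drop=True)
        b = call_focal_events(shuffled, GENES).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestMatchEventsAcrossRegions:
    @staticmethod
    def events(*rows):
        return pd.DataFrame(rows, columns=["class", "chrom", "start", "end"])

    def test_exact_half_overlap_union_is_same_event(self):
        assert _overlap_union(0, 1_000_000, 400_000, 1_200_000) == pytest.approx(0.5)
        out = match_events_across_regions(
            {
                "T1": self.events(("HD", "chr1", 0, 1_000_000)),
                "T2": self.events(("HD", "chr1", 400_000, 1_200_000)),
            }
        )
        assert out["event_id"].nunique() == 1
        assert set(out["status"]) == {"ubiquitous"}

    def test_below_half_distinct(self):
        out = match_events_across_regions(
            {
                "T1": self.events(("HD", "chr1", 0, 1_000_000)),
                "T2": self.events(("HD", "chr1", 510_000, 1_510_000)),
            }
        )
        assert out["event_id"].nunique() == 2
        assert set(out["status"]) == {"private"}

    def test_class_mismatch_never_matches(self):
        out = match_events_across_regions(
            {
                "T1": self.events(("HD", "chr1", 0, 1_000_000)),
                "T2": self.events(("Amp", "chr1", 0, 1_000_000)),
            }
        )
        assert out["event_id"].nunique() == 2

    def test_partial_sharing_status(self):
        out = match_events_across_regions(
            {
                "T1": self.events(("HD", "chr1", 0, 1_000_000)),
                "T2": self.events(("HD", "chr1", 0, 1_000_000)),
                "T3": self.events(),
            }
        )
        assert set(out["status"]) == {"partially_shared"}


class TestCallLargeScale:
    def test_sixty_percent_gain_called(self):
        segs = make_cn_segments(
            [("chr1", 0, 60_000_000, 100, 3), ("chr1", 60_000_000, 100_000_000, 60, 2)]
        )
        out = call_large_scale(segs)
        assert out.loc[out["chrom"] == "chr1", "call"].iloc[0] == "gain"

    def test_forty_nine_percent_not_called(self):
        segs = make_cn_segments(
            [("chr1", 0, 49_000_000, 100, 1), ("chr1", 49_000_000, 100_000_000, 60, 2)]
        )
        assert call_large_scale(segs)["call"].iloc[0] == "none"

    def test_neutral_chromosome_not_called(self):
        segs = make_cn_segments([("chr1", 0, 100_000_000, 100, 2)])
        assert call_large_scale(segs)["call"].iloc[0] == "none"

    def test_cumulative_same_direction_segments(self):
        segs = make_cn_segments(
            [
                ("chr1", 0, 30_000_000, 50, 1),
                ("chr1", 30_000_000, 70_000_000, 50, 2),
                ("chr1", 70_000_000, 100_000_000, 50, 1),
            ]
        )
        assert call_large_scale(segs)["call"].iloc[0] == "loss"


class TestGeneAlterationFraction:
    def test_all_neutral_is_zero(self):
        segs = make_cn_segments([("chr1", 0, 50_000_000, 100, 2)])
        assert gene_alteration_fraction(segs, GENES) == 0.0

    def test_half_of_genes_altered(self):
        segs = make_cn_segments(
            [("chr1", 0, 50_000_000, 100, 3), ("chr2", 0, 50_000_000, 100, 2)]
        )
        assert gene_alteration_fraction(segs, GENES) == pytest.approx(0.5)

    def test_matches_hand_count_on_mixed_fixture(self):
        """20 tiled genes against a per-gene interval-intersection oracle."""
        genes = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(20) * 1_000_000,
                "end": np.arange(20) * 1_000_000 + 500_000,
                "gene": [f"G{i}" for i in range(20)],
            }
        )
        segs = make_cn_segments(
            [
                ("chr1", 0, 5_250_000, 100, 3),    # covers G0..G5 starts
                ("chr1", 5_250_000, 12_000_000, 100, 2),
                ("chr1", 12_000_000, 20_000_000, 100, 1),  # G12..G19
            ]
        )
        hand_count = 0
        for g in genes.itertuples(index=False):
            for s in segs.itertuples(index=False):
                if s.cn_t != 2 and s.start < g.end and s.end > g.start:
                    hand_count += 1
                    break
        assert gene_alteration_fraction(segs, genes) == pytest.approx(hand_count / 20)
        assert hand_count == 14  # G0-G5 gained, G12-G19 lost


def test_correct_segments_classifies(small_genome):
    segs = make_segments(
        [("chr1", 0, 100, 100, float(np.log2((0.5 * c + 1) / 2)), 0.0) for c in range(7)]
    )
    out = correct_segments(segs, p=0.5)
    assert out["cn_t"].tolist() == list(range(7))
    assert out["cn_class"].tolist() == [
        "HD", "loss", "neutral", "gain", "gain", "Amp", "Amp",
    ]
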