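import numpy as np
import pytest

from editome import filters
from editome.model import MethodCall, PipelineConfig, SiteKey


def call(chrom, pos, strand="+", sample="S01", method="RED-ML", level=0.3):
    return MethodCall(
        key=SiteKey(chrom, pos, strand),
        sample_id=sample,
        method_id=method,
        editing_level=level,
        coverage=20,
    )


class TestVariantFilter:
    def test_position_match_removes_regardless_of_strand(self):
        calls = [call("chr1", 100, "+"), call("chr1", 100, "-"), call("chr1", 101)]
        passing, removed = filters.filter_variants(calls, frozenset({("chr1", 100)}))
        assert {c.key.pos for c in removed} == {100} and len(removed) == 2
        assert [c.key.pos for c in passing] == [101]

    def test_empty_variant_set_keeps_everything(self):
        calls = [call("chr1", 100)]
        passing, removed = filters.filter_variants(calls, frozenset())
        assert passing == calls and removed == []

    def test_partition_matches_exhaustive_membership_scan(self):
        rng = np.random.default_rng(11)
        calls = [
            call("chr1", int(p), "+" if s else "-")
            for p, s in zip(rng.integers(1, 500, 1000), rng.integers(0, 2, 1000))
        ]
        variants = frozenset(
            ("chr1", int(p)) for p in rng.integers(1, 500, 100)
        )
        passing, removed = filters.filter_variants(calls, variants)
        for c in calls:
            expect_removed = any(v == (c.key.chrom, c.key.pos) for v in variants)
            assert (c in removed) == expect_removed
            assert (c in passing) != expect_removed


class TestRepeatFilter:
    def test_call_inside_alu_removed_and_counted(self):
        index = filters.build_repeat_index([("chr1", 100, 200, "AluY")])
        passing, removed, alu_fraction = filters.filter_repeats(
            [call("chr1", 150), call("chr1", 250)], index
        )
        assert [c.key.pos for c in removed] == [150]
        assert [c.key.pos for c in passing] == [250]
        assert alu_fraction == 1.0

    def test_half_open_end_coordinate_is_outside(self):
        # interval [100, 200) covers 1-based positions 101..200; 201 is out
        index = filters.build_repeat_index([("chr1", 100, 200, "L1")])
        passing, removed, _ = filters.filter_repeats(
            [call("chr1", 200), call("chr1", 201)], index
        )
        assert [c.key.pos for c in removed] == [200]
        assert [c.key.pos for c in passing] == [201]

    def test_matches_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(7)
        intervals = []
        for _ in range(60):
            start = int(rng.integers(0, 900))
            intervals.append(
                ("chr1", start, start + int(rng.integers(1, 60)),
                 "AluY" if rng.random() < 0.5 else "L1")
            )
        calls = [call("chr1", int(p)) for p in rng.integers(1, 1000, 1000)]
        index = filters.build_repeat_index(intervals)
        passing, removed, alu_fraction = filters.filter_repeats(calls, index)
        removed_set = {id(c) for c in removed}
        n_alu = 0
        for c in calls:
            pos0 = c.key.pos - 1
            hits = [iv for iv in intervals if iv[1] <= pos0 < iv[2]]
            assert (id(c) in removed_set) == bool(hits)
            if hits and any(iv[3].startswith("Alu") for iv in hits):
                n_alu += 1
        assert alu_fraction == pytest.approx(n_alu / len(removed))


class TestMappabilityFilter:
    def test_unique_and_high_window_mean_is_kept(self):
        config = PipelineConfig()
        map100 = {"chr1": np.ones(1000)}
        map24 = {"chr1": np.full(1000, 0.6)}
        passing, removed = filters.filter_mappability(
            [call("chr1", 500)], map100, map24, config
        )
        assert len(passing) == 1 and not removed

    def test_window_mean_exactly_at_threshold_is_removed(self):
        config = PipelineConfig()
        map100 = {"chr1": np.ones(1000)}
        map24 = {"chr1": np.full(1000, 0.5)}  # strict inequality
        passing, removed = filters.filter_mappability(
            [call("chr1", 500)], map100, map24, config
        )
        assert not passing and len(removed) == 1

    def test_missing_contig_removes_site(self):
        config = PipelineConfig()
        passing, removed = filters.filter_mappability(
            [call("chrZ", 10)], {}, {}, config
        )
        assert not passing and len(removed) == 1

    def test_clipped_window_matches_per_position_mean_oracle(self):
        # site 50 bp from the contig start: out-of-contig slots contribute 0
        config = PipelineConfig()
        n = 400
        map24 = {"chr1": np.ones(n)}
        map100 = {"chr1": np.ones(n)}
        decision = filters.filter_mappability([call("chr1", 50)], map100, map24, config)
        pos0 = 49
        window = [
            map24["chr1"][i] if 0 <= i < n else 0.0
            for i in range(pos0 - 150, pos0 + 151)
        ]
        expected_keep = (sum(window) / 301) > 0.5
        assert bool(decision[0]) == expected_keep
        # 200/301 ~ 0.66 > 0.5, so the clipped site is kept here
        assert expected_keep

    def test_random_sites_match_brute_force_window_mean(self):
        rng = np.random.default_rng(3)
        config = PipelineConfig()
        n = 2000
        track24 = rng.random(n)
        track100 = (rng.random(n) < 0.8).astype(float)
        map24 = {"chr1": track24}
        map100 = {"chr1": track100}
        calls = [call("chr1", int(p)) for p in rng.integers(1, n + 1, 1000)]
        passing, removed = filters.filter_mappability(calls, map100, map24, config)
        passing_ids = {id(c) for c in passing}
        for c in calls:
            pos0 = c.key.pos - 1
            mean = (
                sum(track24[i] for i in range(max(0, pos0 - 150), min(n, pos0 + 151)))
                / 301
            )
            expected = track100[pos0] >= 1 - 1e-9 and mean > 0.5
            assert (id(c) in passing_ids) == expected


class TestFilterChain:
    def build_inputs(self):
        rng = np.random.default_rng(21)
        calls = [call("chr1", int(p)) for p in rng.integers(1, 1000, 300)]
        variants = frozenset(("chr1", int(p)) for p in rng.integers(1, 1000, 30))
        index = filters.build_repeat_index(
            [("chr1", int(s), int(s) + 40, "AluY") for s in rng.integers(0, 950, 12)]
        )
        map100 = {"chr1": (rng.random(1000) < 0.9).astype(float)}
        map24 = {"chr1": rng.random(1000)}
        return calls, variants, index, map100, map24

    def test_report_tallies_are_conserved(self):
        calls, variants, index, map100, map24 = self.build_inputs()
        config = PipelineConfig()
        passing, report = filters.apply_filters(
            calls, variants, index, map100, map24, config
        )
        assert report.n_input == len(calls)
        assert (
            report.n_removed_variant
            + report.n_removed_repeat
            + report.n_removed_mappability
            + report.n_pass
            == report.n_input
        )
        assert report.n_pass == len(passing)

    def test_each_filter_is_idempotent_on_its_passing_set(self):
        calls, variants, index, map100, map24 = self.build_inputs()
        config = PipelineConfig()
        p1, _ = filters.filter_variants(calls, variants)
        assert filters.filter_variants(p1, variants)[0] == p1
        p2, _, _ = filters.filter_repeats(p1, index)
        assert filters.filter_repeats(p2, index)[0] == p2
        p3, _ = filters.filter_mappability(p2, map100, map24, config)
        assert filters.filter_mappability(p3, map100, map24, config)[0] == p3
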