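import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from editome import consensus
from editome.model import (
    ContractViolation,
    MethodCall,
    PipelineConfig,
    SiteKey,
)
from conftest import make_site


def call(pos, sample, method, level, chrom="chr1", strand="+"):
    return MethodCall(
        key=SiteKey(chrom, pos, strand),
        sample_id=sample,
        method_id=method,
        editing_level=level,
        coverage=10,
    )


class TestAggregateSampleLevel:
    @pytest.mark.parametrize(
        "levels,expected",
        [
            ([0.2, 0.4], 0.3),
            ([0.7], 0.7),
            ([0.1, 0.2, 0.6], 0.3),
        ],
    )
    def test_mean_of_per_method_levels(self, levels, expected):
        assert consensus.aggregate_sample_level(levels) == pytest.approx(expected)

    def test_empty_input_is_a_contract_violation(self):
        with pytest.raises(ContractViolation):
            consensus.aggregate_sample_level([])


class TestBuildConsensus:
    def test_cross_sample_method_union(self):
        # found by RED-ML at 0.1 in one sample and SPRINT at 0.3 in another:
        # counts as detected by both methods
        sites = consensus.build_consensus(
            [call(100, "A", "RED-ML", 0.1), call(100, "B", "SPRINT", 0.3)]
        )
        assert len(sites) == 1
        site = sites[0]
        assert site.methods == {"RED-ML", "SPRINT"}
        assert site.n_samples == 2
        assert site.max_level == pytest.approx(0.3)

    def test_two_methods_in_one_sample_average(self):
        sites = consensus.build_consensus(
            [call(100, "A", "RED-ML", 0.2), call(100, "A", "SPRINT", 0.4)]
        )
        assert sites[0].n_samples == 1
        assert sites[0].max_level == pytest.approx(0.3)

    def test_duplicate_observation_raises(self):
        with pytest.raises(ContractViolation, match="duplicate"):
            consensus.build_consensus(
                [call(100, "A", "RED-ML", 0.2), call(100, "A", "RED-ML", 0.3)]
            )

    def test_matches_naive_group_by_oracle(self):
        rng = np.random.default_rng(5)
        samples = [f"S{i}" for i in range(6)]
        methods = ["REDItools", "RED-ML", "SPRINT"]
        seen = set()
        calls = []
        while len(calls) < 1000:
            pos = int(rng.integers(1, 200))
            strand = "+" if rng.random() < 0.5 else "-"
            sample = samples[int(rng.integers(0, len(samples)))]
            method = methods[int(rng.integers(0, len(methods)))]
            if (pos, strand, sample, method) in seen:
                continue
            seen.add((pos, strand, sample, method))
            calls.append(call(pos, sample, method, float(rng.random()), strand=strand))

        sites = {s.key: s for s in consensus.build_consensus(calls)}

        # independent route: pandas group-by
        df = pd.DataFrame(
            {
                "pos": [c.key.pos for c in calls],
                "strand": [c.key.strand for c in calls],
                "sample": [c.sample_id for c in calls],
                "method": [c.method_id for c in calls],
                "level": [c.editing_level for c in calls],
            }
        )
        per_sample = df.groupby(["pos", "strand", "sample"]).agg(
            level=("level", "mean"), methods=("method", lambda m: frozenset(m))
        )
        per_site = per_sample.groupby(["pos", "strand"]).agg(
            max_level=("level", "max"),
            n_samples=("level", "size"),
            methods=("methods", lambda sets: frozenset().union(*sets)),
        )
        assert len(sites) == len(per_site)
        for (pos, strand), row in per_site.iterrows():
            site = sites[SiteKey("chr1", pos, strand)]
            assert site.n_samples == row.n_samples
            assert site.methods_all == row.methods
            assert site.max_level == pytest.approx(row.max_level)


class TestReproducibilityThresholds:
    def test_level_exactly_at_threshold_is_excluded(self):
        retained, rejected = consensus.apply_reproducibility_thresholds(
            [make_site(1, {"RED-ML"}, n_samples=3, level=0.2)], PipelineConfig()
        )
        assert not retained and len(rejected) == 1

    def test_singleton_sample_is_excluded_despite_high_level(self):
        retained, rejected = consensus.apply_reproducibility_thresholds(
            [make_site(1, {"RED-ML"}, n_samples=1, level=0.5)], PipelineConfig()
        )
        assert not retained and len(rejected) == 1

    def test_just_above_threshold_in_two_samples_is_retained(self):
        retained, rejected = consensus.apply_reproducibility_thresholds(
            [make_site(1, {"RED-ML"}, n_samples=2, level=0.21)], PipelineConfig()
        )
        assert len(retained) == 1 and not rejected

    def test_partition_is_conserved(self):
        sites = [
            make_site(p, {"RED-ML"}, n_samples=int(n), level=float(l))
            for p, n, l in zip(
                range(1, 101),
                np.random.default_rng(1).integers(1, 4, 100),
                np.random.default_rng(2).random(100),
            )
        ]
        retained, rejected = consensus.apply_reproducibility_thresholds(
            sites, PipelineConfig()
        )
        assert len(retained) + len(rejected) == len(sites)

    @settings(derandomize=True, max_examples=50)
    @given(
        levels=st.lists(st.floats(0, 1), min_size=1, max_size=20),
        thresholds=st.tuples(st.floats(0, 1), st.floats(0, 1)),
    )
    def test_thresholding_is_monotone(self, levels, thresholds):
        """Raising the level threshold never adds a retained site."""
        lo, hi = sorted(thresholds)
        sites = [
            make_site(i + 1, {"RED-ML"}, n_samples=2, level=level)
            for i, level in enumerate(levels)
        ]
        keep_lo = {
            s.key
            for s in consensus.apply_reproducibility_thresholds(
                sites, PipelineConfig(level_threshold=lo)
            )[0]
        }
        keep_hi = {
            s.key
            for s in consensus.apply_reproducibility_thresholds(
                sites, PipelineConfig(level_threshold=hi)
            )[0]
        }
        assert keep_hi <= keep_lo


class TestMethodSpecificity:
    @pytest.mark.parametrize(
        "methods,expected",
        [
            ({"SPRINT"}, "SPRINT-specific"),
            ({"RED-ML", "SPRINT"}, "multi-method"),
            ({"REDItools"}, "REDItools-specific"),
        ],
    )
    def test_labels(self, methods, expected):
        assert consensus.classify_method_specificity(make_site(1, methods)) == expected

    def test_cross_sample_attribution_is_multi_method(self):
        sites = consensus.build_consensus(
            [call(100, "A", "RED-ML", 0.1), call(100, "B", "SPRINT", 0.3)]
        )
        assert consensus.classify_method_specificity(sites[0]) == "multi-method"

    def test_hpc_only_site_is_auxiliary(self):
        site = make_site(1, {"HPC-REDItools"})
        assert consensus.classify_method_specificity(site) == "auxiliary-only"

    def test_hpc_evidence_counts_for_levels_but_not_decisions(self):
        sites = consensus.build_consensus(
            [call(100, "A", "RED-ML", 0.2), call(100, "A", "HPC-REDItools", 0.4)]
        )
        site = sites[0]
        assert site.max_level == pytest.approx(0.3)  # HPC level aggregated
        assert site.methods == {"RED-ML"}  # but excluded from decisions
        assert site.methods_all == {"RED-ML", "HPC-REDItools"}
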