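"""Consensus funnel: size filter, outlier QC, matching, rescue, curation."""

import numpy as np
import pytest

from cnvpop.consensus import (
    ConsensusCnv,
    calls_match,
    curate_breakpoints,
    detect_outlier_samples,
    filter_min_units,
    integrate,
    inter_individual_rescue,
    intra_individual_consensus,
)
from cnvpop.core import CnClass, GenomicInterval, PipelineConfig

from conftest import mk_call


class TestSizeFilter:
    def test_boundary_at_five_units(self):
        below = mk_call(n_units=4)
        at = mk_call(n_units=5)
        assert filter_min_units([below, at], 5) == [at]

    def test_empty_input(self):
        assert filter_min_units([], 5) == []

    def test_order_preserved(self):
        calls = [mk_call(start=s, end=s + 100, n_units=u) for s, u in [(0, 9), (500, 3), (900, 7)]]
        assert filter_min_units(calls, 5) == [calls[0], calls[2]]


class TestOutlierDetection:
    def _cohort(self, counts):
        calls = []
        for i, n in enumerate(counts):
            for j in range(n):
                calls.append(mk_call(sample=f"s{i:03d}", start=j * 10, end=j * 10 + 5))
        return calls

    def test_inflated_samples_excluded(self, rng):
        counts = [int(x) for x in rng.normal(1800, 100, 100)]
        counts[0] = counts[1] = counts[2] = 20000
        out = detect_outlier_samples(self._cohort(counts), k=3)
        assert out == ["s000", "s001", "s002"]

    def test_identical_counts_none_excluded(self):
        assert detect_outlier_samples(self._cohort([50] * 10), k=3) == []

    def test_single_ten_fold_outlier(self, rng):
        """Direct rule evaluation: one sample at 10× the median is the only flag."""
        counts = [int(x) for x in rng.normal(1800, 100, 50)]
        med = int(np.median(counts))
        counts.append(10 * med)
        out = detect_outlier_samples(self._cohort(counts), k=3)
        assert out == ["s050"]

    def test_too_few_samples_fatal(self):
        with pytest.raises(ValueError):
            detect_outlier_samples(self._cohort([10, 10]), k=3)


class TestCallMatching:
    def test_same_direction_different_class_matches(self):
        a = mk_call(cn=CnClass.HET_DEL, start=100, end=200)
        b = mk_call(algorithm="quantisnp", cn=CnClass.HOM_DEL, start=150, end=300)
        assert calls_match(a, b) and calls_match(b, a)

    def test_opposite_direction_no_match(self):
        a = mk_call(cn=CnClass.HET_DEL, start=100, end=200)
        b = mk_call(cn=CnClass.DUP, start=150, end=300)
        assert not calls_match(a, b)

    def test_no_overlap_no_match(self):
        a = mk_call(start=100, end=200)
        b = mk_call(start=200, end=300)
        assert not calls_match(a, b)

    def test_reciprocal_overlap_option(self):
        a = mk_call(start=0, end=1000)
        b = mk_call(algorithm="quantisnp", start=900, end=1100)
        assert calls_match(a, b)
        assert not calls_match(a, b, reciprocal_overlap=0.5)


class TestIntraConsensus:
    def test_two_algorithms_one_group(self):
        a = mk_call(algorithm="cnmops", start=100, end=200)
        b = mk_call(algorithm="quantisnp", start=150, end=250)
        groups, singles = intra_individual_consensus([a, b])
        assert len(groups) == 1 and set(groups[0]) == {a, b} and singles == []

    def test_same_algorithm_only_is_singleton(self):
        a = mk_call(algorithm="cnmops", start=100, end=200)
        b = mk_call(algorithm="cnmops", start=150, end=250)
        groups, singles = intra_individual_consensus([a, b])
        assert groups == [] and set(singles) == {a, b}

    def test_disjoint_calls_all_singletons(self):
        calls = [mk_call(start=i * 1000, end=i * 1000 + 100) for i in range(10)]
        groups, singles = intra_individual_consensus(calls)
        assert groups == [] and len(singles) == 10

    def test_transitive_chain_single_group(self):
        a = mk_call(algorithm="cnmops", start=0, end=100)
        b = mk_call(algorithm="quantisnp", start=90, end=200)
        c = mk_call(algorithm="vendor_ngs", start=190, end=300)
        groups, _ = intra_individual_consensus([a, b, c])
        assert len(groups) == 1 and len(groups[0]) == 3


class TestInterRescue:
    def test_second_occurrence_rescues(self):
        s = mk_call(sample="s1", start=100, end=200)
        other = mk_call(sample="s2", algorithm="quantisnp", start=150, end=250)
        rescued, discarded = inter_individual_rescue([s], [s, other])
        assert rescued == [s] and discarded == []

    def test_cohort_unique_discarded(self):
        s = mk_call(sample="s1", start=100, end=200)
        far = mk_call(sample="s2", start=90_000, end=90_100)
        rescued, discarded = inter_individual_rescue([s], [s, far])
        assert rescued == [] and discarded == [s]

    def test_mutual_singletons_both_rescued(self):
        a = mk_call(sample="s1", start=100, end=200)
        b = mk_call(sample="s2", start=150, end=250)
        rescued, _ = inter_individual_rescue([a, b], [a, b])
        assert set(rescued) == {a, b}


class TestCuration:
    def test_ngs_breakpoints_win_over_array(self):
        arr = mk_call(algorithm="quantisnp", start=1000, end=9000)
        ngs = mk_call(algorithm="cnmops", start=2000, end=8000)
        c = curate_breakpoints([arr, ngs])
        assert (c.interval.start, c.interval.end) == (2000, 8000)
        assert c.breakpoint_source == "ngs"
        assert c.support == frozenset({("array", "quantisnp"), ("ngs", "cnmops")})

    def test_same_platform_intersection(self):
        a = mk_call(algorithm="cnmops", start=2000, end=8000)
        b = mk_call(algorithm="vendor_ngs", start=3000, end=9000)
        c = curate_breakpoints([a, b])
        assert (c.interval.start, c.interval.end) == (3000, 8000)
        assert c.breakpoint_source == "intersection"

    def test_class_follows_narrower_member(self):
        wide = mk_call(algorithm="cnmops", cn=CnClass.HET_DEL, start=0, end=10_000)
        narrow = mk_call(algorithm="vendor_ngs", cn=CnClass.HOM_DEL, start=2000, end=6000)
        assert curate_breakpoints([wide, narrow]).cn is CnClass.HOM_DEL

    def test_single_rescued_call_unchanged(self):
        c = mk_call(start=123, end=456)
        out = curate_breakpoints([c])
        assert (out.interval.start, out.interval.end) == (123, 456)
        assert out.support_mode == "inter"

    def test_empty_chain_intersection_falls_back_to_narrowest(self):
        # a-b overlap and b-c overlap but a-c do not: empty common segment
        a = mk_call(algorithm="cnmops", start=0, end=1000)
        b = mk_call(algorithm="vendor_ngs", start=900, end=2500)
        c = mk_call(algorithm="cnmops", start=2400, end=2800)
        out = curate_breakpoints([a, b, c])
        assert out.fallback
        assert out.interval.span == 400  # narrowest member

    def test_endpoints_come_from_raw_calls(self):
        a = mk_call(algorithm="cnmops", start=2000, end=8000)
        b = mk_call(algorithm="vendor_ngs", start=3000, end=9000)
        out = curate_breakpoints([a, b])
        raw_pts = {2000, 8000, 3000, 9000}
        assert out.interval.start in raw_pts and out.interval.end in raw_pts


class TestConsensusInvariants:
    def test_no_final_call_has_single_evidence(self):
        with pytest.raises(ValueError):
            ConsensusCnv(
                "s1",
                GenomicInterval("1", 0, 10),
                CnClass.HET_DEL,
                frozenset({("ngs", "cnmops")}),
                "intra",
                "ngs",
            )

    def test_min_units_monotonicity(self, small_cohort):
        cfg, truth, call_sets = small_cohort
        calls = [c for v in call_sets.values() for c in v]
        sizes = []
        for mu in (5, 8, 12):
            final, _ = integrate(calls, PipelineConfig(min_units=mu))
            sizes.append(sum(len(v) for v in final.values()))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_intervals_contained_in_raw_union(self, small_cohort):
        cfg, truth, call_sets = small_cohort
        calls = [c for v in call_sets.values() for c in v]
        final, _ = integrate(calls, PipelineConfig())
        raw_pts = {}
        for c in calls:
            raw_pts.setdefault(c.sample_id, set()).update(
                [(c.interval.chrom, c.interval.start), (c.interval.chrom, c.interval.end)]
            )
        for sid, cnvs in final.items():
            for c in cnvs:
                if c.fallback:
                    continue
                assert (c.interval.chrom, c.interval.start) in raw_pts[sid]
                assert (c.interval.chrom, c.interval.end) in raw_pts[sid]

    def test_deterministic_under_input_shuffle(self, small_cohort, rng):
        cfg, truth, call_sets = small_cohort
        calls = [c for v in call_sets.values() for c in v]
        shuffled = list(calls)
        rng.shuffle(shuffled)
        f1, _ = integrate(calls, PipelineConfig())
        f2, _ = integrate(shuffled, PipelineConfig())
        key = lambda d: {
            s: sorted((c.interval, c.cn.value, c.support_mode) for c in v) for s, v in d.items()
        }
        assert key(f1) == key(f2)


class TestIntegrationEndToEnd:
    def test_unique_calls_yield_nothing(self):
        # every call unique in the cohort: all singletons, none rescued
        calls = [
            mk_call(sample=f"s{i}", start=i * 100_000, end=i * 100_000 + 600)
            for i in range(10)
        ]
        final, report = integrate(calls, PipelineConfig())
        assert sum(len(v) for v in final.values()) == 0

    def test_noiseless_recovers_truth(self, noiseless_cohort):
        """In the no-noise limit, final CNVs equal planted truth at every
        locus retained by ≥2 algorithms after the size filter."""
        from cnvpop.consensus import filter_min_units as fmu
        from collections import defaultdict

        cfg, truth, call_sets = noiseless_cohort
        calls = [c for v in call_sets.values() for c in v]
        final, report = integrate(calls, PipelineConfig())
        kept = fmu(calls, 5)
        algs = defaultdict(set)
        for c in kept:
            algs[(c.sample_id, c.interval.chrom, c.interval.start, c.interval.end)].add(c.algorithm)
        expected = defaultdict(set)
        for tc in truth.cnvs:
            if tc.sample_id in report.excluded_samples:
                continue
            if len(algs[(tc.sample_id, tc.interval.chrom, tc.interval.start, tc.interval.end)]) >= 2:
                expected[tc.sample_id].add((tc.interval, tc.cn))
        got = {s: {(c.interval, c.cn) for c in v} for s, v in final.items()}
        for s in set(expected) | set(got):
            assert got.get(s, set()) == expected.get(s, set())

    def test_specificity_gain_on_noisy_cohort(self, small_cohort):
        """Final-call precision strictly exceeds raw-union precision."""
        from intervaltree import IntervalTree
        from collections import defaultdict

        cfg, truth, call_sets = small_cohort
        trees = defaultdict(IntervalTree)
        for l in truth.loci:
            trees[(l.interval.chrom, l.direction)].addi(l.interval.start, l.interval.end)

        def is_true(c):
            return bool(
                trees[(c.interval.chrom, c.cn.direction)].overlap(c.interval.start, c.interval.end)
            )

        calls = [c for v in call_sets.values() for c in v]
        final, report = integrate(calls, PipelineConfig())
        kept_samples = set(final)
        raw = [c for c in calls if c.sample_id in kept_samples]
        fin = [c for v in final.values() for c in v]
        raw_precision = sum(map(is_true, raw)) / len(raw)
        final_precision = sum(map(is_true, fin)) / len(fin)
        assert final_precision > raw_precision
        # and zero retained calls carry single-algorithm intra evidence
        assert all(
            len({a for _, a in c.support}) >= 2 or c.support_mode == "inter" for c in fin
        )
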