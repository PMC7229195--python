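"""Consensus pipelines, collation, and region statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvrkit.consensus import (
    ConsensusConfig,
    animal_high_confidence_calls,
    animal_pipeline,
    collate_regions,
    passes_reciprocal,
    population_pipeline,
    reciprocal_overlap,
    summarize,
    threshold_sweep,
    unique_high_confidence,
)
from cnvrkit.types import (
    CNVRegion,
    Event,
    GenomicInterval,
    RegionType,
    SourceSet,
)

from conftest import make_gen_call, make_wgs_call, oracle_components, random_instance

intervals_st = st.tuples(
    st.integers(min_value=1, max_value=5_000), st.integers(min_value=1, max_value=2_000)
).map(lambda t: GenomicInterval("1", t[0], t[0] + t[1] - 1))


class TestReciprocalOverlap:
    def test_identity(self):
        a = GenomicInterval("1", 100, 199)
        assert reciprocal_overlap(a, a) == (1.0, 1.0)

    def test_disjoint_and_cross_chromosome(self):
        a = GenomicInterval("1", 100, 199)
        assert reciprocal_overlap(a, GenomicInterval("1", 300, 399)) == (0.0, 0.0)
        assert reciprocal_overlap(a, GenomicInterval("2", 100, 199)) == (0.0, 0.0)

    def test_worked_case_60_percent(self):
        a = GenomicInterval("1", 1000, 1999)  # 1000 bp
        b = GenomicInterval("1", 1400, 2399)  # 1000 bp; shared 1400..1999 = 600 bp
        assert reciprocal_overlap(a, b) == (0.6, 0.6)
        assert passes_reciprocal(a, b, 0.5)

    def test_exact_threshold_pass(self):
        a = GenomicInterval("1", 1, 1000)
        b = GenomicInterval("1", 501, 1500)  # 500 bp shared of 1000 each
        assert reciprocal_overlap(a, b) == (0.5, 0.5)
        assert passes_reciprocal(a, b, 0.5)
        assert not passes_reciprocal(a, b, 0.501)

    @settings(derandomize=True, max_examples=200)
    @given(intervals_st, intervals_st)
    def test_symmetry_and_range(self, a, b):
        fa, fb = reciprocal_overlap(a, b)
        fb2, fa2 = reciprocal_overlap(b, a)
        assert (fa, fb) == (fa2, fb2)
        assert 0.0 <= fa <= 1.0 and 0.0 <= fb <= 1.0
        # shared bases are identical from both sides
        assert fa * a.length == pytest.approx(fb * b.length)


class TestCollation:
    def test_empty(self):
        assert collate_regions([]) == []

    def test_contiguous_chain_merges(self):
        calls = [
            make_gen_call(1, 100, 199),
            make_gen_call(1, 150, 300, sample="S002"),
            make_gen_call(1, 301, 400, sample="S003"),  # adjacent to 300
        ]
        (region,) = collate_regions(calls)
        assert region.interval == GenomicInterval("1", 100, 400)
        assert region.samples == {"S001", "S002", "S003"}

    def test_gap_of_one_base_does_not_merge(self):
        calls = [make_gen_call(1, 100, 199), make_gen_call(1, 201, 300)]
        assert len(collate_regions(calls)) == 2
        assert len(collate_regions(calls, contiguity_gap=1)) == 1

    def test_chromosomes_never_merge(self):
        calls = [
            make_gen_call(1, 100, 199),
            make_gen_call(1, 150, 300),
            make_gen_call(2, 301, 400),
        ]
        assert len(collate_regions(calls)) == 2

    def test_region_typing(self):
        loss = make_gen_call(1, 100, 199, event=Event.LOSS)
        gain = make_gen_call(1, 150, 250, sample="S002", event=Event.GAIN)
        assert collate_regions([loss])[0].rtype == RegionType.CNL
        assert collate_regions([gain])[0].rtype == RegionType.CNG
        assert collate_regions([loss, gain])[0].rtype == RegionType.MIX

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("gap", [0, 500])
    def test_matches_union_find_oracle(self, seed, gap):
        rng = np.random.default_rng(seed)
        calls, intervals = random_instance(rng)
        regions = collate_regions(calls, contiguity_gap=gap)
        expected = oracle_components(intervals, contiguity_gap=gap)
        got = sorted(
            (r.interval.chrom, r.interval.start, r.interval.end) for r in regions
        )
        assert got == sorted(span for _, span in expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_invariant_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        calls, _ = random_instance(rng)
        regions = collate_regions(calls)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        regions2 = collate_regions(shuffled)
        key = lambda r: (r.interval, r.samples, r.rtype)
        assert sorted(map(key, regions)) == sorted(map(key, regions2))
        # regions are pairwise non-mergeable: collating spans changes nothing
        spans = [make_gen_call(r.interval.chrom, r.interval.start, r.interval.end) for r in regions]
        assert len(collate_regions(spans)) == len(regions)


class TestAnimalPipeline:
    def test_gen_only_sample_contributes_nothing(self):
        assert animal_pipeline([make_gen_call(1, 1000, 1999)], []) == []

    def test_matched_pair_yields_union_span_region(self):
        gen = make_gen_call(1, 1000, 1999, event=Event.LOSS)
        wgs = make_wgs_call(1, 1400, 2399, event=Event.LOSS)
        (region,) = animal_pipeline([gen], [wgs])
        assert region.interval == GenomicInterval("1", 1000, 2399)
        assert region.rtype == RegionType.CNL
        assert region.samples == {"S001"}
        assert region.source_set == SourceSet.ANIMAL_CNVR

    def test_low_overlap_pair_rejected(self):
        gen = make_gen_call(1, 1000, 1999)
        wgs = make_wgs_call(1, 1500, 1799)  # 300 bp / 1000 bp = 0.3 on the GEN side
        assert animal_pipeline([gen], [wgs]) == []

    def test_cross_sample_pairs_never_match(self):
        gen = make_gen_call(1, 1000, 1999, sample="A")
        wgs = make_wgs_call(1, 1000, 1999, sample="B")
        assert animal_pipeline([gen], [wgs]) == []

    def test_discordant_event_pair_dropped_and_counted(self):
        gen = make_gen_call(1, 1000, 1999, event=Event.LOSS)
        wgs = make_wgs_call(1, 1000, 1999, event=Event.GAIN)
        hc, n_discordant = animal_high_confidence_calls([gen], [wgs], 0.5)
        assert hc == [] and n_discordant == 1


class TestPopulationPipeline:
    def _pair(self, sample_gen, sample_wgs, chrom=1, event_gen=Event.LOSS, event_wgs=Event.LOSS):
        return (
            make_gen_call(chrom, 1000, 1999, sample=sample_gen, event=event_gen),
            make_wgs_call(chrom, 1200, 2199, sample=sample_wgs, event=event_wgs),
        )

    def test_no_matching_pair_gives_empty_set(self):
        gen = [make_gen_call(1, 1000, 1999)]
        wgs = [make_wgs_call(2, 1000, 1999)]
        assert population_pipeline(gen, wgs, 20) == []

    def test_frequency_floor_is_strict(self):
        gen, wgs = self._pair("A", "A")
        # one carrier of 20 = 5.0% -> excluded by the strict "more than 5%"
        assert population_pipeline([gen], [wgs], 20) == []
        # two carriers of 20 = 10% -> included
        gen2, wgs2 = self._pair("A", "B")
        (region,) = population_pipeline([gen2], [wgs2], 20)
        assert region.samples == {"A", "B"}
        # non-strict mode admits exactly 5%
        cfg = ConsensusConfig(strict=False)
        assert len(population_pipeline([gen], [wgs], 20, cfg)) == 1

    def test_mix_typing_across_sources(self):
        gen, wgs = self._pair("A", "B", event_gen=Event.GAIN, event_wgs=Event.LOSS)
        (region,) = population_pipeline([gen], [wgs], 10)
        assert region.rtype == RegionType.MIX
        assert region.source_set == SourceSet.POPULATION_CNVR

    def test_zero_samples_errors(self):
        with pytest.raises(ValueError):
            population_pipeline([], [], 0)


class TestUniqueHighConfidence:
    def _region(self, start, end, source_set, chrom="1"):
        return CNVRegion(
            GenomicInterval(chrom, start, end), RegionType.CNL, frozenset({"A"}), source_set
        )

    def test_identical_sets_counted_once(self):
        animal = [self._region(i * 10_000, i * 10_000 + 100, SourceSet.ANIMAL_CNVR) for i in range(1, 4)]
        population = [self._region(i * 10_000, i * 10_000 + 100, SourceSet.POPULATION_CNVR) for i in range(1, 4)]
        unique = unique_high_confidence(animal, population)
        assert len(unique) == 3
        assert all(r.origins == {"ANIMAL_CNVR", "POPULATION_CNVR"} for r in unique)

    def test_overlapping_regions_merge_to_union(self):
        unique = unique_high_confidence(
            [self._region(1, 1000, SourceSet.ANIMAL_CNVR)],
            [self._region(900, 2000, SourceSet.POPULATION_CNVR)],
        )
        (region,) = unique
        assert region.interval == GenomicInterval("1", 1, 2000)
        assert region.source_set == SourceSet.UNIQUE_HC

    def test_disjoint_region_carried_through(self):
        unique = unique_high_confidence([self._region(1, 1000, SourceSet.ANIMAL_CNVR)], [])
        (region,) = unique
        assert region.interval == GenomicInterval("1", 1, 1000)
        assert region.origins == {"ANIMAL_CNVR"}

    def test_adjacent_but_not_overlapping_regions_stay_separate(self):
        unique = unique_high_confidence(
            [self._region(1, 1000, SourceSet.ANIMAL_CNVR)],
            [self._region(1001, 2000, SourceSet.POPULATION_CNVR)],
        )
        assert len(unique) == 2


class TestThresholdSweep:
    def _all_point_six(self, n=10):
        gen, wgs = [], []
        for i in range(n):
            offset = i * 100_000
            gen.append(make_gen_call(1, offset + 1000, offset + 1999, sample=f"S{i:03d}"))
            wgs.append(make_wgs_call(1, offset + 1400, offset + 2399, sample=f"S{i:03d}"))
        return gen, wgs

    def test_consistent_with_pipeline_at_default(self):
        gen, wgs = self._all_point_six()
        table = threshold_sweep(gen, wgs, [0.5])
        assert table.loc[0, "n_regions"] == len(animal_pipeline(gen, wgs))

    def test_step_function_at_constructed_overlap(self):
        gen, wgs = self._all_point_six(10)
        thresholds = [round(0.1 * k, 1) for k in range(1, 10)]
        table = threshold_sweep(gen, wgs, thresholds)
        counts = dict(zip(table["threshold"], table["n_regions"]))
        for t in thresholds:
            assert counts[t] == (10 if t <= 0.6 else 0)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([], [], [1.0])


class TestSummarize:
    def test_coverage_arithmetic(self):
        region = CNVRegion(
            GenomicInterval("1", 1, 2_716_000), RegionType.CNL, frozenset({"A"}),
            SourceSet.ANIMAL_CNVR,
        )
        s = summarize([region], {"1": 2_716_000_000}, 10)
        assert s["coverage_pct"] == pytest.approx(0.1)

    def test_empty_set(self):
        s = summarize([], {"1": 1_000}, 10)
        assert s["n_regions"] == 0 and s["coverage_pct"] == 0.0

    def test_private_and_shared_counts(self):
        def region(start, samples):
            return CNVRegion(
                GenomicInterval("1", start, start + 99), RegionType.CNL,
                frozenset(samples), SourceSet.ANIMAL_CNVR,
            )
        regions = [
            region(1_000, {"A"}),
            region(10_000, {"B"}),
            region(20_000, {"A", "B", "C", "D", "E"}),
        ]
        s = summarize(regions, {"1": 1_000_000}, 10)
        assert s["n_private"] == 2
        assert s["samples_max"] == 5
        assert s["n_shared_by_all"] == 0
        s_all = summarize(regions, {"1": 1_000_000}, 5)
        assert s_all["n_shared_by_all"] == 1

    def test_unknown_chromosome_errors(self):
        region = CNVRegion(
            GenomicInterval("7", 1, 100), RegionType.CNL, frozenset({"A"}), SourceSet.ANIMAL_CNVR
        )
        with pytest.raises(KeyError, match="7"):
            summarize([region], {"1": 1_000}, 10)
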