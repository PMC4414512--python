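"""Count tables, normalization, error rates, correlations and detection."""

import math
import random

import numpy as np
import pytest

from ampliconid import (
    AlignmentResult,
    CountTable,
    PoolSpec,
    SPECIES_CLASS,
    aggregate_by_species,
    builtin_pool,
    call_species,
    compare_libraries,
    count_by_region,
    estimate_error_rates,
    normalize_per_ng,
    pearson_correlation,
)
from ampliconid.datasets import dilution_series_tables


def _aln(species, pair, n_mm=0, n_ins=0, n_del=0, aligned=100, rid="r"):
    return AlignmentResult(
        rid, species, pair, "+", 100, 0, 60, n_mm, n_ins, n_del, aligned, "100M", 0, 100
    )


class TestCountByRegion:
    def test_basic_tally(self):
        alns = [_aln("pig", "12S_KH")] * 3 + [_aln("horse", "16S_Ki")] * 2
        table = count_by_region(alns, "lib")
        assert table.get("pig", "12S_KH") == 3
        assert table.get("horse", "16S_Ki") == 2
        assert table.total == 5

    def test_dilution_table_pair_totals(self):
        t10, t50 = dilution_series_tables()
        assert t10.pair_total("16S_Ki") == 16639
        assert t50.pair_total("12S_KH") == 4917

    def test_counts_reconcile_with_truth_read_by_read(self, panel3):
        from conftest import run_identification

        pool = PoolSpec(name="tri", masses={s: 1.0 for s in panel3.species})
        sim, retained, tally = run_identification(panel3, pool, n_reads=400, seed=17)
        table = count_by_region(retained, "tri")
        truth = {}
        retained_ids = {r.read_id for r in retained}
        for r in sim:
            if r.read_id in retained_ids:
                truth[(r.species, r.pair)] = truth.get((r.species, r.pair), 0) + 1
        # every retained read was assigned to its simulated origin
        assert dict(table.counts) == truth
        assert table.total + sum(tally.values()) == len(sim)


class TestAggregate:
    def test_two_species_proportions(self):
        table = CountTable("lib", {("A", "P"): 80, ("B", "P"): 20})
        agg = aggregate_by_species(table)
        assert agg["proportions"][("A", "P")] == pytest.approx(0.8)
        assert agg["proportions"][("B", "P")] == pytest.approx(0.2)

    def test_class_proportions_sum_to_one(self):
        table = CountTable(
            "lib",
            {("pig", "P"): 30, ("cattle", "P"): 30, ("chicken", "P"): 25, ("duck", "P"): 15},
        )
        agg = aggregate_by_species(table, class_map=SPECIES_CLASS)
        cp = agg["class_proportions"]
        assert cp[("mammal", "P")] + cp[("avian", "P")] == pytest.approx(1.0)
        # independent explicit summation
        assert cp[("mammal", "P")] == pytest.approx((30 + 30) / 100)

    def test_all_zero_pair_reported_missing(self):
        table = CountTable("lib", {("A", "P"): 0, ("A", "Q"): 5})
        agg = aggregate_by_species(table)
        assert agg["undefined_pairs"] == ["P"]
        assert ("A", "P") not in agg["proportions"]


class TestNormalizePerNg:
    def test_simple_division(self):
        table = CountTable("lib", {("pig", "P"): 100})
        pool = PoolSpec(name="x", masses={"pig": 2.0}, reaction_ng=2.0)
        assert normalize_per_ng(table, pool)[("pig", "P")] == pytest.approx(50.0)

    def test_equimolar_thirteen_species_reaction_mass(self):
        # each species contributes 20/13 ~ 1.54 ng per reaction
        table = CountTable("lib", {("pig", "P"): 154})
        out = normalize_per_ng(table, builtin_pool("c1"))
        assert out[("pig", "P")] == pytest.approx(154 / (20 / 13))

    def test_fiftyfold_dilution_reaction_mass(self):
        # pig at 2 ng among 504 ng total -> 20*2/504 ~ 0.079 ng per reaction
        table = CountTable("lib", {("pig", "P"): 10})
        out = normalize_per_ng(table, builtin_pool("e"))
        assert out[("pig", "P")] == pytest.approx(10 / (20 * 2 / 504))

    def test_scale_equivariance(self):
        counts = {("pig", "P"): 7, ("horse", "P"): 13}
        pool = builtin_pool("a")
        base = normalize_per_ng(CountTable("l", counts), pool)
        doubled = normalize_per_ng(
            CountTable("l", {k: 2 * v for k, v in counts.items()}), pool
        )
        for k in counts:
            assert doubled[k] == pytest.approx(2 * base[k])

    def test_missing_species_raises(self):
        table = CountTable("lib", {("pigeon", "P"): 1})
        with pytest.raises(KeyError, match="pigeon"):
            normalize_per_ng(table, builtin_pool("a"))


class TestErrorRates:
    def test_error_free_alignments_rate_zero(self):
        table = estimate_error_rates([_aln("pig", "P") for _ in range(10)])
        assert table.rate("pig", "P") == 0.0

    def test_forced_single_deletion(self):
        table = estimate_error_rates([_aln("pig", "P", n_del=1, aligned=100)])
        assert table.rate("pig", "P") == pytest.approx(0.01)

    def test_substitutions_only_mode(self):
        alns = [_aln("pig", "P", n_mm=1, n_ins=1, n_del=1, aligned=100)]
        assert estimate_error_rates(alns).rate("pig", "P") == pytest.approx(0.03)
        assert estimate_error_rates(alns, substitutions_only=True).rate(
            "pig", "P"
        ) == pytest.approx(0.01)

    def test_invariant_to_read_order(self, rng):
        alns = [
            _aln("pig", "P", n_mm=int(rng.integers(0, 3)), aligned=100, rid=f"r{i}")
            for i in range(50)
        ]
        shuffled = alns.copy()
        random.Random(5).shuffle(shuffled)
        assert estimate_error_rates(alns).rates() == estimate_error_rates(shuffled).rates()

    def test_parameter_recovery_small(self, panel3):
        """sub_rate 0.005 with homopolymer errors off is recovered within the
        99% binomial interval over >= 50k aligned bases."""
        from conftest import run_identification
        from ampliconid.simulate import ErrorModel

        pool = PoolSpec(name="tri", masses={s: 1.0 for s in panel3.species})
        err = ErrorModel(sub_rate=0.005, hp_slope=0.0, hp_max=0.0)
        _, retained, _ = run_identification(panel3, pool, err=err, n_reads=600, seed=23)
        cells = estimate_error_rates(retained).cells.values()
        n = sum(c.aligned_ref_bases for c in cells)
        k = sum(c.mismatch_bases + c.inserted_bases + c.deleted_bases for c in cells)
        assert n >= 50_000
        p = 0.005
        half = 2.576 * math.sqrt(p * (1 - p) / n)
        assert abs(k / n - p) < half


class TestPearson:
    def test_perfect_positive(self):
        x = [1, 5, 9, 14]
        assert pearson_correlation(x, [2 * v for v in x]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1, 5, 9, 14]
        assert pearson_correlation(x, [-v + 3 for v in x]) == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        assert math.isnan(pearson_correlation([1, 2, 3], [4, 4, 4]))

    def test_dilution_replicates_highly_correlated(self):
        t10, t50 = dilution_series_tables()
        keys = [k for k in t10.counts if k[0] not in ("pig", "horse")]
        assert len(keys) == 15
        r = pearson_correlation([t10.get(*k) for k in keys], [t50.get(*k) for k in keys])
        assert round(r, 2) >= 0.99


class TestCallSpecies:
    def test_zero_counts_not_detected(self):
        table = CountTable("lib", {("pig", "P"): 0, ("pig", "Q"): 0})
        calls = {c.species: c for c in call_species(table, min_reads=1)}
        assert not calls["pig"].detected

    def test_dilution_horse_detected_via_two_pairs(self):
        # horse counts at 1:50 are 1 / 0 / 17 across the three pairs
        _, t50 = dilution_series_tables()
        calls = {c.species: c for c in call_species(t50, min_reads=1, min_pairs=2)}
        horse = calls["horse"]
        assert horse.detected
        assert sorted(horse.supporting) == ["12S_KH", "16S_Ki"]

    def test_panel_species_absent_from_counts_reported(self):
        table = CountTable("lib", {("pig", "P"): 5})
        calls = {c.species: c for c in call_species(table, species=["goose"])}
        assert not calls["goose"].detected

    def test_detection_monotone_in_min_reads(self):
        _, t50 = dilution_series_tables()
        detected = []
        for min_reads in range(1, 51):
            calls = {c.species: c for c in call_species(t50, min_reads=min_reads, min_pairs=2)}
            detected.append(calls["pig"].detected)
        assert all(a >= b for a, b in zip(detected, detected[1:]))


class TestCompareLibraries:
    def test_self_correlation_is_one(self):
        t10, _ = dilution_series_tables()
        clone = CountTable("copy", dict(t10.counts))
        df = compare_libraries([t10, clone])
        defined = df[df["defined"]]
        assert (defined["r"] > 0.9999).all()

    def test_degenerate_slice_flagged_not_one(self):
        counts_a = {("chicken", "P"): 0, ("duck", "P"): 0, ("goose", "P"): 0,
                    ("pig", "P"): 10, ("cattle", "P"): 20, ("horse", "P"): 5}
        counts_b = dict(counts_a)
        a = CountTable("a", counts_a)
        b = CountTable("b", counts_b)
        df = compare_libraries([a, b], class_map=SPECIES_CLASS)
        avian = df[df["slice"] == "avian"].iloc[0]
        assert not avian["defined"] and math.isnan(avian["r"])

    def test_disjoint_key_sets_error(self):
        a = CountTable("a", {("pig", "P"): 1})
        b = CountTable("b", {("horse", "Q"): 1})
        with pytest.raises(ValueError, match="share no"):
            compare_libraries([a, b])

    def test_simulated_replicates_correlate(self, panel3):
        from conftest import run_identification

        # uneven masses give the count table real structure; an equimolar
        # pool would leave only sampling noise and no correlation to measure
        pool = PoolSpec(name="uneven", masses={"pig": 100.0, "horse": 20.0, "cattle": 2.0})
        tables = []
        for seed in (31, 32):
            _, retained, _ = run_identification(panel3, pool, n_reads=1500, seed=seed)
            tables.append(count_by_region(retained, f"rep{seed}"))
        df = compare_libraries(tables)
        r_all = df[df["slice"] == "all"]["r"].iloc[0]
        assert r_all >= 0.95
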