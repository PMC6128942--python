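import math

import numpy as np
import pytest

from barcode_eval import (classify_at_threshold, compare_family_vs_partitions,
                          cumulative_error_percent, default_grid,
                          distance_matrix, partitioned_scan, threshold_scan)
from barcode_eval.synthetic_data import (SimulationConfig,
                                         inject_problem_cases,
                                         simulate_library)

from conftest import make_dataset, rng_seeds


def brute_force_counts(matrix, species, t):
    """Independent FP/FN recount straight from the definitions."""
    fp, fn = set(), set()
    n = matrix.n
    for i in range(n):
        intra = [matrix.d[i, j] for j in range(n)
                 if j != i and species[j] == species[i]
                 and not math.isnan(matrix.d[i, j])]
        inter = [matrix.d[i, j] for j in range(n)
                 if species[j] != species[i]
                 and not math.isnan(matrix.d[i, j])]
        if intra and min(intra) > t:
            fp.add(matrix.ids[i])
        if inter and min(inter) <= t:
            fn.add(matrix.ids[i])
    return fp, fn


class TestClassifyAtThreshold:
    def test_clean_gap_zero_error(self, two_species_dataset):
        m = distance_matrix(two_species_dataset)
        fp, fn = classify_at_threshold(
            m, two_species_dataset.species_labels, 0.05)
        assert fp == [] and fn == []

    def test_threshold_below_gap_all_fp(self, two_species_dataset):
        # intra ~0.0101 > t=0.005: every sequence's nearest conspecific is
        # beyond the threshold
        m = distance_matrix(two_species_dataset)
        fp, fn = classify_at_threshold(
            m, two_species_dataset.species_labels, 0.005)
        assert sorted(fp) == ["a1", "a2", "b1", "b2"] and fn == []

    def test_threshold_above_gap_all_fn(self, two_species_dataset):
        m = distance_matrix(two_species_dataset)
        fp, fn = classify_at_threshold(
            m, two_species_dataset.species_labels, 0.20)
        assert fp == [] and sorted(fn) == ["a1", "a2", "b1", "b2"]

    def test_singletons_only_fn(self):
        ds = make_dataset([("x1", "A" * 100, "sp_a"),
                           ("x2", "G" * 3 + "A" * 97, "sp_b")])
        m = distance_matrix(ds)
        fp, fn = classify_at_threshold(m, ds.species_labels, 0.001)
        assert fp == [] and fn == []
        fp, fn = classify_at_threshold(m, ds.species_labels, 0.5)
        assert fp == [] and sorted(fn) == ["x1", "x2"]


class TestThresholdScan:
    def test_gapped_fixture_ot_inside_gap(self, two_species_dataset):
        m = distance_matrix(two_species_dataset)
        scan = threshold_scan(m, two_species_dataset.species_labels,
                              default_grid(0.001, 0.30, 0.001))
        assert scan.ce_at_optimal == 0
        assert 0.0101 < scan.optimal < 0.111

    def test_tie_break_smallest_threshold(self, two_species_dataset):
        # every t in the gap has CE = 0; smallest wins
        m = distance_matrix(two_species_dataset)
        grid = [0.02, 0.05, 0.08]
        scan = threshold_scan(m, two_species_dataset.species_labels, grid)
        assert scan.optimal == 0.02

    def test_shared_haplotype_floor_on_ce(self):
        ds = make_dataset([("x1", "A" * 100, "sp_a"),
                           ("x2", "A" * 100, "sp_b"),
                           ("x3", "G" * 20 + "A" * 80, "sp_a"),
                           ("x4", "G" * 20 + "C" * 20 + "A" * 60, "sp_b")])
        m = distance_matrix(ds)
        scan = threshold_scan(m, ds.species_labels, default_grid())
        # x1 and x2 sit at distance 0: FN at every threshold
        assert np.all(scan.fn >= 2)
        assert np.all(scan.ce >= 2)

    def test_equals_brute_force_recount(self, sim30):
        ds, _ = sim30
        m = distance_matrix(ds)
        grid = default_grid(0.005, 0.25, 0.005)
        scan = threshold_scan(m, ds.species_labels, grid)
        for k, t in enumerate(grid):
            fp, fn = brute_force_counts(m, ds.species_labels, t)
            assert scan.fp[k] == len(fp)
            assert scan.fn[k] == len(fn)
            assert scan.ce[k] == len(fp) + len(fn)
        assert scan.ce[scan.optimal_index] == scan.ce.min()

    def test_monotonicity_on_random_libraries(self):
        for seed in rng_seeds(42, 20):
            cfg = SimulationConfig(seed=int(seed), n_subfamilies=1,
                                   species_per_subfamily=6,
                                   seqs_per_species=3, alignment_length=300,
                                   target_intra=0.03, target_inter=0.15)
            ds, _ = simulate_library(cfg)
            m = distance_matrix(ds)
            scan = threshold_scan(m, ds.species_labels,
                                  default_grid(0.002, 0.2, 0.004))
            assert np.all(np.diff(scan.fp) <= 0)
            assert np.all(np.diff(scan.fn) >= 0)
            assert np.all(scan.ce == scan.fp + scan.fn)

    def test_empty_grid_rejected(self, two_species_dataset):
        m = distance_matrix(two_species_dataset)
        with pytest.raises(ValueError):
            threshold_scan(m, two_species_dataset.species_labels, [])


class TestPartitionedScan:
    def test_single_partition_matches_plain_scan(self, two_species_dataset):
        grid = default_grid()
        m = distance_matrix(two_species_dataset)
        plain = threshold_scan(m, two_species_dataset.species_labels, grid)
        parts = partitioned_scan(two_species_dataset, grid=grid)
        assert len(parts) == 1
        _, scan = parts[0]
        assert scan.optimal == plain.optimal
        assert np.array_equal(scan.ce, plain.ce)

    def test_heterogeneous_gaps_favour_partition_thresholds(self):
        """Two subfamilies with different divergence scales: per-partition
        OTs straddle their own gaps and partition CE <= family CE."""
        cfg = SimulationConfig(seed=5, n_subfamilies=2,
                               species_per_subfamily=8, seqs_per_species=3,
                               alignment_length=1500,
                               target_intra=0.015,
                               target_inter=[0.06, 0.25],
                               subfamily_branch=0.05,
                               branch_length_shape=None)
        ds, _ = simulate_library(cfg)
        grid = default_grid(0.002, 0.10, 0.002)
        m = distance_matrix(ds)
        fam = threshold_scan(m, ds.species_labels, grid)
        parts = partitioned_scan(ds, grid=grid)
        assert len(parts) == 2
        for _, scan in parts:
            assert scan.ce_at_optimal == 0
        assert sum(s.ce_at_optimal for _, s in parts) <= fam.ce_at_optimal


class TestComparison:
    def test_identical_classifications(self, two_species_dataset):
        grid = default_grid()
        m = distance_matrix(two_species_dataset)
        fam = threshold_scan(m, two_species_dataset.species_labels, grid)
        parts = partitioned_scan(two_species_dataset, grid=grid)
        cmp = compare_family_vs_partitions(fam, parts)
        assert cmp.family_ce == cmp.partition_ce_sum == 0
        assert math.isnan(cmp.t_statistic)  # all-zero indicators

    def test_partition_improvement_gives_negative_t(self):
        cfg = SimulationConfig(seed=9, n_subfamilies=2,
                               species_per_subfamily=10, seqs_per_species=3,
                               alignment_length=800,
                               target_intra=0.02,
                               target_inter=[0.05, 0.30],
                               subfamily_branch=0.05,
                               branch_length_shape=2.0)
        ds, _ = simulate_library(cfg)
        grid = default_grid(0.002, 0.10, 0.002)
        m = distance_matrix(ds)
        fam = threshold_scan(m, ds.species_labels, grid)
        parts = partitioned_scan(ds, grid=grid)
        cmp = compare_family_vs_partitions(fam, parts)
        assert cmp.partition_ce_sum <= cmp.family_ce
        if cmp.partition_ce_sum < cmp.family_ce:
            assert cmp.t_statistic < 0

    def test_percentage_worked_example(self):
        assert cumulative_error_percent(38, 59, 889) == pytest.approx(
            10.9, abs=0.05)
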