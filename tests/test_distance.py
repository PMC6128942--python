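import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcode_eval import (decompose, distance_matrix, k2p_distance,
                          p_distance, pairs_long_format)
from barcode_eval.synthetic_data import evolve, k2p_event_probabilities

from conftest import BASE, make_dataset

PURINES = {"A", "G"}


def naive_k2p(seq_a: str, seq_b: str):
    """Independent K2P oracle: explicit per-site loop."""
    n = ts = tv = 0
    for x, y in zip(seq_a, seq_b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x != y:
            if (x in PURINES) == (y in PURINES):
                ts += 1
            else:
                tv += 1
    if n == 0:
        return None
    p, q = ts / n, tv / n
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return math.nan
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


class TestK2PDistance:
    def test_identical_sequences(self):
        r = k2p_distance(BASE, BASE)
        assert (r.distance, r.p_transitions, r.q_transversions) == (0, 0, 0)
        assert r.defined and r.n_sites == len(BASE)

    def test_pure_transitions_closed_form(self):
        # P = 0.1, Q = 0 over 100 sites -> -0.5 ln(0.8)
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        r = k2p_distance(a, b)
        assert r.p_transitions == pytest.approx(0.1)
        assert r.q_transversions == 0
        assert r.distance == pytest.approx(-0.5 * math.log(0.8), rel=1e-12)

    def test_pure_transversions_closed_form(self):
        # P = 0, Q = 0.1 -> -0.5 ln(0.9) - 0.25 ln(0.8)
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        r = k2p_distance(a, b)
        assert r.distance == pytest.approx(
            -0.5 * math.log(0.9) - 0.25 * math.log(0.8), rel=1e-12)

    def test_saturation_flagged_undefined(self):
        # P = 0.3, Q = 0.45 -> 1 - 2P - Q < 0
        b = "G" * 30 + "C" * 45 + "A" * 25
        r = k2p_distance("A" * 100, b)
        assert not r.defined and math.isnan(r.distance)

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        a = "AAAA--AANA"
        b = "AAGA" + "AA" + "AA-A"
        r = k2p_distance(a, b)
        assert r.n_sites == 7  # gap/N sites on either side excluded
        assert r.p_transitions == pytest.approx(1 / 7)

    def test_zero_comparable_sites_undefined(self):
        r = k2p_distance("NNNN", "ACGT")
        assert not r.defined and r.n_sites == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance("ACGT", "ACG")

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from("ACGTN-"), min_size=20, max_size=60),
           st.lists(st.sampled_from("ACGTN-"), min_size=20, max_size=60))
    def test_matches_naive_oracle_and_is_symmetric(self, xs, ys):
        n = min(len(xs), len(ys))
        a, b = "".join(xs[:n]), "".join(ys[:n])
        r = k2p_distance(a, b)
        s = k2p_distance(b, a)
        expect = naive_k2p(a, b)
        if expect is None or math.isnan(expect):
            assert not r.defined and not s.defined
        else:
            assert r.distance == pytest.approx(expect, rel=1e-12)
            assert s.distance == pytest.approx(r.distance, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_k2p_at_least_p_distance(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 200))
        b = "".join(rng.choice(list("ACGT"), 200))
        k, p = k2p_distance(a, b), p_distance(a, b)
        if k.defined:
            assert k.distance >= p.distance - 1e-12


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        ds = make_dataset([("x1", BASE, "sp_a"), ("x2", BASE, "sp_a"),
                           ("x3", BASE, "sp_b")])
        m = distance_matrix(ds)
        assert np.all(m.d == 0)

    def test_p_distance_model(self):
        ds = make_dataset([("x1", "A" * 100, "sp_a"),
                           ("x2", "C" * 5 + "A" * 95, "sp_b")])
        m = distance_matrix(ds, model="p")
        assert m.d[0, 1] == pytest.approx(0.05)

    def test_matrix_equals_per_pair_calls(self, sim30):
        ds, _ = sim30
        m = distance_matrix(ds)
        for i in range(len(ds)):
            for j in range(i + 1, len(ds)):
                expect = k2p_distance(ds.records[i].sequence,
                                      ds.records[j].sequence)
                assert m.d[i, j] == pytest.approx(expect.distance, abs=1e-12)
                assert m.d[j, i] == m.d[i, j]
                assert m.n_sites[i, j] == expect.n_sites
        assert np.all(np.diag(m.d) == 0)

    def test_undefined_pairs_listed_not_zeroed(self):
        sat = "G" * 300 + "C" * 450 + "A" * 250
        ds = make_dataset([("x1", "A" * 1000, "sp_a"), ("x2", sat, "sp_b")])
        m = distance_matrix(ds)
        assert math.isnan(m.d[0, 1])
        assert m.undefined_pairs == [("x1", "x2")]


class TestDecompose:
    def test_constructed_means(self, two_species_dataset):
        m = distance_matrix(two_species_dataset)
        dec = decompose(m, two_species_dataset)
        s = dec.summary()
        assert s["intra"]["n"] == 2 and s["inter"]["n"] == 4
        assert s["intra"]["mean"] == pytest.approx(0.0101, abs=0.001)
        assert s["inter"]["mean"] == pytest.approx(0.115, abs=0.02)
        assert s["intra"]["n"] + s["inter"]["n"] + s["n_undefined"] == 6

    def test_all_singletons_empty_intra(self):
        ds = make_dataset([("x1", BASE, "sp_a"), ("x2", BASE, "sp_b"),
                           ("x3", BASE, "sp_c")])
        s = decompose(distance_matrix(ds), ds).summary()
        assert s["intra"]["n"] == 0 and s["intra"]["mean"] is None
        assert s["inter"]["n"] == 3

    def test_undefined_pairs_excluded_from_sets(self):
        sat = "G" * 300 + "C" * 450 + "A" * 250
        ds = make_dataset([("x1", "A" * 1000, "sp_a"), ("x2", sat, "sp_a")])
        dec = decompose(distance_matrix(ds), ds)
        assert len(dec.intra) == 0 and dec.n_undefined == 1

    def test_long_format_classes(self, two_species_dataset):
        m = distance_matrix(two_species_dataset)
        pairs = pairs_long_format(m, two_species_dataset)
        assert len(pairs) == 6
        assert (pairs["class"] == "intra").sum() == 2


class TestEstimatorConsistency:
    def test_mean_estimate_converges_to_true_distance(self):
        """Sequences evolved at known K2P distance: mean estimate within 5%
        at L = 10,000."""
        rng = np.random.default_rng(3)
        L, delta, kappa = 10_000, 0.15, 2.0
        ests = []
        for _ in range(30):
            anc = rng.integers(0, 4, size=L)
            a = evolve(anc, delta / 2, kappa, rng)
            b = evolve(anc, delta / 2, kappa, rng)
            bases = np.array(list("ACGT"))
            d = k2p_distance("".join(bases[a]), "".join(bases[b]))
            ests.append(d.distance)
        assert np.mean(ests) == pytest.approx(delta, rel=0.05)

    def test_event_probabilities_invert_through_k2p(self):
        # the generator's P,Q at distance d must map back to d exactly
        for d in (0.01, 0.1, 0.3):
            p, q = k2p_event_probabilities(d, kappa=2.0)
            est = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
            assert est == pytest.approx(d, rel=1e-9)
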