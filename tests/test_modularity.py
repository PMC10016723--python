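"""Spearman machinery and the dorsal/anal + endo/exoskeleton module tests."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from finseq import (PairingMap, dafpm_test, eem_test, smallest_specimen_sl,
                    spearman_pvalue, spearman_with_ties)
from finseq.modularity import ModularityError

from test_sequence import make_profile


def exhaustive_permutation_pvalue(rho, n):
    """Independent oracle: exact two-sided permutation p-value."""
    base = list(range(1, n + 1))
    mean = (n + 1) / 2
    var = sum((b - mean) ** 2 for b in base)
    hits = total = 0
    for perm in itertools.permutations(base):
        r = sum((b - mean) * (p - mean) for b, p in zip(base, perm)) / var
        total += 1
        hits += abs(r) >= abs(rho) - 1e-12
    return hits / total


class TestSpearman:

    def test_identity_and_reversal(self):
        x = [3.1, 7.2, 1.0, 9.9, 5.5]
        assert spearman_with_ties(x, x) == pytest.approx(1.0)
        assert spearman_with_ties(x, [-v for v in x]) == pytest.approx(-1.0)
        assert spearman_with_ties(sorted(x), sorted(x, reverse=True)) \
            == pytest.approx(-1.0)

    def test_zero_variance_is_undefined(self):
        assert math.isnan(spearman_with_ties([1, 1, 1], [1, 2, 3]))

    def test_published_radial_ossification_value(self, trout_profiles):
        # the ten paired PR-ossification SL50s, positions 2-11
        d = trout_profiles[("dorsal", 10)]
        a = trout_profiles[("anal", 10)]
        x = [d.entry(p).sl50 for p in range(2, 12)]
        y = [a.entry(p).sl50 for p in range(2, 12)]
        assert spearman_with_ties(x, y) == pytest.approx(0.9268293,
                                                         abs=5e-8)

    @given(st.lists(st.tuples(st.floats(0.001, 1), st.floats(0.001, 1)),
                    min_size=4, max_size=20))
    def test_monotone_transform_invariance_and_symmetry(self, pairs):
        x, y = zip(*pairs)
        r = spearman_with_ties(x, y)
        if math.isnan(r):
            return
        assert spearman_with_ties(y, x) == pytest.approx(r)
        assert spearman_with_ties(np.exp(x), [3 * v + 2 for v in y]) \
            == pytest.approx(r)


class TestPValues:

    def test_zero_rho_permutation_p_is_one(self):
        p, method, _ = spearman_pvalue(0.0, 5, "exact_permutation")
        assert method == "exact_permutation"
        assert p == pytest.approx(1.0)

    def test_t_and_exact_agree_on_toy_pair(self):
        x = [1.0, 2, 3, 4, 5]
        y = [1.0, 3, 4, 5, 2]
        rho = spearman_with_ties(x, y)
        p_exact, _, _ = spearman_pvalue(rho, 5, "exact_permutation")
        p_t, _, _ = spearman_pvalue(rho, 5, "t_approx")
        assert p_t == pytest.approx(p_exact, abs=0.02)

    def test_exact_matches_independent_enumeration(self):
        rho = 0.7
        p, _, _ = spearman_pvalue(rho, 6, "exact_permutation")
        assert p == pytest.approx(exhaustive_permutation_pvalue(rho, 6))

    def test_strong_large_sample_correlation_is_significant(self):
        p, method, _ = spearman_pvalue(0.9576292, 15)
        assert method == "t_approx"
        assert p < 0.001

    def test_perfect_correlation_is_flagged(self):
        p, _, perfect = spearman_pvalue(1.0, 10, "t_approx")
        assert p == 0.0 and perfect

    def test_needs_three_points(self):
        with pytest.raises(ModularityError):
            spearman_pvalue(0.5, 2)


class TestDafpm:

    def test_ray_ossification_row(self, trout_profiles):
        res = dafpm_test(trout_profiles[("dorsal", 8)],
                         trout_profiles[("anal", 8)])
        assert res.n == 15
        assert res.rho == pytest.approx(0.9576292, abs=5e-8)
        assert res.p_value < 0.001 and res.stars == "<0.001"

    def test_radial_chondrification_row(self, trout_profiles):
        res = dafpm_test(trout_profiles[("dorsal", 3)],
                         trout_profiles[("anal", 3)])
        assert res.n == 13
        assert res.rho == pytest.approx(0.9185589, abs=5e-8)

    def test_radial_apparition_needs_smallest_specimen_proxies(
            self, trout_profiles):
        res = dafpm_test(trout_profiles[("dorsal", 2)],
                         trout_profiles[("anal", 2)],
                         dorsal_proxy_size=smallest_specimen_sl("dorsal"),
                         anal_proxy_size=smallest_specimen_sl("anal"))
        assert res.n == 8
        assert res.rho == pytest.approx(0.8553628, abs=5e-8)

    def test_identical_profiles_correlate_perfectly(self):
        prof = make_profile([14.0, 12, 11, 12.5, 16])
        res = dafpm_test(prof, make_profile([14.0, 12, 11, 12.5, 16],
                                            fin="anal"))
        assert res.rho == pytest.approx(1.0)


class TestEem:

    def test_dorsal_apparition_row(self, trout_profiles):
        res = eem_test(trout_profiles[("dorsal", 5)],
                       trout_profiles[("dorsal", 4)])
        assert res.n == 14
        assert res.rho == pytest.approx(0.972, abs=5e-4)

    def test_identity_pairing_on_equal_profiles(self):
        endo = make_profile([15.0, 13, 12, 13.5, 17], series="DR")
        exo = make_profile([15.0, 13, 12, 13.5, 17])
        pairing = PairingMap(tuple((i, i) for i in range(1, 6)),
                             "published_columns")
        assert eem_test(endo, exo, pairing).rho == pytest.approx(1.0)

    def test_independent_profiles_center_on_zero(self):
        rng = np.random.default_rng(123)
        pairing = PairingMap(tuple((i, i) for i in range(1, 13)),
                             "published_columns")
        rhos = []
        for _ in range(500):
            endo = make_profile(list(rng.uniform(10, 30, 12)), series="DR")
            exo = make_profile(list(rng.uniform(10, 30, 12)))
            rhos.append(eem_test(endo, exo, pairing).rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_pairing_rejects_duplicated_elements(self):
        with pytest.raises(ModularityError):
            PairingMap(((1, 2), (1, 3)), "published_columns")

    def test_retention_drops_unrankable_pairs(self):
        endo = make_profile([15.0, 13, 12, 13.5],
                            statuses=["estimated", "nonsignificant",
                                      "estimated", "estimated"],
                            series="DR")
        exo = make_profile([14.0, 13, 12, 15, 16, 17])
        pairing = PairingMap(tuple((i, i) for i in range(1, 5)),
                             "published_columns")
        res = eem_test(endo, exo, pairing)
        assert res.n == 3  # the ns radial pair is excluded
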