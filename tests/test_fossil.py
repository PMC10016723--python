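"""Fossil fin profiles: I/O, segment-count direction calls and
bifurcation summaries."""
import numpy as np
import pytest

from finseq import (FossilFinProfile, FossilRay, bifurcation_summary,
                    read_fossil_profile, segment_profile_direction,
                    simulate_fossil_fin)
from finseq.data.synthetic_fossils import load_fossil_fixture
from finseq.fossil import FossilError, write_fossil_profile


def profile_from_counts(counts, taxon="toy", fin="dorsal"):
    return FossilFinProfile(taxon, fin, tuple(
        FossilRay(i, c) for i, c in enumerate(counts, start=1)))


def test_csv_roundtrip(tmp_path):
    prof = simulate_fossil_fin(5, 3, 6, seed=2,
                               bifurcation={"site": 4, "span": 1,
                                            "fb_min": 2, "orders": 1})
    path = tmp_path / "fossil.csv"
    write_fossil_profile(prof, path)
    back = read_fossil_profile(path)
    assert back.rays == prof.rays
    assert len(back.rays) == 5


def test_bifurcation_beyond_segment_count_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "taxon,fin,position,segment_count,first_bifurcation_segment,"
        "bifurcation_orders\nx,dorsal,1,3,4,1\n")
    with pytest.raises(FossilError, match="exceeds segment count"):
        read_fossil_profile(path)


def test_orders_zero_iff_no_first_bifurcation():
    with pytest.raises(FossilError):
        FossilRay(1, 5, None, 2)
    with pytest.raises(FossilError):
        FossilRay(1, 5, 3, 0)


class TestSegmentDirection:

    def test_coelacanth_dorsal_fin_is_bidirectional_from_l4_l7(self):
        prof = load_fossil_fixture("miguashaia", "dorsal")
        call = segment_profile_direction(prof)
        assert call.call == "bidirectional"
        assert call.site == (4, 7)

    def test_constant_counts_are_indeterminate(self):
        call = segment_profile_direction(profile_from_counts([3, 3, 3]))
        assert call.call == "indeterminate"

    def test_missing_counts_yield_indeterminate_when_too_few(self):
        prof = load_fossil_fixture("quebecius", "anal")
        assert segment_profile_direction(prof).call == "indeterminate"

    def test_mirrored_profile_swaps_ap_and_pa(self):
        swap = {"antero_posterior": "postero_anterior",
                "postero_anterior": "antero_posterior",
                "bidirectional": "bidirectional",
                "indeterminate": "indeterminate"}
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = int(rng.integers(4, 15))
            counts = [int(c) for c in rng.integers(1, 12, m)]
            a = segment_profile_direction(profile_from_counts(counts))
            b = segment_profile_direction(
                profile_from_counts(counts[::-1]))
            assert b.call == swap[a.call]

    def test_site_recovery_from_simulated_fins(self):
        # exact at zero noise; within one position at sd 0.5 in >=90%
        exact = near = 0
        for seed in range(200):
            clean = simulate_fossil_fin(20, 8, 12, decay=1.0, seed=seed)
            c0 = segment_profile_direction(clean)
            exact += c0.site == (8, 8)
            noisy = simulate_fossil_fin(20, 8, 12, decay=1.0,
                                        count_noise_sd=0.5, seed=seed)
            c1 = segment_profile_direction(noisy)
            near += (c1.site is not None
                     and c1.site[0] - 1 <= 8 <= c1.site[1] + 1)
        assert exact == 200
        assert near >= 180


class TestBifurcation:

    def test_lungfish_anal_fin_three_nested_orders(self):
        summ = bifurcation_summary(load_fossil_fixture("dipterus", "anal"))
        assert summ.max_orders == 3
        assert summ.order_ranges == ((10, 20), (11, 18), (13, 16))
        assert 13 <= summ.site[0] and summ.site[1] <= 16
        # nesting of successive orders
        for (a0, b0), (a1, b1) in zip(summ.order_ranges,
                                      summ.order_ranges[1:]):
            assert a0 <= a1 and b1 <= b0

    def test_unbranched_fin_yields_empty_summary(self):
        summ = bifurcation_summary(load_fossil_fixture("rhabdoderma"))
        assert summ.empty
        assert summ.site is None and summ.max_orders == 0

    def test_single_bifurcated_ray(self):
        prof = FossilFinProfile("toy", "anal", (
            FossilRay(1, 5), FossilRay(2, 6, 3, 2), FossilRay(3, 5)))
        summ = bifurcation_summary(prof)
        assert summ.site == (2, 2)
        assert summ.max_orders == 2

    def test_site_is_subset_of_bifurcated_rays(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            rays = []
            for pos in range(1, int(rng.integers(5, 12))):
                count = int(rng.integers(3, 10))
                if rng.random() < 0.5:
                    fb = int(rng.integers(1, count + 1))
                    rays.append(FossilRay(pos, count, fb,
                                          int(rng.integers(1, 4))))
                else:
                    rays.append(FossilRay(pos, count))
            prof = FossilFinProfile("rand", "dorsal", tuple(rays))
            if not prof.bifurcated_rays:
                continue
            summ = bifurcation_summary(prof)
            bif_pos = {r.position for r in prof.bifurcated_rays}
            assert {summ.site[0], summ.site[1]} <= bif_pos
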