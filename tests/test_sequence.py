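"""Rank sequences, initiation sites and direction-of-development calls."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from finseq import (ElementId, SL50Entry, SL50Profile, build_rank_sequence,
                    classify_direction, find_initiation_site)
from finseq.sequence import SequenceError


def make_profile(values, fin="dorsal", event=8, series="L", statuses=None):
    """Profile from a list of sl50 values (None = always_present)."""
    entries = []
    for i, v in enumerate(values, start=1):
        status = statuses[i - 1] if statuses else (
            "always_present" if v is None else "estimated")
        entries.append(SL50Entry(ElementId(fin, series, i),
                                 v if status in ("estimated",
                                                 "nonsignificant") else None,
                                 status))
    tested = sum(1 for e in entries if e.rankable)
    return SL50Profile(fin, event, tuple(entries), tested)


def brute_force_ranks(values):
    """Independent sort-and-average tied ranking."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and \
                values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def test_tied_minimum_shares_averaged_rank(trout_profiles):
    # three rays share the smallest ossification SL50 -> ranks 1-3 average
    seq = build_rank_sequence(trout_profiles[("dorsal", 8)])
    by_pos = {e.entry.element.position: e.rank for e in seq.entries}
    assert by_pos[6] == by_pos[7] == by_pos[8] == pytest.approx(2.0)


def test_single_rankable_entry_raises():
    prof = make_profile([12.0, None], statuses=["estimated", "inestimable"])
    with pytest.raises(SequenceError):
        build_rank_sequence(prof)


def test_ranks_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        m = rng.integers(3, 15)
        vals = np.round(rng.uniform(10, 30, m), rng.integers(0, 3))
        seq = build_rank_sequence(make_profile(list(vals)))
        got = [e.rank for e in sorted(seq.entries,
                                      key=lambda r: r.entry.element.position)]
        assert got == pytest.approx(brute_force_ranks(list(vals)))


@given(st.lists(st.floats(5, 45), min_size=3, max_size=12, unique=True),
       st.sampled_from([np.exp, np.cbrt, lambda v: 3 * v + 1]))
def test_rank_invariance_under_monotone_transforms(vals, f):
    seq_a = build_rank_sequence(make_profile(vals))
    seq_b = build_rank_sequence(make_profile([float(f(v)) for v in vals]))
    assert seq_a.ranks == pytest.approx(seq_b.ranks)


def test_always_present_entries_rank_first():
    prof = make_profile([15.0, None, None, 12.0, 18.0])
    seq = build_rank_sequence(prof, always_present_sizes=8.0)
    ranks = {e.entry.element.position: e.rank for e in seq.entries}
    assert ranks[2] == ranks[3] == pytest.approx(1.5)
    assert ranks[4] == 3 and ranks[1] == 4 and ranks[5] == 5
    bases = {e.entry.element.position: e.basis for e in seq.entries}
    assert bases[2] == "always_present_proxy" and bases[1] == "sl50"


class TestInitiationSite:

    def test_published_ossification_sites(self, trout_profiles):
        assert find_initiation_site(trout_profiles[("dorsal", 8)]) == (6, 8)
        assert find_initiation_site(trout_profiles[("anal", 8)]) == (5, 6)

    def test_strictly_increasing_profile_starts_anteriorly(self):
        prof = make_profile([10.0, 11, 12, 13, 14])
        assert find_initiation_site(prof) == (1, 1)

    @given(st.lists(st.floats(10, 30), min_size=3, max_size=10,
                    unique=True))
    def test_zero_tolerance_returns_argmin_run(self, vals):
        site = find_initiation_site(make_profile(vals))
        argmin = int(np.argmin(vals)) + 1
        assert site == (argmin, argmin)

    def test_always_present_elements_constitute_the_site(
            self, trout_profiles):
        assert find_initiation_site(trout_profiles[("dorsal", 2)]) == (5, 9)

    def test_plateau_tolerance_extends_the_run(self):
        prof = make_profile([14.0, 12.2, 12.0, 12.1, 15.0])
        assert find_initiation_site(prof, plateau_tol=0.0) == (3, 3)
        assert find_initiation_site(prof, plateau_tol=0.25) == (2, 4)


class TestDirection:

    def test_radial_chondrification_is_bidirectional(self, trout_profiles):
        call = classify_direction(trout_profiles[("dorsal", 3)])
        assert call.call == "bidirectional"
        assert call.initiation_site == (4, 9)

    def test_monotone_profile_is_antero_posterior(self):
        call = classify_direction(make_profile([10.0, 12, 14, 16, 18]))
        assert call.call == "antero_posterior"
        assert call.initiation_site == (1, 1)

    def test_noiseless_v_profiles_are_bidirectional(self):
        n = 9
        for site in range(2, n):  # every interior minimum
            vals = [10 + 1.5 * abs(i - site) for i in range(1, n + 1)]
            call = classify_direction(make_profile(vals))
            assert call.call == "bidirectional"
            assert call.initiation_site == (site, site)

    def test_mirror_symmetry_swaps_ap_and_pa(self):
        swap = {"antero_posterior": "postero_anterior",
                "postero_anterior": "antero_posterior",
                "bidirectional": "bidirectional",
                "indeterminate": "indeterminate"}
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = rng.integers(4, 12)
            vals = list(np.round(rng.uniform(10, 30, m), 2))
            a = classify_direction(make_profile(vals))
            b = classify_direction(make_profile(vals[::-1]))
            assert b.call == swap[a.call]

    def test_too_few_entries_raise(self):
        with pytest.raises(SequenceError):
            classify_direction(make_profile([10.0, 12.0]))
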