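"""Rank developmental sequences, initiation sites and direction calls.

A fin's SL50 profile is converted into a rank sequence (smaller SL50 =
earlier development, average ranks for ties).  The initiation site is the
contiguous run of elements with the smallest SL50 — or the always-present
elements, which developed before the smallest surveyed specimen.  The
direction of development (bidirectional / antero-posterior /
postero-anterior) is called from the monotone trend of SL50 with distance
from the site on each flank, quantified by Spearman correlation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coding import SL50Entry, SL50Profile

DIRECTIONS = ("bidirectional", "antero_posterior", "postero_anterior",
              "indeterminate")


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class RankEntry:
    entry: SL50Entry
    rank: float
    basis: str  # 'sl50' or 'always_present_proxy'


@dataclass(frozen=True)
class RankSequence:
    fin: str
    event: int
    entries: tuple[RankEntry, ...]

    def __post_init__(self):
        m = len(self.entries)
        total = sum(e.rank for e in self.entries)
        if abs(total - m * (m + 1) / 2) > 1e-9:
            raise SequenceError("ranks are not a valid tied-rank vector")

    @property
    def ranks(self) -> np.ndarray:
        return np.array([e.rank for e in self.entries])


@dataclass(frozen=True)
class DirectionCall:
    call: str
    initiation_site: tuple[int, int] | None  # inclusive position range
    anterior_trend: float  # Spearman rho of sl50 vs distance (nan if <2)
    posterior_trend: float
    n_anterior: int = 0
    n_posterior: int = 0


def build_rank_sequence(profile: SL50Profile,
                        include_nonsignificant: bool = False,
                        always_present_sizes=None) -> RankSequence:
    """Rank the profile's elements by ascending SL50, ties averaged.

    Only significant (estimated) entries are ranked by default; pass
    ``include_nonsignificant=True`` to keep flagged entries.  When
    ``always_present_sizes`` is given (a scalar proxy size or one size per
    always-present element), those elements are ranked ahead of every
    fitted entry — they had already developed in the smallest specimens —
    tied among themselves unless distinct proxy sizes are supplied.
    Inestimable and never_reached entries are excluded.
    """
    wanted = ["estimated"] + (
        ["nonsignificant"] if include_nonsignificant else [])
    fitted = [e for e in profile.entries if e.status in wanted]
    ap = profile.with_status("always_present") \
        if always_present_sizes is not None else []
    if len(fitted) + len(ap) < 2:
        raise SequenceError("fewer than 2 rankable entries")

    entries: list[RankEntry] = []
    if ap:
        proxies = np.broadcast_to(
            np.asarray(always_present_sizes, float), (len(ap),))
        ap_ranks = stats.rankdata(proxies, method="average")
        for e, r in zip(ap, ap_ranks):
            entries.append(RankEntry(e, float(r), "always_present_proxy"))
    if fitted:
        vals = np.array([e.sl50 for e in fitted])
        ranks = stats.rankdata(vals, method="average") + len(ap)
        for e, r in zip(fitted, ranks):
            entries.append(RankEntry(e, float(r), "sl50"))
    entries.sort(key=lambda re: re.entry.element.position)
    return RankSequence(profile.fin, profile.event, tuple(entries))


def find_initiation_site(profile: SL50Profile, plateau_tol: float = 0.0
                         ) -> tuple[int, int]:
    """Locate the initiation site as an inclusive position range.

    Always-present elements, when any exist, constitute the site — they
    preceded every estimate.  Otherwise the site is the maximal contiguous
    run of estimated elements whose SL50 is within ``plateau_tol`` mm of
    the minimum (exact ties only by default).
    """
    ap = profile.with_status("always_present")
    if ap:
        pos = [e.element.position for e in ap]
        return min(pos), max(pos)
    est = profile.with_status("estimated")
    if not est:
        raise SequenceError("no estimated entries")
    lo = min(e.sl50 for e in est)
    members = {e.element.position for e in est
               if e.sl50 <= lo + plateau_tol}
    present = [e.element.position for e in est]
    runs = _contiguous_runs(sorted(members), present)
    center = (present[0] + present[-1]) / 2

    # maximal run; ties resolved toward the overall minimum, then the
    # profile centre (mirror-symmetric), then anteriorly
    def run_key(run):
        vals = [e.sl50 for e in est
                if run[0] <= e.element.position <= run[1]]
        return (run[1] - run[0], -min(vals),
                -abs((run[0] + run[1]) / 2 - center), -run[0])
    return max(runs, key=run_key)


def _contiguous_runs(members, present_positions):
    """Group member positions into runs contiguous within the profile's
    own position grid (gaps from excluded elements do not break a run
    only if no intervening profile element exists)."""
    present = sorted(present_positions)
    runs, cur = [], [members[0]]
    for p in members[1:]:
        prev = cur[-1]
        between = [q for q in present if prev < q < p]
        if not between:
            cur.append(p)
        else:
            runs.append((cur[0], cur[-1]))
            cur = [p]
    runs.append((cur[0], cur[-1]))
    return runs


def _flank_trend(entries, site, anterior: bool):
    """Spearman rho of SL50 vs distance from the site on one flank."""
    lo, hi = site
    if anterior:
        flank = [e for e in entries if e.element.position < lo]
        dist = [lo - e.element.position for e in flank]
    else:
        flank = [e for e in entries if e.element.position > hi]
        dist = [e.element.position - hi for e in flank]
    if len(flank) < 2:
        return (np.nan, len(flank), flank)
    vals = [e.sl50 for e in flank]
    if min(vals) == max(vals):  # constant flank: trend undefined
        return (np.nan, len(flank), flank)
    rho = stats.spearmanr(vals, dist).statistic
    return (float(rho), len(flank), flank)


def classify_direction(profile: SL50Profile, min_flank: int = 1,
                       trend_threshold: float = 0.5,
                       plateau_tol: float = 0.0) -> DirectionCall:
    """Call the direction of development of a profile.

    The initiation site is located first; each flank then qualifies when
    it holds at least ``min_flank`` elements whose SL50 increases with
    distance from the site (Spearman rho >= ``trend_threshold``; a
    single-element flank qualifies when its SL50 is not below the site's).
    Both flanks qualifying is bidirectional; a qualifying posterior flank
    with no anterior elements is antero-posterior, and symmetrically;
    anything else is indeterminate.
    """
    est = profile.with_status("estimated")
    ap = profile.with_status("always_present")
    if len(est) + len(ap) < 3:
        raise SequenceError("need at least 3 estimated entries")
    site = find_initiation_site(profile, plateau_tol)
    site_max = max((e.sl50 for e in est
                    if site[0] <= e.element.position <= site[1]),
                   default=None)  # None when the site is always-present
    a_rho, n_a, a_flank = _flank_trend(est, site, anterior=True)
    p_rho, n_p, p_flank = _flank_trend(est, site, anterior=False)

    def qualifies(rho, n, flank):
        if n < min_flank or n == 0:
            return False
        if n == 1:
            return site_max is None or flank[0].sl50 >= site_max
        return rho >= trend_threshold

    a_ok = qualifies(a_rho, n_a, a_flank)
    p_ok = qualifies(p_rho, n_p, p_flank)
    if a_ok and p_ok:
        call = "bidirectional"
    elif p_ok and n_a == 0:
        call = "antero_posterior"
    elif a_ok and n_p == 0:
        call = "postero_anterior"
    else:
        call = "indeterminate"
    return DirectionCall(call, site, a_rho, p_rho, n_a, n_p)


def sequence_report(seq: RankSequence) -> list[dict]:
    return [{"element": e.entry.element.label,
             "sl50": e.entry.sl50,
             "rank": e.rank,
             "basis": e.basis} for e in seq.entries]
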