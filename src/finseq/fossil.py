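"""Direction-of-development inference from fossil fin ray profiles.

Fossil fins preserve individual developmental history in their rays:
segments are added distally through growth, so the rays with the most
segments started segmenting first, and the location of the longest rays
marks the initiation site of segmentation.  Bifurcation (distal branching,
possibly in successive orders) leaves an analogous record: the rays whose
first bifurcation sits most proximally branched first.  This module
formalizes both readings for per-ray profiles of segment counts and
first-bifurcation positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sequence import DIRECTIONS


class FossilError(ValueError):
    pass


@dataclass(frozen=True)
class FossilRay:
    """One lepidotrichium: ``segment_count`` may be missing (preservation),
    ``first_bifurcation_segment`` is the 1-based segment carrying the most
    proximal branching, absent iff ``bifurcation_orders`` is 0."""
    position: int
    segment_count: int | None = None
    first_bifurcation_segment: int | None = None
    bifurcation_orders: int = 0

    def __post_init__(self):
        if self.position < 1:
            raise FossilError("ray position must be >= 1")
        if self.segment_count is not None and self.segment_count < 1:
            raise FossilError("segment_count must be >= 1")
        fb = self.first_bifurcation_segment
        if (fb is None) != (self.bifurcation_orders == 0):
            raise FossilError(
                f"ray {self.position}: bifurcation_orders is 0 iff "
                "first_bifurcation_segment is absent")
        if fb is not None:
            if fb < 1:
                raise FossilError("first_bifurcation_segment must be >= 1")
            if self.segment_count is not None and fb > self.segment_count:
                raise FossilError(
                    f"ray {self.position}: bifurcation at segment {fb} "
                    f"exceeds segment count {self.segment_count}")


@dataclass(frozen=True)
class FossilFinProfile:
    taxon: str
    fin: str
    rays: tuple[FossilRay, ...]
    total_length: float | None = None  # TL, mm
    notes: str = ""

    def __post_init__(self):
        pos = [r.position for r in self.rays]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise FossilError("rays must be ordered by unique position")

    @property
    def counted_rays(self) -> list[FossilRay]:
        return [r for r in self.rays if r.segment_count is not None]

    @property
    def bifurcated_rays(self) -> list[FossilRay]:
        return [r for r in self.rays if r.bifurcation_orders > 0]


@dataclass(frozen=True)
class SegmentDirectionCall:
    call: str
    site: tuple[int, int] | None  # inclusive ray-position range
    anterior_trend: float
    posterior_trend: float
    n_anterior: int = 0
    n_posterior: int = 0


@dataclass(frozen=True)
class BifurcationSummary:
    site: tuple[int, int] | None  # range of most-proximal first bifurcation
    max_orders: int
    order_ranges: tuple[tuple[int, int], ...] = field(default=())

    @property
    def empty(self) -> bool:
        return self.max_orders == 0


def read_fossil_profile(path) -> FossilFinProfile:
    """Read a per-ray CSV with columns ``taxon, fin, position,
    segment_count, first_bifurcation_segment, bifurcation_orders`` (and
    optionally ``total_length_mm``); blank cells are missing."""
    f = pd.read_csv(path)
    required = ["taxon", "fin", "position"]
    missing = [c for c in required if c not in f.columns]
    if missing:
        raise FossilError(f"missing columns: {missing}")
    taxa = f.taxon.unique()
    fins = f.fin.unique()
    if len(taxa) != 1 or len(fins) != 1:
        raise FossilError("a profile file holds exactly one taxon and fin")
    tl = None
    if "total_length_mm" in f.columns and f.total_length_mm.notna().any():
        tl = float(f.total_length_mm.dropna().iloc[0])

    def _opt(v):
        return None if pd.isna(v) else int(v)

    rays = []
    for r in f.sort_values("position").itertuples():
        rays.append(FossilRay(
            position=int(r.position),
            segment_count=_opt(getattr(r, "segment_count", np.nan)),
            first_bifurcation_segment=_opt(
                getattr(r, "first_bifurcation_segment", np.nan)),
            bifurcation_orders=int(getattr(r, "bifurcation_orders", 0) or 0),
        ))
    return FossilFinProfile(str(taxa[0]), str(fins[0]), tuple(rays), tl)


def write_fossil_profile(profile: FossilFinProfile, path) -> None:
    rows = [{
        "taxon": profile.taxon,
        "fin": profile.fin,
        "position": r.position,
        "segment_count": r.segment_count,
        "first_bifurcation_segment": r.first_bifurcation_segment,
        "bifurcation_orders": r.bifurcation_orders,
        "total_length_mm": profile.total_length,
    } for r in profile.rays]
    pd.DataFrame(rows).to_csv(path, index=False)


def segment_profile_direction(profile: FossilFinProfile,
                              plateau_tol: int = 0,
                              trend_threshold: float = 0.5,
                              min_flank: int = 1) -> SegmentDirectionCall:
    """Direction of segmentation from per-ray segment counts.

    The site is the maximal contiguous run of rays with count within
    ``plateau_tol`` segments of the maximum (the longest rays segmented
    first); each flank's trend is the Spearman correlation of count with
    distance from the site — development spreading away from the site
    shows counts decreasing, i.e. rho <= -threshold.  Rays with missing
    counts are skipped.  All counts equal, or fewer than 3 usable rays,
    is indeterminate.
    """
    rays = profile.counted_rays
    if len(rays) < 3:
        return SegmentDirectionCall("indeterminate", None,
                                    float("nan"), float("nan"))
    counts = {r.position: r.segment_count for r in rays}
    top = max(counts.values())
    if top == min(counts.values()):
        return SegmentDirectionCall("indeterminate", None,
                                    float("nan"), float("nan"))
    members = sorted(p for p, c in counts.items() if c >= top - plateau_tol)
    site = _longest_run(members, sorted(counts), counts)
    lo, hi = site
    site_min = min(c for p, c in counts.items() if lo <= p <= hi)

    def flank(anterior: bool):
        if anterior:
            sel = [(lo - p, c) for p, c in counts.items() if p < lo]
        else:
            sel = [(p - hi, c) for p, c in counts.items() if p > hi]
        if len(sel) < 2:
            return float("nan"), len(sel), sel
        d, c = zip(*sel)
        if min(c) == max(c):  # constant flank: trend undefined
            return float("nan"), len(sel), sel
        rho = stats.spearmanr(c, [-x for x in d]).statistic
        return float(rho), len(sel), sel

    a_rho, n_a, a_sel = flank(True)
    p_rho, n_p, p_sel = flank(False)

    def qualifies(rho, n, sel):
        if n < min_flank or n == 0:
            return False
        if n == 1:
            return sel[0][1] <= site_min
        return rho >= trend_threshold

    a_ok = qualifies(a_rho, n_a, a_sel)
    p_ok = qualifies(p_rho, n_p, p_sel)
    if a_ok and p_ok:
        call = "bidirectional"
    elif p_ok and n_a == 0:
        call = "antero_posterior"
    elif a_ok and n_p == 0:
        call = "postero_anterior"
    else:
        call = "indeterminate"
    assert call in DIRECTIONS
    return SegmentDirectionCall(call, site, a_rho, p_rho, n_a, n_p)


def _longest_run(members, present, values):
    runs, cur = [], [members[0]]
    for p in members[1:]:
        between = [q for q in present if cur[-1] < q < p]
        if not between:
            cur.append(p)
        else:
            runs.append((cur[0], cur[-1]))
            cur = [p]
    runs.append((cur[0], cur[-1]))
    center = (present[0] + present[-1]) / 2

    # longest run; ties resolved toward the profile's centre (a
    # mirror-symmetric choice), then anteriorly
    def key(run):
        return (run[1] - run[0],
                -abs((run[0] + run[1]) / 2 - center),
                -run[0])
    return max(runs, key=key)


def bifurcation_summary(profile: FossilFinProfile) -> BifurcationSummary:
    """Summarize the bifurcation record of a fin.

    The site is the ray-position range attaining the most proximal
    (minimal) first-bifurcation segment; per-order ranges span the rays
    reaching each successive order of branching.  A fin with no
    bifurcated rays yields an empty summary.
    """
    bif = profile.bifurcated_rays
    if not bif:
        return BifurcationSummary(None, 0)
    max_orders = max(r.bifurcation_orders for r in bif)
    ranges = []
    for order in range(1, max_orders + 1):
        pos = [r.position for r in bif if r.bifurcation_orders >= order]
        ranges.append((min(pos), max(pos)))
    fb_min = min(r.first_bifurcation_segment for r in bif)
    at = [r.position for r in bif if r.first_bifurcation_segment == fb_min]
    return BifurcationSummary((min(at), max(at)), max_orders, tuple(ranges))
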