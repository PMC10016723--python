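"""Schematic SYNTHETIC reconstructions of the surveyed fossil fins.

The per-ray measurements of the fossil specimens are not published; what
is published are descriptive ranges — which rays are longest (most
segments), where the most proximal bifurcations sit, which rays reach
each order of branching, and the ray counts.  The profiles built here are
synthetic stand-ins consistent with those ranges: segment counts peak on
the reported longest-ray interval and decrease bilaterally; first
bifurcations are most proximal on the reported interval and move distally
away from it; order ranges are nested exactly as reported.  They support
the direction and bifurcation-site inferences, not any quantitative claim
about individual specimens.
"""
from __future__ import annotations

import math

from ..fossil import FossilFinProfile, FossilRay

_TAXA = ("elonichthys", "miguashaia", "rhabdoderma", "quebecius",
         "dipterus", "eusthenopteron")


def _schematic(taxon, fin, n_rays, seg_site, max_count, decay=1.0,
               min_count=1, order_ranges=(), fb_site=None, fb_min=2,
               counts_known=True, notes=""):
    lo, hi = seg_site
    rays = []
    for pos in range(1, n_rays + 1):
        if counts_known:
            d = 0 if lo <= pos <= hi else min(abs(pos - lo), abs(pos - hi))
            # floor keeps the reported longest-ray interval an exact plateau
            count = max(min_count, math.floor(max_count - decay * d))
        else:
            count = None
        orders = sum(1 for (a, b) in order_ranges if a <= pos <= b)
        fb = None
        if orders > 0:
            fa, fbz = fb_site
            df = 0 if fa <= pos <= fbz else min(abs(pos - fa),
                                                abs(pos - fbz))
            fb = fb_min + df
            if count is not None:
                fb = min(fb, count)
        rays.append(FossilRay(pos, count, fb, orders))
    return FossilFinProfile(taxon, fin, tuple(rays), notes=notes)


def elonichthys(fin: str = "dorsal") -> FossilFinProfile:
    """Carboniferous 'palaeonisciform' actinopterygian; longest rays
    anterior (L7-15 dorsal, L10-13 anal), 4-7 segments, no bifurcation."""
    if fin == "dorsal":
        return _schematic("elonichthys", fin, 40, (7, 15), 7, decay=0.25,
                          min_count=4)
    return _schematic("elonichthys", fin, 47, (10, 13), 7, decay=0.25,
                      min_count=4)


def miguashaia(fin: str = "dorsal") -> FossilFinProfile:
    """Devonian coelacanth; longest rays L4-7 (dorsal) / L5-8 (anal),
    most proximal bifurcations about L12-15, up to three orders."""
    if fin == "dorsal":
        return _schematic("miguashaia", fin, 28, (4, 7), 9, decay=0.5,
                          min_count=4,
                          order_ranges=((8, 24), (10, 20), (12, 15)),
                          fb_site=(12, 15))
    return _schematic("miguashaia", fin, 25, (5, 8), 9, decay=0.5,
                      min_count=4,
                      order_ranges=((9, 22), (11, 19), (12, 15)),
                      fb_site=(12, 15))


def rhabdoderma(fin: str = "dorsal") -> FossilFinProfile:
    """Carboniferous coelacanth; longest rays L9-12 in both fins,
    no bifurcation in any specimen."""
    n = 21
    return _schematic("rhabdoderma", fin, n, (9, 12), 13, decay=0.5,
                      min_count=5)


def quebecius(fin: str = "dorsal") -> FossilFinProfile:
    """Devonian porolepiform; segment counts unreadable (preservation),
    most proximal bifurcations L18-21."""
    n = 35 if fin == "dorsal" else 34
    return _schematic("quebecius", fin, n, (1, 1), 1, counts_known=False,
                      order_ranges=((15, 28),), fb_site=(18, 21),
                      notes="segment counts unclear owing to preservation")


def dipterus(fin: str = "dorsal") -> FossilFinProfile:
    """Devonian lungfish; segmentation sites differ between fins (dorsal
    L16-26, anal L8-12); anal fin with three nested orders of bifurcation
    (L10-20 / L11-18 / L13-16), most proximal first bifurcations in
    L13-16; dorsal with two orders (L15-42 / L28-39), most proximal in
    L36-37."""
    if fin == "dorsal":
        return _schematic("dipterus", fin, 44, (16, 26), 20, decay=0.5,
                          min_count=4,
                          order_ranges=((15, 42), (28, 39)),
                          fb_site=(36, 37))
    return _schematic("dipterus", fin, 25, (8, 12), 16, decay=0.5,
                      min_count=4,
                      order_ranges=((10, 20), (11, 18), (13, 16)),
                      fb_site=(13, 16))


def eusthenopteron(fin: str = "dorsal") -> FossilFinProfile:
    """Devonian 'osteolepiform'; first segmentation L11-14 (dorsal) /
    L8-13 (anal), bifurcations initiated posterior to the segmentation
    site with successive orders nested around it."""
    if fin == "dorsal":
        return _schematic("eusthenopteron", fin, 26, (11, 14), 10,
                          decay=0.5, min_count=2,
                          order_ranges=((7, 25), (9, 17)),
                          fb_site=(13, 17))
    return _schematic("eusthenopteron", fin, 25, (8, 13), 10, decay=0.5,
                      min_count=2,
                      order_ranges=((6, 25), (13, 18), (15, 17)),
                      fb_site=(15, 17))


def load_fossil_fixture(taxon: str, fin: str = "dorsal"
                        ) -> FossilFinProfile:
    """Profile for one of the six surveyed taxa ('elonichthys',
    'miguashaia', 'rhabdoderma', 'quebecius', 'dipterus',
    'eusthenopteron')."""
    if taxon not in _TAXA:
        raise ValueError(f"unknown taxon {taxon!r}; choose from {_TAXA}")
    return globals()[taxon](fin)
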