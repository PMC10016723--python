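"""Synthetic ontogenies with the statistical structure the analysis assumes.

The generator emulates a cleared-and-stained growth series: each serial
element has a true SL50 following a spatial gradient from an initiation
site (V-shaped for bidirectional development, monotone for AP/PA), and
each later event of the same element is offset to larger sizes
(apparition before chondrification before segmentation before
ossification).  A specimen attains an event's state when its standard
length exceeds a latent threshold

    T = true_sl50(element) + event_offset + e,   e ~ Logistic(0, s)

with one deviate ``e`` shared per (specimen, element) across events, so
the within-element ontogenetic order holds by construction — an element
is never ossified before it exists.  Under this model the per-event
attainment probability is exactly the logistic law fitted downstream,
with slope 1/s.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import (EVENT_NAMES, EVENT_SERIES, EventCodingTable,
                     coding_table_from_rows)
from .fossil import FossilFinProfile, FossilRay

DIRECTIONS = ("bidirectional", "AP", "PA")


@dataclass(frozen=True)
class SimConfig:
    """Study design of a simulated growth series.

    Defaults mirror the trout survey: ~80 specimens spanning 8-50 mm SL,
    15 serial elements with a central initiation site, a trout-like
    spatial gradient of ~0.8 mm per element step and event offsets on the
    scale of the published SL50 differences between events.
    ``noise_scale`` is the scale parameter s of the logistic threshold
    noise (mm); the induced logistic-regression slope is 1/s.
    """
    n_elements: int = 15
    site_position: int = 8
    direction: str = "bidirectional"
    base_sl50: float = 14.0
    gradient: float = 0.8
    event_offsets: dict = field(default_factory=lambda: {
        4: 0.0,    # ray apparition
        7: 4.0,    # ray segmentation
        8: 6.0,    # ray ossification
    })
    noise_scale: float = 1.5
    specimen_sizes: tuple = (80, 8.0, 50.0)  # (n, min, max) or explicit
    dropout_rate: float = 0.0
    seed: int = 0
    fin: str = "dorsal"

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not (1 <= self.site_position <= self.n_elements):
            raise ValueError("site_position outside 1..n_elements")
        if self.gradient < 0:
            raise ValueError("gradient must be >= 0")
        if not self.noise_scale > 0:
            raise ValueError("noise_scale must be > 0")
        offs = [self.event_offsets[c] for c in sorted(self.event_offsets)]
        if any(o < 0 for o in offs):
            raise ValueError("event offsets must be non-negative")
        if offs != sorted(offs):
            raise ValueError(
                "event offsets must be non-decreasing in event order")

    def sizes(self, rng: np.random.Generator) -> np.ndarray:
        if len(self.specimen_sizes) == 3 and np.isscalar(
                self.specimen_sizes[0]):
            n, lo, hi = self.specimen_sizes
            if float(n) == int(n) and int(n) > 3:
                return rng.uniform(float(lo), float(hi), int(n))
        return np.asarray(self.specimen_sizes, float)


def make_sl50_profile(config: SimConfig, event: int) -> np.ndarray:
    """True SL50 vector of one event, element positions 1..n.

    bidirectional: base + gradient*|i - site| + offset;
    AP: base + gradient*(i-1) + offset; PA mirrored.
    """
    offset = config.event_offsets.get(event, 0.0)
    i = np.arange(1, config.n_elements + 1, dtype=float)
    if config.direction == "bidirectional":
        dist = np.abs(i - config.site_position)
    elif config.direction == "AP":
        dist = i - 1
    else:  # PA
        dist = config.n_elements - i
    return config.base_sl50 + config.gradient * dist + offset


def simulate_coding(config: SimConfig, events=None) -> EventCodingTable:
    """Generate a validated event-coding table.

    One logistic deviate per (specimen, element) is shared across events,
    offset per event; state = 1 iff SL >= threshold.  Optional uniform
    dropout replaces states with missing.  Fully reproducible from
    ``config.seed``.
    """
    events = sorted(events if events is not None else config.event_offsets)
    for ev in events:
        if ev not in EVENT_NAMES:
            raise ValueError(f"unknown event {ev}")
    rng = np.random.default_rng(config.seed)
    sizes = config.sizes(rng)
    n_spec = len(sizes)
    deviates = rng.logistic(0.0, config.noise_scale,
                            size=(n_spec, config.n_elements))
    rows = []
    base = make_sl50_profile(config, events[0]) \
        - config.event_offsets.get(events[0], 0.0)
    for ev in events:
        series = EVENT_SERIES[ev]
        offset = config.event_offsets.get(ev, 0.0)
        thresholds = base[None, :] + offset + deviates
        states = (sizes[:, None] >= thresholds).astype(float)
        if config.dropout_rate > 0:
            drop = rng.random(states.shape) < config.dropout_rate
        else:
            drop = np.zeros(states.shape, bool)
        for j in range(n_spec):
            sid = f"S{j + 1:03d}"
            for i in range(config.n_elements):
                state = None if drop[j, i] else states[j, i]
                rows.append((sid, sizes[j], config.fin, ev, series, i + 1,
                             state))
    return coding_table_from_rows(rows)


def simulate_fossil_fin(n_rays: int, site: int, max_count: int,
                        decay: float = 1.0, count_noise_sd: float = 0.0,
                        direction: str = "bidirectional",
                        bifurcation: dict | None = None,
                        seed: int = 0,
                        taxon: str = "synthetic",
                        fin: str = "dorsal") -> FossilFinProfile:
    """Generate a per-ray fossil fin profile with a known direction.

    Segment counts decrease away from the site (rounded, floored at 1,
    optional Gaussian noise).  ``bifurcation``, when given, is a dict with
    keys ``site`` (ray position), ``span`` (rays on each side of it that
    bifurcate), ``fb_min`` (most proximal first-bifurcation segment) and
    optionally ``orders`` — first-bifurcation positions grow with distance
    from the bifurcation site, which sits posterior to the segmentation
    site in the observed fossils.
    """
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    rng = np.random.default_rng(seed)
    i = np.arange(1, n_rays + 1, dtype=float)
    if direction == "bidirectional":
        dist = np.abs(i - site)
    elif direction == "AP":
        dist = i - 1
    else:
        dist = n_rays - i
    noise = rng.normal(0.0, count_noise_sd, n_rays) if count_noise_sd > 0 \
        else np.zeros(n_rays)
    counts = np.maximum(1, np.rint(max_count - decay * dist + noise)
                        ).astype(int)
    rays = []
    for k, pos in enumerate(range(1, n_rays + 1)):
        fb = orders = None
        if bifurcation is not None:
            bsite = bifurcation["site"]
            span = bifurcation.get("span", 3)
            fb_min = bifurcation.get("fb_min", 2)
            d = abs(pos - bsite)
            if d <= span:
                fb = min(int(fb_min + d), int(counts[k]))
                orders = max(1, int(bifurcation.get("orders", 1)) - d // 2)
        rays.append(FossilRay(pos, int(counts[k]), fb, orders or 0))
    return FossilFinProfile(taxon, fin, tuple(rays))
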