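"""Spearman tests of developmental modularity between rank sequences.

Two modules are tested.  The dorsal-anal fin patterning module (DAFPM):
homologous serial elements of the two fins develop in correlated order —
tested by pairing elements of the same series positionally across fins.
The endoskeleton-exoskeleton module (EEM): radials and lepidotrichia of
one fin develop in correlated order — tested by pairing radial i with the
lepidotrichium articulating at its column in the published layout
(lepidotrichium i+2 by default).

A pair enters the correlation only when both members are rankable
(significant SL50, or always-present with a proxy size); ranks are then
recomputed within the retained subset.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coding import SL50Profile

#: Radial column offset of the published table layout: radial i
#: articulates at the column of lepidotrichium i + 2 in both fins.
PUBLISHED_COLUMN_OFFSET = 2

EXACT_PERMUTATION_MAX_N = 7


class ModularityError(ValueError):
    pass


@dataclass(frozen=True)
class PairingMap:
    """Ordered (position_a, position_b) element pairing between two
    profiles; each position appears at most once per side."""
    pairs: tuple[tuple[int, int], ...]
    scheme: str  # 'positional_same_series' or 'published_columns'

    def __post_init__(self):
        for side in (0, 1):
            seen = [p[side] for p in self.pairs]
            if len(set(seen)) != len(seen):
                raise ModularityError("element repeated within one side")

    @classmethod
    def positional(cls, profile_a: SL50Profile, profile_b: SL50Profile
                   ) -> "PairingMap":
        pos_a = {e.element.position for e in profile_a.entries}
        pos_b = {e.element.position for e in profile_b.entries}
        common = sorted(pos_a & pos_b)
        return cls(tuple((p, p) for p in common), "positional_same_series")

    @classmethod
    def column_aligned(cls, radial_profile: SL50Profile,
                      ray_profile: SL50Profile,
                      offset: int = PUBLISHED_COLUMN_OFFSET) -> "PairingMap":
        ray_pos = {e.element.position for e in ray_profile.entries}
        pairs = [(e.element.position, e.element.position + offset)
                 for e in radial_profile.entries
                 if e.element.position + offset in ray_pos]
        return cls(tuple(pairs), "published_columns")


@dataclass(frozen=True)
class CorrelationResult:
    module_tested: str  # 'DAFPM' or 'EEM'
    n: int
    rho: float
    p_value: float | None
    method: str  # 't_approx' or 'exact_permutation'
    perfect: bool = False  # |rho| = 1 under t approximation

    @property
    def stars(self) -> str:
        if self.p_value is None:
            return "NA"
        for cut, s in ((0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05")):
            if self.p_value < cut:
                return s
        return "ns"


def spearman_with_ties(x, y) -> float:
    """Spearman rho: Pearson correlation of average-tied ranks.

    Returns NaN when either side has zero rank variance (undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ModularityError("need two equal-length vectors of length >= 2")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_pvalue(rho: float, n: int, method: str = "auto"
                    ) -> tuple[float, str, bool]:
    """Two-sided p-value for an observed Spearman rho.

    't_approx' uses t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df;
    'exact_permutation' enumerates all n! rank permutations (n <= 7).
    'auto' picks the exact enumeration for small n.  Returns
    (p, method_used, perfect_flag) — the flag marks |rho| = 1 under the
    t approximation, where p degenerates to 0.
    """
    if n < 3:
        raise ModularityError("p-value needs n >= 3")
    if math.isnan(rho):
        raise ModularityError("rho is undefined")
    if method == "auto":
        method = ("exact_permutation" if n <= EXACT_PERMUTATION_MAX_N
                  else "t_approx")
    if method == "t_approx":
        if abs(rho) >= 1.0 - 1e-12:
            return 0.0, method, True
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2 * stats.t.sf(abs(t), df=n - 2)), method, False
    if method == "exact_permutation":
        if n > EXACT_PERMUTATION_MAX_N:
            raise ModularityError(
                f"exact permutation limited to n <= {EXACT_PERMUTATION_MAX_N}")
        # untied ranks: rho = (12*S - 3n(n+1)^2)/(n^3 - n), S = sum(i*perm_i)
        base = tuple(range(1, n + 1))
        denom = n ** 3 - n
        const = 3 * n * (n + 1) ** 2
        count = total = 0
        thresh = abs(rho) - 1e-12
        for perm in itertools.permutations(base):
            s = sum(i * p for i, p in zip(base, perm))
            r = (12 * s - const) / denom
            total += 1
            if abs(r) >= thresh:
                count += 1
        return count / total, method, False
    raise ModularityError(f"unknown method {method!r}")


def _rankable_values(profile: SL50Profile, proxy_size: float | None
                     ) -> dict[int, float]:
    """position -> orderable value: SL50 for estimated entries, the proxy
    size for always-present entries when a proxy is supplied."""
    out = {}
    for e in profile.entries:
        if e.status == "estimated":
            out[e.element.position] = e.sl50
        elif e.status == "always_present" and proxy_size is not None:
            out[e.element.position] = float(proxy_size)
    return out


def _paired_correlation(profile_a: SL50Profile, profile_b: SL50Profile,
                        pairing: PairingMap, module: str,
                        proxy_a: float | None = None,
                        proxy_b: float | None = None,
                        p_method: str = "auto") -> CorrelationResult:
    va = _rankable_values(profile_a, proxy_a)
    vb = _rankable_values(profile_b, proxy_b)
    kept = [(va[pa], vb[pb]) for pa, pb in pairing.pairs
            if pa in va and pb in vb]
    n = len(kept)
    if n < 2:
        raise ModularityError(f"{module}: fewer than 2 retained pairs")
    x, y = zip(*kept)
    rho = spearman_with_ties(x, y)
    if n < 3 or math.isnan(rho):
        return CorrelationResult(module, n, rho, None, "none")
    p, method, perfect = spearman_pvalue(rho, n, p_method)
    return CorrelationResult(module, n, rho, p, method, perfect)


def dafpm_test(dorsal_profile: SL50Profile, anal_profile: SL50Profile,
               pairing: PairingMap | None = None,
               dorsal_proxy_size: float | None = None,
               anal_proxy_size: float | None = None,
               p_method: str = "auto") -> CorrelationResult:
    """Dorsal-vs-anal congruence of one event's developmental sequence.

    Default pairing is positional within the shared series.  Proxy sizes
    (the smallest specimen SL of each fin) admit always-present elements,
    ranked first, as in the published analysis of radial apparition.
    """
    pairing = pairing or PairingMap.positional(dorsal_profile, anal_profile)
    return _paired_correlation(dorsal_profile, anal_profile, pairing,
                               "DAFPM", dorsal_proxy_size, anal_proxy_size,
                               p_method)


def eem_test(endo_profile: SL50Profile, exo_profile: SL50Profile,
             pairing: PairingMap | None = None,
             endo_proxy_size: float | None = None,
             exo_proxy_size: float | None = None,
             p_method: str = "auto") -> CorrelationResult:
    """Endoskeleton-vs-exoskeleton congruence within one fin.

    ``endo_profile`` is a radial series (PR or DR), ``exo_profile`` the
    lepidotrichia; the default pairing follows the published column
    alignment (radial i with lepidotrichium i+2).
    """
    pairing = pairing or PairingMap.column_aligned(endo_profile, exo_profile)
    return _paired_correlation(endo_profile, exo_profile, pairing, "EEM",
                               endo_proxy_size, exo_proxy_size, p_method)
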