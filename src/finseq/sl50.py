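"""Per-element logistic regression of attainment state on standard length.

For each serial element the probability of having attained a developmental
state is modelled as P(state=1 | SL) = 1/(1+exp(-(b0 + b1*SL))); the size
at which half the specimens have attained the state is SL50 = -b0/b1.
Model significance is a likelihood-ratio test against the intercept-only
model, gated at a Bonferroni-corrected nominal level (family alpha divided
by the number of elements fitted in the profile).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .coding import (ElementId, EventCodingTable, SL50Entry,
                     SL50Profile)

_SEPARATION_BETA = 1e3  # |b1| beyond this is treated as separation


class FitError(ValueError):
    """Raised when a logistic fit is requested on unusable data."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit for one element.

    ``fit_status`` is 'converged', 'separated' (states perfectly ordered
    by size: SL50 is the midpoint of the bracketing sizes, reported
    significant-by-separation) or 'degenerate' (one state only).
    Log-likelihoods are in nats; ``lrt_g`` = 2*(full - null) and the
    p-value is the chi-square(1) upper tail.
    """
    element: ElementId | None
    beta0: float
    beta1: float
    sl50: float | None
    loglik_full: float
    loglik_null: float
    lrt_g: float
    p_value: float
    n_obs: int
    fit_status: str


@dataclass(frozen=True)
class SignificancePolicy:
    """Bonferroni rule: the family-wise level is divided by the number of
    elements tested in the profile."""
    family_alpha: float = 0.05

    def nominal_alpha(self, k: int) -> float:
        if k < 1:
            raise ValueError("k must be >= 1")
        a = self.family_alpha / k
        assert 0 < a <= self.family_alpha
        return a


def _null_loglik(states: np.ndarray) -> float:
    n = len(states)
    n1 = states.sum()
    p = n1 / n
    if p in (0.0, 1.0):
        return 0.0
    return n1 * np.log(p) + (n - n1) * np.log(1 - p)


def fit_logistic(sizes, states, element: ElementId | None = None
                 ) -> LogisticFit:
    """Fit P(state=1|SL) by maximum likelihood.

    Missing states must already be dropped.  Raises :class:`FitError` with
    fewer than two observations; returns a degenerate fit (no SL50) when
    only one state is represented.  Perfect separation yields the midpoint
    between the largest size with state 0 and the smallest with state 1,
    flagged but still rankable.
    """
    sizes = np.asarray(sizes, float)
    states = np.asarray(states, float)
    if sizes.shape != states.shape:
        raise FitError("sizes and states must have equal length")
    if len(sizes) < 2:
        raise FitError("need at least 2 observations")
    if not np.isin(states, (0.0, 1.0)).all():
        raise FitError("states must be 0 or 1")
    n = len(sizes)
    ll0 = _null_loglik(states)

    if states.min() == states.max():
        return LogisticFit(element, np.nan, np.nan, None, ll0, ll0, 0.0,
                           1.0, n, "degenerate")

    s0max = sizes[states == 0].max()
    s1min = sizes[states == 1].min()
    if s0max < s1min:  # perfectly ordered: complete separation
        return _separated_fit(element, s0max, s1min, ll0, n)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(states, sm.add_constant(sizes),
                       family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100, tol=1e-8)
        except Exception:
            return _separated_fit(element, s0max, s1min, ll0, n)
    b0, b1 = res.params
    if not np.isfinite([b0, b1]).all() or abs(b1) > _SEPARATION_BETA:
        return _separated_fit(element, s0max, s1min, ll0, n)
    llf = float(res.llf)
    g = max(0.0, 2.0 * (llf - ll0))
    p = float(stats.chi2.sf(g, df=1))
    sl50 = float(-b0 / b1) if b1 > 0 else None
    return LogisticFit(element, float(b0), float(b1), sl50, llf, ll0, g, p,
                       n, "converged")


def _separated_fit(element, s0max, s1min, ll0, n) -> LogisticFit:
    # midpoint of the bracketing sizes; with an infinite slope the full
    # model fits perfectly (loglik 0), so G = -2*ll0
    mid = 0.5 * (s0max + s1min)
    g = max(0.0, -2.0 * ll0)
    p = float(stats.chi2.sf(g, df=1))
    return LogisticFit(element, np.nan, np.inf, float(mid), 0.0, ll0, g, p,
                       n, "separated")


def likelihood_ratio_test(fit: LogisticFit, policy: SignificancePolicy,
                          k: int) -> str:
    """Classify a fit as 'significant' or 'nonsignificant' at the
    Bonferroni-corrected nominal level alpha/k.

    Separated fits achieve the supremum of the likelihood and are reported
    by their (conservative, boundary) likelihood-ratio p-value; degenerate
    fits must not be tested.
    """
    if fit.fit_status == "degenerate":
        raise FitError("degenerate fit cannot be tested")
    alpha = policy.nominal_alpha(k)
    return "significant" if fit.p_value < alpha else "nonsignificant"


def estimate_sl50_profile(coding: EventCodingTable, fin: str, event: int,
                          policy: SignificancePolicy | None = None
                          ) -> SL50Profile:
    """Estimate the full SL50 profile of one fin and event.

    Elements attained in every observed specimen are always_present
    (no model is possible), in none never_reached; otherwise the logistic
    fit runs and the likelihood-ratio gate (with k = number of fitted
    elements) labels entries estimated or nonsignificant.  Elements whose
    fit yields no usable SL50 (non-positive slope) are inestimable.
    """
    policy = policy or SignificancePolicy()
    elements = coding.elements(fin, event)
    if not elements:
        raise FitError(f"no rows for ({fin}, event {event})")
    fits: dict[ElementId, LogisticFit | None] = {}
    statuses: dict[ElementId, str] = {}
    for el in elements:
        sizes, states = coding.observations(el, event)
        if len(sizes) == 0:
            statuses[el] = "inestimable"
            fits[el] = None
            continue
        if states.min() == 1.0:
            statuses[el] = "always_present"
            fits[el] = None
            continue
        if states.max() == 0.0:
            statuses[el] = "never_reached"
            fits[el] = None
            continue
        try:
            fit = fit_logistic(sizes, states, el)
        except FitError:
            statuses[el] = "inestimable"
            fits[el] = None
            continue
        fits[el] = fit
        statuses[el] = "fitted" if fit.sl50 is not None else "inestimable"

    k = sum(1 for s in statuses.values() if s == "fitted")
    entries = []
    for el in elements:
        st = statuses[el]
        fit = fits[el]
        if st == "fitted":
            verdict = likelihood_ratio_test(fit, policy, k)
            status = "estimated" if verdict == "significant" \
                else "nonsignificant"
            entries.append(SL50Entry(el, fit.sl50, status,
                                     p_value=fit.p_value, n_obs=fit.n_obs,
                                     fit_status=fit.fit_status))
        else:
            n_obs = fit.n_obs if fit is not None else None
            entries.append(SL50Entry(el, None, st, n_obs=n_obs))
    return SL50Profile(fin, event, tuple(entries), k)


def fit_report(profile: SL50Profile) -> list[dict]:
    """JSON-ready per-element fit report."""
    out = []
    for e in profile.entries:
        out.append({
            "element": e.element.label,
            "sl50": e.sl50,
            "status": e.status,
            "n_obs": e.n_obs,
            "p_value": e.p_value,
            "fit_status": e.fit_status,
        })
    return out
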