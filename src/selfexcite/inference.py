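"""Unbinned likelihood fitting of the contagion model and model comparison.

The fit minimises the Poisson negative log-likelihood over every day of the
span — zero-count days included — subject to the constraint that the total
expected count equals the total observed count (the constraint fixes the
baseline normalisation, so it is not a free parameter).  A Negative
Binomial (NB2) likelihood is available for over-dispersed data.  Nested
models are compared with the Wilks likelihood ratio test and with AIC.

The (n_secondary, t_excite) surface is optimised by a nested scheme that
exploits the model structure: for fixed t_excite the excitation shape is a
single convolution and the profile over n_secondary is a cheap 1-D bounded
search; the outer search over t_excite runs bounded scalar minimisations
from a fixed ladder of overlapping brackets, which makes the fit
deterministic and robust to the multi-modality that can appear near the
n_secondary = 0 boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .contagion_model import (
    BaselineSpec,
    ContagionParams,
    IntensitySeries,
    baseline_series,
    excitation_shape,
)
from .event_io import DailyCounts, GapHistogram

__all__ = [
    "FitResult",
    "ModelComparison",
    "ProfileCI",
    "GapHistogramComparison",
    "poisson_negloglik",
    "negbin_negloglik",
    "fit_null",
    "fit_contagion",
    "profile_ci",
    "lrt",
    "aic",
    "gap_histogram_aic",
]

#: Penalty returned for parameter points where the contagion mass alone
#: exceeds the observed total (no feasible baseline scale).  A finite
#: penalty plus the distance to feasibility keeps derivative-free searches
#: stable where an exception or infinity would strand them.
INFEASIBLE_PENALTY = 1e12

#: Default parameter box.  The branching ratio is bounded below 1 (the
#: subcritical regime; values near 1 are unidentifiable on a finite span)
#: and the decay time is searched between half a day and 60 days.
N_SECONDARY_MAX = 0.95
T_EXCITE_BOUNDS = (0.5, 60.0)

# Overlapping t_excite brackets for the multi-start outer search.
_T_BRACKETS = ((0.5, 4.0), (2.0, 10.0), (6.0, 20.0), (13.0, 35.0), (25.0, 60.0))


@dataclass
class FitResult:
    """Outcome of a likelihood fit.

    ``params`` is ``None`` for the null (baseline-only) model.  ``n_params``
    counts the freely fitted quantities: 0 for the Poisson null (the
    baseline normalisation is a constraint), 2 for the Poisson contagion
    model, plus 1 whenever an NB dispersion is estimated.  ``at_bound``
    flags optimiser termination at the edge of the parameter box, where the
    decay time is effectively unidentified.
    """

    params: ContagionParams | None
    negloglik: float
    n_params: int
    converged: bool
    likelihood: str = "poisson"
    dispersion: float | None = None
    at_bound: bool = False
    n_evaluations: int = 0
    n_days: int = 0
    n_events: int = 0
    profile_cis: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ModelComparison:
    """Wilks likelihood-ratio test and AIC for a nested model pair."""

    negll_null: float
    negll_alt: float
    lrt_stat: float
    df: int
    p_value: float
    aic_null: float
    aic_alt: float


@dataclass(frozen=True)
class ProfileCI:
    """Profile-likelihood confidence interval for one parameter.

    ``lower_open``/``upper_open`` flag sides where the profile never rose
    above the threshold inside the parameter box (one-sided interval).
    """

    lower: float
    upper: float
    level: float
    lower_open: bool = False
    upper_open: bool = False

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class GapHistogramComparison:
    """AIC of a predicted gap distribution against an observed histogram."""

    aic: float
    negloglik: float
    dispersion: float
    n_params: int  # total tally including the fitted dispersion


def poisson_negloglik(intensity, counts) -> float:
    """Poisson negative log-likelihood ``sum_i (mu_i - k_i log mu_i)``.

    The ``log k!`` term depends only on the data and is dropped (an
    additive constant for any model comparison on the same data).  A day
    with ``mu = 0`` but ``k > 0`` is an impossible observation and yields
    ``+inf`` — returned as a value, not raised, so optimisers can recover.
    """
    mu = intensity.mu if isinstance(intensity, IntensitySeries) else np.asarray(intensity, dtype=float)
    k = counts.counts if isinstance(counts, DailyCounts) else np.asarray(counts)
    if mu.shape != k.shape:
        raise ValueError("intensity and counts must have equal length")
    if np.any(mu < 0):
        raise ValueError("intensity must be non-negative")
    pos = k > 0
    if np.any(mu[pos] == 0):
        return np.inf
    with np.errstate(divide="ignore"):
        return float(mu.sum() - np.sum(k[pos] * np.log(mu[pos])))


def negbin_negloglik(mu, counts, dispersion: float) -> float:
    """Negative Binomial (NB2) negative log-likelihood, full log-pmf.

    NB2 parameterisation: ``variance = mu + dispersion * mu**2``.  As the
    dispersion tends to 0 the value converges to the full Poisson negative
    log-likelihood (including the ``log k!`` term, unlike
    :func:`poisson_negloglik` — constants are handled consistently within
    each comparison).
    """
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(counts)
    if mu.shape != k.shape:
        raise ValueError("mu and counts must have equal length")
    if not (dispersion >= 0):
        raise ValueError("dispersion must be non-negative")
    pos = k > 0
    if np.any(mu[pos] == 0):
        return np.inf
    if dispersion < 1e-10:
        return float(-stats.poisson.logpmf(k, mu).sum())
    r = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mu)
    return float(-stats.nbinom.logpmf(k, r, p).sum())


class _Objective:
    """Constrained negative log-likelihood as a function of the contagion
    parameters, with the excitation shape cached per decay time."""

    def __init__(self, counts: DailyCounts, spec: BaselineSpec, likelihood: str = "poisson"):
        if likelihood not in ("poisson", "negbin"):
            raise ValueError(f"unknown likelihood {likelihood!r}")
        self.k = counts.counts
        self.n_total = counts.total
        self.n_days = counts.n_days
        self.baseline_raw = baseline_series(counts, spec)
        self.baseline_sum = float(self.baseline_raw.sum())
        if self.baseline_sum <= 0:
            raise ValueError("baseline has zero mass; no events to model")
        self.event_idx = np.nonzero(self.k)[0]
        self.event_k = self.k[self.event_idx]
        self.likelihood = likelihood
        self._shapes: dict[float, tuple[np.ndarray, float]] = {}
        self.n_evaluations = 0

    def shape(self, t_excite: float) -> tuple[np.ndarray, float]:
        t_excite = float(t_excite)
        hit = self._shapes.get(t_excite)
        if hit is None:
            c = excitation_shape(self.k, t_excite)
            hit = (c, float(c.sum()))
            self._shapes[t_excite] = hit
        return hit

    def __call__(self, n_secondary: float, t_excite: float, dispersion: float = 0.0) -> float:
        self.n_evaluations += 1
        c, c_sum = self.shape(t_excite)
        remainder = self.n_total - n_secondary * c_sum
        if remainder <= 0:  # infeasible: constraint unsatisfiable
            return INFEASIBLE_PENALTY + (n_secondary * c_sum - self.n_total)
        scale = remainder / self.baseline_sum
        if self.likelihood == "poisson":
            mu_ev = scale * self.baseline_raw[self.event_idx] + n_secondary * c[self.event_idx]
            if np.any(mu_ev <= 0):
                return INFEASIBLE_PENALTY
            # Under the total-count constraint sum(mu) == n_total exactly.
            return self.n_total - float(np.sum(self.event_k * np.log(mu_ev)))
        mu = scale * self.baseline_raw + n_secondary * c
        return negbin_negloglik(mu, self.k, dispersion)

    def profile_n_secondary(self, t_excite: float, n_max: float = N_SECONDARY_MAX,
                            dispersion: float = 0.0):
        """Minimise over n_secondary at fixed t_excite; returns (negll, nsec)."""
        res = optimize.minimize_scalar(
            lambda s: self(s, t_excite, dispersion),
            bounds=(0.0, n_max), method="bounded", options={"xatol": 1e-6})
        return float(res.fun), float(res.x)


def fit_null(counts: DailyCounts, spec: BaselineSpec | None = None,
             likelihood: str = "poisson") -> FitResult:
    """Fit the no-contagion null model (intensity = rescaled baseline).

    The Poisson null has no free parameters: the baseline is built from the
    data and rescaled to the observed total.  Under an NB likelihood the
    dispersion is fitted by maximum likelihood (one free parameter).
    """
    spec = spec or BaselineSpec()
    if counts.total == 0:
        raise ValueError("cannot fit with zero observed events")
    b = baseline_series(counts, spec)
    mu = b * (counts.total / b.sum())
    if likelihood == "poisson":
        negll = poisson_negloglik(mu, counts.counts)
        return FitResult(params=None, negloglik=negll, n_params=0, converged=True,
                         likelihood="poisson", n_days=counts.n_days, n_events=counts.total)
    if likelihood != "negbin":
        raise ValueError(f"unknown likelihood {likelihood!r}")
    res = optimize.minimize_scalar(lambda a: negbin_negloglik(mu, counts.counts, a),
                                   bounds=(1e-9, 50.0), method="bounded",
                                   options={"xatol": 1e-8})
    negll0 = negbin_negloglik(mu, counts.counts, 0.0)
    alpha, negll = (0.0, negll0) if negll0 <= res.fun else (float(res.x), float(res.fun))
    return FitResult(params=None, negloglik=negll, n_params=1, converged=True,
                     likelihood="negbin", dispersion=alpha,
                     n_days=counts.n_days, n_events=counts.total)


def fit_contagion(counts: DailyCounts, spec: BaselineSpec | None = None,
                  likelihood: str = "poisson",
                  n_secondary_max: float = N_SECONDARY_MAX,
                  t_excite_bounds: tuple = T_EXCITE_BOUNDS,
                  compute_ci: bool = False, ci_level: float = 0.95) -> FitResult:
    """Maximum-likelihood fit of (n_secondary, t_excite).

    The baseline is rebuilt and rescaled to the observed total at every
    evaluation, enforcing the total-count constraint throughout.  The fit
    is deterministic: the outer search over t_excite starts from a fixed
    ladder of overlapping brackets.  With ``likelihood="negbin"`` the NB
    dispersion is fitted jointly (counted as a third parameter).
    """
    spec = spec or BaselineSpec()
    if counts.total < 2:
        raise ValueError("need at least 2 events to fit the contagion model")
    obj = _Objective(counts, spec, likelihood="poisson")
    t_lo, t_hi = t_excite_bounds

    def outer(t):
        return obj.profile_n_secondary(float(t), n_secondary_max)[0]

    best = (np.inf, None)
    ok = True
    for lo, hi in _T_BRACKETS:
        lo, hi = max(lo, t_lo), min(hi, t_hi)
        if lo >= hi:
            continue
        res = optimize.minimize_scalar(outer, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-4})
        ok = ok and bool(res.success)
        if res.fun < best[0]:
            best = (float(res.fun), float(res.x))
    negll, t_hat = best
    if t_hat is None or not np.isfinite(negll):
        return FitResult(params=None, negloglik=np.inf, n_params=2, converged=False,
                         likelihood=likelihood, n_days=counts.n_days, n_events=counts.total)
    negll, n_hat = obj.profile_n_secondary(t_hat, n_secondary_max)
    # Exact boundary evaluation enforces nesting: the contagion fit can
    # never be worse than the no-contagion point it contains.
    f_zero = obj(0.0, t_hat)
    if f_zero <= negll:
        negll, n_hat = f_zero, 0.0

    dispersion = None
    n_params = 2
    if likelihood == "negbin":
        nb = _Objective(counts, spec, likelihood="negbin")
        alpha0 = _moment_dispersion(counts.counts)
        starts = [(n_hat, t_hat, alpha0), (max(n_hat, 0.1), t_hat, 1e-4)]
        best_nb = (np.inf, None)
        for x0 in starts:
            res = optimize.minimize(
                lambda x: nb(x[0], x[1], x[2]), x0=np.asarray(x0), method="Nelder-Mead",
                bounds=[(0.0, n_secondary_max), (t_lo, t_hi), (0.0, 50.0)],
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
            if res.fun < best_nb[0]:
                best_nb = (float(res.fun), res.x)
        negll, (n_hat, t_hat, alpha) = best_nb
        dispersion = float(alpha)
        n_params = 3
        obj = nb

    margin = 0.01 * (t_hi - t_lo)
    at_bound = (t_hat >= t_hi - margin) or (t_hat <= t_lo + margin) \
        or (n_hat >= 0.999 * n_secondary_max)
    fit = FitResult(params=ContagionParams(n_secondary=max(n_hat, 0.0), t_excite=t_hat),
                    negloglik=negll, n_params=n_params, converged=ok,
                    likelihood=likelihood, dispersion=dispersion, at_bound=at_bound,
                    n_evaluations=obj.n_evaluations,
                    n_days=counts.n_days, n_events=counts.total)
    if compute_ci:
        for name in ("n_secondary", "t_excite"):
            fit.profile_cis[name] = profile_ci(counts, spec, fit, name, level=ci_level,
                                               n_secondary_max=n_secondary_max,
                                               t_excite_bounds=t_excite_bounds)
    return fit


def _moment_dispersion(k: np.ndarray) -> float:
    mean = k.mean()
    var = k.var(ddof=1)
    return float(np.clip((var - mean) / mean**2, 1e-4, 10.0))


def profile_ci(counts: DailyCounts, spec: BaselineSpec | None, fit: FitResult,
               param: str, level: float = 0.95,
               n_secondary_max: float = N_SECONDARY_MAX,
               t_excite_bounds: tuple = T_EXCITE_BOUNDS) -> ProfileCI:
    """Profile-likelihood confidence interval for one contagion parameter.

    The bound is where the profile negative log-likelihood (re-optimising
    the other parameter, and the dispersion when present) rises
    ``qchisq(level, 1) / 2`` above the minimum.  The lower bound of
    ``n_secondary`` is clipped at 0; a side whose threshold crossing is not
    bracketed inside the parameter box is flagged open.
    """
    if not fit.converged or fit.params is None:
        raise ValueError("profile CI requires a converged contagion fit")
    if param not in ("n_secondary", "t_excite"):
        raise ValueError(f"unknown parameter {param!r}")
    spec = spec or BaselineSpec()
    obj = _Objective(counts, spec, likelihood=fit.likelihood)
    threshold_rise = stats.chi2.ppf(level, 1) / 2.0
    t_lo, t_hi = t_excite_bounds

    if fit.likelihood == "negbin":
        alpha_hat = fit.dispersion

        def profile(x):
            if param == "n_secondary":
                x0 = [fit.params.t_excite, alpha_hat]
                res = optimize.minimize(lambda y: obj(x, y[0], y[1]), x0=np.asarray(x0),
                                        method="Nelder-Mead",
                                        bounds=[(t_lo, t_hi), (0.0, 50.0)],
                                        options={"xatol": 1e-4, "fatol": 1e-6})
            else:
                x0 = [fit.params.n_secondary, alpha_hat]
                res = optimize.minimize(lambda y: obj(y[0], x, y[1]), x0=np.asarray(x0),
                                        method="Nelder-Mead",
                                        bounds=[(0.0, n_secondary_max), (0.0, 50.0)],
                                        options={"xatol": 1e-4, "fatol": 1e-6})
            return float(res.fun)
    elif param == "n_secondary":
        def profile(x):
            best = np.inf
            for lo, hi in ((t_lo, 6.0), (3.0, 20.0), (10.0, t_hi)):
                lo, hi = max(lo, t_lo), min(hi, t_hi)
                if lo >= hi:
                    continue
                res = optimize.minimize_scalar(lambda t: obj(x, t),
                                               bounds=(lo, hi), method="bounded",
                                               options={"xatol": 0.01})
                best = min(best, float(res.fun))
            return best
    else:
        def profile(x):
            return obj.profile_n_secondary(x, n_secondary_max)[0]

    if param == "n_secondary":
        x_hat, box = fit.params.n_secondary, (0.0, n_secondary_max)
    else:
        x_hat, box = fit.params.t_excite, (t_lo, t_hi)

    # Self-consistent minimum: the profile at the estimate can only improve
    # on the fit's reported minimum.
    f_min = min(fit.negloglik, profile(x_hat))
    threshold = f_min + threshold_rise

    def crossing(x):
        return profile(x) - threshold

    lower, upper = box
    lower_open = upper_open = False
    if crossing(box[0]) > 0:
        lower = optimize.brentq(crossing, box[0], x_hat, xtol=2e-3)
    elif param == "t_excite":
        lower_open = True  # profile still below threshold at the box edge
    if crossing(box[1]) > 0:
        upper = optimize.brentq(crossing, x_hat, box[1], xtol=2e-3)
    else:
        upper_open = True
    return ProfileCI(lower=float(lower), upper=float(upper), level=level,
                     lower_open=lower_open, upper_open=upper_open)


def lrt(null: FitResult, alt: FitResult) -> ModelComparison:
    """Wilks likelihood-ratio test of the contagion model against its null.

    ``stat = 2 (negll_null - negll_alt)`` referred to a chi-square with
    ``df`` equal to the difference in free-parameter counts (2 for the
    Poisson pair).  The n_secondary = 0 boundary makes the test
    conservative; calibration is checked by simulation in the power
    harness rather than adjusted analytically.
    """
    if null.n_days != alt.n_days or null.n_events != alt.n_events:
        raise ValueError("LRT requires fits to the same data")
    if null.likelihood != alt.likelihood:
        raise ValueError("LRT requires the same likelihood family")
    stat = 2.0 * (null.negloglik - alt.negloglik)
    if stat < 0:
        if stat < -1e-6:
            warnings.warn(f"negative LRT statistic {stat:.3g} clamped to 0 "
                          "(optimizer tolerance)", stacklevel=2)
        stat = 0.0
    df = alt.n_params - null.n_params
    return ModelComparison(negll_null=null.negloglik, negll_alt=alt.negloglik,
                           lrt_stat=stat, df=df, p_value=float(stats.chi2.sf(stat, df)),
                           aic_null=aic(null), aic_alt=aic(alt))


def aic(fit: FitResult) -> float:
    """Akaike information criterion, ``2 k + 2 (-log L)``."""
    if not fit.converged:
        raise ValueError("AIC requires a converged fit")
    return 2.0 * fit.n_params + 2.0 * fit.negloglik


def gap_histogram_aic(observed: GapHistogram, predicted: np.ndarray,
                      n_params: int) -> GapHistogramComparison:
    """AIC of a model's gap distribution on a binned gap histogram.

    ``predicted`` is a probability vector over bins 0..d_max plus the
    overflow bin (must sum to 1).  Expected bin counts are the predicted
    probabilities scaled by the observed total, so totals match by
    construction.  Per-bin stochasticity is Negative Binomial with the
    dispersion fitted by maximum likelihood; the returned parameter tally
    is ``n_params + 1`` to count it, and is printed alongside the AIC so
    the tally can be re-examined.
    """
    predicted = np.asarray(predicted, dtype=float)
    obs = observed.all_bins()
    if len(predicted) != len(obs):
        raise ValueError("predicted distribution must cover bins 0..d_max plus overflow")
    if np.any(predicted < 0) or abs(predicted.sum() - 1.0) > 1e-6:
        raise ValueError("predicted distribution must be normalised probabilities")
    if observed.total == 0:
        raise ValueError("observed histogram is empty")
    expected = predicted * observed.total
    if np.any((expected == 0) & (obs > 0)):
        return GapHistogramComparison(aic=np.inf, negloglik=np.inf,
                                      dispersion=0.0, n_params=n_params + 1)
    res = optimize.minimize_scalar(lambda a: negbin_negloglik(expected, obs, a),
                                   bounds=(1e-9, 50.0), method="bounded",
                                   options={"xatol": 1e-8})
    negll0 = negbin_negloglik(expected, obs, 0.0)
    alpha, negll = (0.0, negll0) if negll0 <= res.fun else (float(res.x), float(res.fun))
    total_params = n_params + 1
    return GapHistogramComparison(aic=2.0 * total_params + 2.0 * negll,
                                  negloglik=negll, dispersion=alpha,
                                  n_params=total_params)
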