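"""The self-excitation (Hawkes-type) contagion model on daily-binned data.

Each event temporarily raises the probability of further events.  The
elevation decays exponentially with mean ``t_excite`` days; integrating the
exponential density over the 24 hours of a day that lies ``d`` whole days
after the parent event gives the day-binned kernel

    P(d | T) = exp(-(d-1)/T) - exp(-d/T),     d = 1, 2, ...

which sums (telescopes) to 1 over all future days.  The conditional
expected number of events on day ``n`` is

    mu[n] = b[n] + n_secondary * sum_{events on days i < n} P(n - i | T)

where ``b`` is a baseline (non-contagion) rate: a constant, or a running
mean of the data itself, optionally modulated by day-of-week weights.
``n_secondary`` is the branching ratio — the mean number of secondary
events incited per event; the process is subcritical when it is below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .event_io import DailyCounts

__all__ = [
    "ContagionParams",
    "BaselineSpec",
    "IntensitySeries",
    "WeekdayEffect",
    "InfeasibleParameterError",
    "excitation_probability",
    "excitation_kernel",
    "weekday_weights",
    "baseline_series",
    "expected_events",
    "rescale_to_total",
]

#: Kernel truncation horizon in units of t_excite.  Beyond 20 mean decay
#: times the remaining kernel mass is exp(-20) ~ 2e-9, far below optimizer
#: tolerance; truncation makes the excitation sum O(events * horizon).
KERNEL_TRUNCATION_MULTIPLIER = 20.0


@dataclass(frozen=True)
class ContagionParams:
    """Parameters of the self-excitation model.

    n_secondary : mean secondary events incited per event (dimensionless, >= 0).
    t_excite    : mean decay time of the excitation, in days (> 0).
    """

    n_secondary: float
    t_excite: float

    def __post_init__(self):
        if not (self.n_secondary >= 0):
            raise ValueError("n_secondary must be non-negative")
        if not (self.t_excite > 0):
            raise ValueError("t_excite must be positive")


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline-rate estimator configuration.

    kind : {"constant", "running_mean", "running_mean_weekday"}
    window_days : width of the centred running-mean window (default 365).
    weekday_weights : optional 7-vector of day-of-week weights averaging 1
        (Monday first).  When absent and the kind requires them, they are
        estimated from the data.
    """

    kind: str = "constant"
    window_days: int = 365
    weekday_weights: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("constant", "running_mean", "running_mean_weekday"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.weekday_weights is not None:
            w = np.asarray(self.weekday_weights, dtype=float)
            if w.shape != (7,) or np.any(w < 0):
                raise ValueError("weekday_weights must be 7 non-negative reals")
            if abs(w.mean() - 1.0) > 1e-9:
                raise ValueError("weekday_weights must average 1")
            object.__setattr__(self, "weekday_weights", tuple(w))


@dataclass(frozen=True)
class IntensitySeries:
    """Expected events/day, decomposed into baseline and contagion parts."""

    baseline: np.ndarray
    contagion: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.baseline, dtype=float)
        c = np.asarray(self.contagion, dtype=float)
        if b.shape != c.shape or b.ndim != 1:
            raise ValueError("baseline and contagion parts must be 1-D and equal length")
        if np.any(b < 0) or np.any(c < 0):
            raise ValueError("intensity components must be non-negative")
        object.__setattr__(self, "baseline", b)
        object.__setattr__(self, "contagion", c)

    @property
    def mu(self) -> np.ndarray:
        return self.baseline + self.contagion

    def __len__(self):
        return len(self.baseline)


@dataclass(frozen=True)
class WeekdayEffect:
    """Day-of-week weights plus a Pearson chi-square uniformity test."""

    weights: np.ndarray  # Monday first, mean exactly 1
    chi2: float
    p_value: float
    event_counts: np.ndarray


class InfeasibleParameterError(ValueError):
    """Raised when the contagion part alone meets or exceeds the observed
    total, so no positive baseline scale can satisfy the total-count
    constraint.  Fitters treat such parameter points as rejected/penalised
    rather than fatal."""


def excitation_probability(d, t_excite: float):
    """Probability that a secondary event lands exactly ``d`` whole days
    after its parent, for an exponential delay with mean ``t_excite``.

    Strictly decreasing in ``d``; sums to 1 over d = 1, 2, ...  Same-day
    excitation (d = 0) is excluded: the intensity sum runs over strictly
    prior days only.
    """
    d = np.asarray(d)
    if np.any(d < 1):
        raise ValueError("day gap d must be >= 1 (only strictly prior days excite)")
    if not (t_excite > 0):
        raise ValueError("t_excite must be positive")
    out = np.exp(-(d - 1.0) / t_excite) - np.exp(-d / t_excite)
    return float(out) if out.ndim == 0 else out


def excitation_kernel(t_excite: float, max_days: int | None = None,
                      truncation_multiplier: float = KERNEL_TRUNCATION_MULTIPLIER) -> np.ndarray:
    """Kernel values P(d | t_excite) for d = 1..horizon as a vector.

    The horizon is ``ceil(truncation_multiplier * t_excite)``, optionally
    capped at ``max_days``.
    """
    raw = truncation_multiplier * t_excite
    if not np.isfinite(raw):
        if max_days is None:
            raise ValueError("an untruncated kernel needs an explicit max_days")
        horizon = int(max_days)
    else:
        horizon = int(np.ceil(raw))
        if max_days is not None:
            horizon = min(horizon, int(max_days))
    horizon = max(horizon, 1)
    d = np.arange(1, horizon + 1, dtype=float)
    return np.exp(-(d - 1.0) / t_excite) - np.exp(-d / t_excite)


def weekday_weights(counts: DailyCounts) -> WeekdayEffect:
    """Estimate day-of-week weights from the data.

    The weight for weekday ``w`` is 7 times the share of events falling on
    ``w``, so the seven weights average exactly 1.  A Pearson chi-square
    test against a uniform weekday distribution is returned alongside.
    """
    if counts.total == 0:
        raise ValueError("cannot estimate weekday weights with zero events")
    wd = counts.weekday_of_index(np.arange(counts.n_days))
    per_weekday = np.array([counts.counts[wd == w].sum() for w in range(7)], dtype=float)
    weights = 7.0 * per_weekday / per_weekday.sum()
    chi2, p = stats.chisquare(per_weekday)
    return WeekdayEffect(weights=weights, chi2=float(chi2), p_value=float(p),
                         event_counts=per_weekday.astype(np.int64))


def baseline_series(counts: DailyCounts, spec: BaselineSpec) -> np.ndarray:
    """Baseline expected events/day under ``spec``, as a vector of length M.

    constant             : total/M on every day.
    running_mean         : centred boxcar moving average; at the span edges
                           the window is renormalised by the number of days
                           actually covered (no padding), so a flat series
                           is a fixed point of the smoother.
    running_mean_weekday : the running mean multiplied by the weekday weight
                           of each day.
    """
    m = counts.n_days
    if spec.kind == "constant":
        return np.full(m, counts.total / m)
    if spec.window_days > m:
        raise ValueError(f"running-mean window {spec.window_days} exceeds span {m}")
    window = np.ones(spec.window_days)
    sums = np.convolve(counts.counts.astype(float), window, mode="same")
    coverage = np.convolve(np.ones(m), window, mode="same")
    b = sums / coverage
    if spec.kind == "running_mean_weekday":
        if spec.weekday_weights is not None:
            w = np.asarray(spec.weekday_weights, dtype=float)
        else:
            w = weekday_weights(counts).weights
        b = b * w[counts.weekday_of_index(np.arange(m))]
    return b


def expected_events(history: DailyCounts, params: ContagionParams,
                    baseline: np.ndarray) -> IntensitySeries:
    """Conditional expected-events series given the observed history.

    ``mu[n] = baseline[n] + n_secondary * sum_{i<n} k_i P(n-i | t_excite)``
    where ``k_i`` is the observed count on day ``i`` — a day with k events
    contributes k kernel terms (the sum is linear in the history).
    """
    baseline = np.asarray(baseline, dtype=float)
    if len(baseline) != history.n_days:
        raise ValueError("baseline length must match the daily-count span")
    shape = excitation_shape(history.counts, params.t_excite)
    return IntensitySeries(baseline=baseline, contagion=params.n_secondary * shape)


def excitation_shape(counts: np.ndarray, t_excite: float) -> np.ndarray:
    """Per-day excitation sum ``sum_{i<n} k_i P(n-i | t_excite)`` for a unit
    branching ratio.  The contagion part of the intensity is
    ``n_secondary`` times this vector."""
    counts = np.asarray(counts, dtype=float)
    m = len(counts)
    kernel = excitation_kernel(t_excite, max_days=m - 1 if m > 1 else 1)
    full = np.convolve(counts, kernel)
    out = np.empty(m)
    out[0] = 0.0
    out[1:] = full[: m - 1]
    return out


def rescale_to_total(intensity: IntensitySeries, total: float) -> IntensitySeries:
    """Rescale the baseline part so the intensity sums to ``total``.

    The total-count constraint fixes the baseline normalisation: the
    contagion part is left untouched and the baseline is multiplied by
    ``(total - sum(contagion)) / sum(baseline)``.

    Raises
    ------
    InfeasibleParameterError
        If the contagion part alone already accounts for ``total`` or more.
    """
    contagion_sum = float(intensity.contagion.sum())
    if contagion_sum >= total:
        raise InfeasibleParameterError(
            f"contagion mass {contagion_sum:.6g} >= target total {total:.6g}; "
            "no positive baseline scale exists")
    baseline_sum = float(intensity.baseline.sum())
    if baseline_sum <= 0:
        raise ValueError("baseline part must have positive mass to rescale")
    scale = (total - contagion_sum) / baseline_sum
    return replace(intensity, baseline=intensity.baseline * scale)
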