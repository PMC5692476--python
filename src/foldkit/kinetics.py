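"""Kinetic analysis of fluorescence folding transients.

A folding transient is a time course of tryptophan fluorescence recorded
while an unfolded outer-membrane protein inserts and folds into a lipid
bilayer.  Transients that decay (or rise) exponentially are described by

    y(t) = A1 * exp(-k1 * t) + c                       (single exponential)
    y(t) = A1 * exp(-k1 * t) + A2 * exp(-k2 * t) + c   (double exponential)

with rate constants ``k`` in s^-1; a rising transient simply has a
negative amplitude.  Replicate transients measured under the same
condition are fitted *globally*: they share the rate constant(s) while
each replicate keeps its own amplitude(s) and offset.  The shared rates
are found by variable projection — for any trial set of rates the
amplitudes and offset of each replicate are the solution of a linear
least-squares problem, so the nonlinear search runs only over the rates
(log-parameterized, multi-started from a log-spaced grid to avoid local
minima).

Transients that show a lag phase are summarized non-parametrically by the
half-time ``t50``: the time to reach halfway between the signal minimum
and a horizontal baseline fitted to the trailing part of the trace.  The
module also provides the small summary statistics used to compare
conditions: mean / SD / s.e.m., and fold changes with errors propagated in
quadrature, delta_R = |R| * sqrt((dX/X)^2 + (dY/Y)^2).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .errors import DegenerateDataError, FitConvergenceError, NoCrossingError

__all__ = [
    "FoldingTransient",
    "ExpFitResult",
    "T50Result",
    "SummaryStat",
    "FoldChange",
    "SigmoidFit",
    "fit_exponential_global",
    "select_model",
    "extract_t50",
    "summarize",
    "fold_change",
    "fit_sigmoid",
    "batch_rate_summary",
]

MIN_SAMPLES = 10


@dataclass(frozen=True)
class FoldingTransient:
    """One time-resolved fluorescence trace with condition metadata.

    ``time`` is in seconds and must be strictly increasing with at least
    10 samples; ``signal`` is fluorescence intensity in arbitrary units.
    ``batch_id`` identifies the liposome batch the trace was recorded
    with, which matters because errors are reported between batches.
    """

    time: np.ndarray
    signal: np.ndarray
    condition_label: str = ""
    replicate_id: str = ""
    batch_id: str | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise DegenerateDataError("time and signal must be matching 1-D arrays")
        if t.size < MIN_SAMPLES:
            raise DegenerateDataError(
                f"transient needs >= {MIN_SAMPLES} samples, got {t.size}"
            )
        if not np.all(np.diff(t) > 0):
            raise DegenerateDataError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise DegenerateDataError("time/signal must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class ExpFitResult:
    """Shared rate constant(s) plus per-transient amplitudes and offsets.

    Rates are ordered descending (k1 >= k2).  ``amplitudes[i]`` and
    ``offsets[i]`` belong to the i-th transient of the global fit.
    ``information_criterion`` is the corrected AIC used for model
    selection; ``rate_stderr`` are approximate standard errors from the
    profiled least-squares Jacobian (NaN when not estimable).
    """

    rates: tuple[float, ...]
    amplitudes: tuple[tuple[float, ...], ...]
    offsets: tuple[float, ...]
    n_exponentials: int
    residual_sum_squares: float
    information_criterion: float
    rate_stderr: tuple[float, ...] = ()
    n_observations: int = 0

    def __post_init__(self):
        if any(k <= 0 for k in self.rates):
            raise DegenerateDataError("rates must be positive")
        if len(self.rates) == 2 and not self.rates[0] >= self.rates[1]:
            raise DegenerateDataError("rate ordering convention k1 >= k2 violated")

    @property
    def k1(self) -> float:
        return self.rates[0]

    @property
    def k2(self) -> float | None:
        return self.rates[1] if len(self.rates) > 1 else None

    def predict(self, time: np.ndarray, transient_index: int = 0) -> np.ndarray:
        t = np.asarray(time, dtype=float)
        y = np.full_like(t, self.offsets[transient_index])
        for a, k in zip(self.amplitudes[transient_index], self.rates):
            y = y + a * np.exp(-k * t)
        return y


@dataclass(frozen=True)
class T50Result:
    """Half-time of a folding transient (seconds) and how it was located."""

    t50: float
    f_min: float
    baseline_level: float
    baseline_fraction: float
    crossing_method: str = "linear_interpolation"


@dataclass(frozen=True)
class SummaryStat:
    """Mean, sample SD and standard error of the mean of a set of values."""

    mean: float
    sd: float
    sem: float
    n_samples: int

    @classmethod
    def from_moments(cls, mean: float, sem: float, n_samples: int = 1) -> "SummaryStat":
        """Build a summary from a reported mean +/- s.e.m. (e.g. a published value)."""
        return cls(mean=float(mean), sd=float(sem) * math.sqrt(n_samples),
                   sem=float(sem), n_samples=n_samples)


@dataclass(frozen=True)
class FoldChange:
    """Ratio of two measured means with quadrature-propagated error."""

    ratio: float
    error: float
    numerator_mean: float
    numerator_sem: float
    denominator_mean: float
    denominator_sem: float


@dataclass(frozen=True)
class SigmoidFit:
    """4-parameter logistic fit of a lag-phase transient (display only).

    y(t) = lower + (upper - lower) / (1 + exp(-steepness * (t - midpoint))).
    Half-times for quantitative comparison always come from
    :func:`extract_t50`, never from this fit.
    """

    lower_asymptote: float
    upper_asymptote: float
    midpoint_time: float
    steepness: float
    residual_sum_squares: float


# ---------------------------------------------------------------------------
# global exponential fitting (variable projection)
# ---------------------------------------------------------------------------

def _projected_residuals(log_rates: np.ndarray,
                         transients: Sequence[FoldingTransient]):
    """Residuals of the globally-optimal linear fit at fixed rates.

    For given rates the per-transient amplitudes and offset minimizing the
    squared residuals are a linear least-squares solution, so the outer
    optimizer only searches rate space.
    """
    # clamp so wandering optimizer steps cannot overflow exp()
    rates = np.exp(np.clip(log_rates, math.log(1e-12), math.log(1e9)))
    residuals = []
    linear = []
    for tr in transients:
        design = np.column_stack(
            [np.exp(np.clip(-k * tr.time, -700.0, 0.0)) for k in rates]
            + [np.ones_like(tr.time)]
        )
        coef, *_ = np.linalg.lstsq(design, tr.signal, rcond=None)
        residuals.append(design @ coef - tr.signal)
        linear.append(coef)
    return np.concatenate(residuals), linear


def _rate_grid(transients: Sequence[FoldingTransient], n_points: int) -> np.ndarray:
    t_span = max(tr.time[-1] - tr.time[0] for tr in transients)
    dt_min = min(np.min(np.diff(tr.time)) for tr in transients)
    return np.geomspace(1.0 / (10.0 * t_span), 10.0 / dt_min, n_points)


def _aicc(rss: float, n: int, n_params: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * n_params
    denom = n - n_params - 1
    if denom > 0:
        aic += 2 * n_params * (n_params + 1) / denom
    return aic


def fit_exponential_global(transients: Sequence[FoldingTransient],
                           n_exponentials: int = 1,
                           *,
                           grid_points: int = 8) -> ExpFitResult:
    """Globally fit transients to a shared-rate multi-exponential model.

    All transients share the same rate constant(s); each keeps its own
    amplitude(s) and constant offset.  The rate search is multi-started
    from a log-spaced grid spanning [1/(10*t_span), 10/dt_min] so the
    result is deterministic for a given input.

    Parameters
    ----------
    transients:
        One or more replicate traces recorded under comparable conditions.
    n_exponentials:
        1 or 2 exponential terms.

    Raises
    ------
    DegenerateDataError
        If there are fewer data points than free parameters.
    FitConvergenceError
        If no optimizer start converges; the best candidate is attached.
    """
    transients = list(transients)
    if not transients:
        raise DegenerateDataError("need at least one transient")
    if n_exponentials not in (1, 2):
        raise DegenerateDataError("n_exponentials must be 1 or 2")

    n_obs = sum(tr.n_samples for tr in transients)
    n_params = n_exponentials + len(transients) * (n_exponentials + 1)
    if n_obs <= n_params:
        raise DegenerateDataError(
            f"{n_obs} samples cannot constrain {n_params} parameters"
        )
    for tr in transients:
        if tr.n_samples <= n_exponentials + 1:
            raise DegenerateDataError("a transient has fewer samples than parameters")

    grid = _rate_grid(transients, grid_points)
    if n_exponentials == 1:
        starts = [[k] for k in grid]
    else:
        coarse = _rate_grid(transients, max(5, grid_points - 3))
        starts = [[ki, kj] for ki, kj in itertools.combinations(coarse, 2)]

    best = None
    for start in starts:
        x0 = np.log(start)
        try:
            sol = optimize.least_squares(
                lambda x: _projected_residuals(x, transients)[0],
                x0, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=400,
            )
        except Exception:
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
    if best is None:
        raise FitConvergenceError("no optimizer start converged", best=None)

    rss, sol = best
    rates = np.exp(np.clip(sol.x, math.log(1e-12), math.log(1e9)))
    _, linear = _projected_residuals(sol.x, transients)

    # descending-rate convention, amplitudes permuted accordingly
    order = np.argsort(rates)[::-1]
    rates = rates[order]
    amplitudes = tuple(tuple(coef[order]) for coef in
                       (np.asarray(c[:-1]) for c in linear))
    offsets = tuple(float(c[-1]) for c in linear)

    stderr = _rate_stderr(sol, rates, order, rss, n_obs, n_params)
    return ExpFitResult(
        rates=tuple(float(k) for k in rates),
        amplitudes=amplitudes,
        offsets=offsets,
        n_exponentials=n_exponentials,
        residual_sum_squares=rss,
        information_criterion=_aicc(rss, n_obs, n_params),
        rate_stderr=stderr,
        n_observations=n_obs,
    )


def _rate_stderr(sol, rates, order, rss, n_obs, n_params) -> tuple[float, ...]:
    """Approximate rate standard errors from the profiled Jacobian.

    The residual function re-solves the linear amplitudes at every rate,
    so the finite-difference Jacobian is the profile-likelihood one; the
    usual s^2 (J^T J)^-1 estimate in log-rate space then converts to the
    rate scale by multiplying with k.
    """
    dof = n_obs - n_params
    if dof <= 0 or sol.jac is None:
        return tuple(float("nan") for _ in rates)
    try:
        jtj = sol.jac.T @ sol.jac
        cov_log = (rss / dof) * np.linalg.inv(jtj)
        sd_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))[order]
        return tuple(float(k * s) for k, s in zip(rates, sd_log))
    except np.linalg.LinAlgError:
        return tuple(float("nan") for _ in rates)


def select_model(transients: Sequence[FoldingTransient],
                 *,
                 aicc_improvement: float = 10.0,
                 min_rate_ratio: float = 3.0,
                 min_amplitude_fraction: float = 0.1) -> ExpFitResult:
    """Choose between single- and double-exponential global fits.

    The double-exponential model is preferred only when its corrected-AIC
    improvement over the single-exponential fit exceeds
    ``aicc_improvement``, the two recovered rates are separated by a
    factor of more than ``min_rate_ratio``, and each component carries at
    least ``min_amplitude_fraction`` of the signal change (median over
    transients) — a reproducible surrogate for judging residuals by eye
    that rejects vanishing-amplitude phantom phases fitting single noisy
    samples.

    Raises
    ------
    DegenerateDataError
        For constant signals (no decay component to fit).
    """
    transients = list(transients)
    if not transients:
        raise DegenerateDataError("need at least one transient")
    span = max(tr.signal.max() - tr.signal.min() for tr in transients)
    scale = max(abs(float(tr.signal.mean())) for tr in transients)
    if span <= 1e-12 * max(scale, 1.0):
        raise DegenerateDataError("constant signal: no decay component")

    fit1 = fit_exponential_global(transients, 1)
    if max(abs(a[0]) for a in fit1.amplitudes) < 1e-9 * span:
        raise DegenerateDataError("no resolvable decay amplitude")
    try:
        fit2 = fit_exponential_global(transients, 2)
    except (FitConvergenceError, DegenerateDataError):
        return fit1

    improvement = fit1.information_criterion - fit2.information_criterion
    separated = fit2.rates[1] > 0 and fit2.rates[0] / fit2.rates[1] > min_rate_ratio
    median_span = float(np.median(
        [tr.signal.max() - tr.signal.min() for tr in transients]))
    significant = all(
        float(np.median([abs(amps[j]) for amps in fit2.amplitudes]))
        >= min_amplitude_fraction * median_span
        for j in range(2))
    if improvement > aicc_improvement and separated and significant:
        return fit2
    return fit1


# ---------------------------------------------------------------------------
# t50 and summary statistics
# ---------------------------------------------------------------------------

def extract_t50(transient: FoldingTransient,
                baseline_fraction: float = 0.1) -> T50Result:
    """Half-time of a folding transient.

    Locates the global signal minimum, fits a horizontal baseline (the
    mean) to the trailing ``baseline_fraction`` of samples, and returns
    the first time at or after the minimum at which the signal crosses
    halfway between the two, by linear interpolation between the
    bracketing samples.

    Raises
    ------
    DegenerateDataError
        If the fitted baseline does not exceed the minimum (e.g. a
        monotonically decreasing trace).
    NoCrossingError
        If the signal never reaches the half level ("no folding detected").
    """
    if not 0.0 < baseline_fraction <= 0.5:
        raise DegenerateDataError("baseline_fraction must be in (0, 0.5]")
    t, s = transient.time, transient.signal
    n_tail = max(1, int(round(t.size * baseline_fraction)))
    baseline = float(np.mean(s[-n_tail:]))
    i_min = int(np.argmin(s))
    f_min = float(s[i_min])
    if baseline <= f_min:
        raise DegenerateDataError("baseline does not exceed minimum: no rise to time")
    half = 0.5 * (f_min + baseline)

    after = s[i_min:]
    idx = np.nonzero(after >= half)[0]
    if idx.size == 0:
        raise NoCrossingError("no folding detected: signal never reaches half level")
    j = i_min + int(idx[0])
    if j == i_min:
        t50 = float(t[j])
    else:
        s0, s1 = s[j - 1], s[j]
        frac = (half - s0) / (s1 - s0)
        t50 = float(t[j - 1] + frac * (t[j] - t[j - 1]))
    return T50Result(t50=t50, f_min=f_min, baseline_level=baseline,
                     baseline_fraction=baseline_fraction)


def summarize(values: Iterable[float]) -> SummaryStat:
    """Mean, sample SD (ddof=1) and s.e.m. = SD/sqrt(n) of a list of values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DegenerateDataError("cannot summarize an empty list")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryStat(mean=float(np.mean(arr)), sd=sd,
                       sem=sd / math.sqrt(arr.size), n_samples=int(arr.size))


def fold_change(numerator: SummaryStat, denominator: SummaryStat) -> FoldChange:
    """Ratio of two means with s.e.m. propagated in quadrature.

    R = X/Y and delta_R = |R| * sqrt((dX/X)^2 + (dY/Y)^2), where dX and dY
    are the s.e.m. of the two means.
    """
    x, y = numerator.mean, denominator.mean
    if x == 0 or y == 0:
        raise DegenerateDataError("fold change undefined for zero mean")
    ratio = x / y
    rel = math.sqrt((numerator.sem / x) ** 2 + (denominator.sem / y) ** 2)
    return FoldChange(ratio=ratio, error=abs(ratio) * rel,
                      numerator_mean=x, numerator_sem=numerator.sem,
                      denominator_mean=y, denominator_sem=denominator.sem)


def batch_rate_summary(transients: Sequence[FoldingTransient],
                       n_exponentials: int = 1) -> SummaryStat:
    """Shared rate fitted per liposome batch, summarized across batches.

    Replicates sharing a ``batch_id`` are globally fitted together; the
    fastest rate of each batch fit is then summarized so the reported
    s.e.m. is between batches.  Transients without a ``batch_id`` are
    treated as one batch.
    """
    groups: dict[str, list[FoldingTransient]] = {}
    for tr in transients:
        groups.setdefault(tr.batch_id or "", []).append(tr)
    rates = [fit_exponential_global(group, n_exponentials).k1
             for _, group in sorted(groups.items())]
    return summarize(rates)


# ---------------------------------------------------------------------------
# sigmoid (lag-phase) fitting, display only
# ---------------------------------------------------------------------------

def _logistic(t, lower, upper, midpoint, steepness):
    return lower + (upper - lower) / (1.0 + np.exp(-steepness * (t - midpoint)))


def fit_sigmoid(transient: FoldingTransient) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit of a lag-phase transient.

    Used for display and qualitative summary of traces showing a lag then
    rise; half-times are always taken from :func:`extract_t50`.
    """
    t, s = transient.time, transient.signal
    span = float(s.max() - s.min())
    if span <= 1e-12 * max(abs(float(s.mean())), 1.0):
        raise DegenerateDataError("constant signal: nothing to fit")

    slope = np.gradient(s, t)
    t_mid0 = float(t[int(np.argmax(slope))])
    k0 = max(4.0 * float(np.max(slope)) / span, 1e-6)
    p0 = [float(s.min()), float(s.max()), t_mid0, k0]
    try:
        # midpoint constrained to the observed window so traces without a
        # genuine inflection (e.g. pure exponentials) stay interpretable
        popt, _ = optimize.curve_fit(
            _logistic, t, s, p0=p0, maxfev=20000,
            bounds=([-np.inf, -np.inf, float(t[0]), 1e-12],
                    [np.inf, np.inf, float(t[-1]), np.inf]),
        )
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(f"sigmoid fit did not converge: {exc}") from exc
    if popt[1] <= popt[0]:
        raise FitConvergenceError("sigmoid fit collapsed (upper <= lower)",
                                  best=tuple(popt))
    rss = float(np.sum((_logistic(t, *popt) - s) ** 2))
    return SigmoidFit(lower_asymptote=float(popt[0]), upper_asymptote=float(popt[1]),
                      midpoint_time=float(popt[2]), steepness=float(popt[3]),
                      residual_sum_squares=rss)
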