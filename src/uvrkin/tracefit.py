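"""Closed-form stopped-flow trace models and their least-squares fitters.

Implements the standard transient-kinetics toolbox used for mant-nucleotide
binding and Pi-release traces:

* single exponential (association: ``A(1 - e^{-k t}) + c``; dissociation:
  ``A e^{-k t} + c``), optionally with a linear photobleach drift term,
* the observed-rate line ``kobs = k_on [ligand] + k_off``,
* the lag + burst + linear model ``A1 e^{-k_lag t} + A2 e^{-k_burst t} +
  v t + c`` for pre-steady-state Pi release, with an F-test against the
  nested pure-linear model to decide whether a burst is present at all,
* the turnover-number arithmetic ``kcat = slope / (sites × [dimer])``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .params import ExperimentCondition
from .units import per_micromolar_to_per_molar

__all__ = [
    "KineticTrace",
    "ExponentialFit",
    "BurstFit",
    "KobsLine",
    "FitError",
    "fit_single_exponential",
    "fit_kobs_line",
    "fit_burst_linear",
    "kcat_from_slope",
]


class FitError(ValueError):
    """Degenerate input or non-convergent fit."""


@dataclass(frozen=True)
class KineticTrace:
    """One averaged stopped-flow time series."""

    times: np.ndarray  # s, strictly increasing
    signal: np.ndarray  # fluorescence units or uM Pi
    condition: ExperimentCondition | None = None
    n_averaged: int = 1
    signal_kind: str = "pi_concentration"  # or mant_fluorescence
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class ExponentialFit:
    amplitude: float  # signal units
    kobs: float  # s^-1
    offset: float  # signal units
    drift_slope: float | None  # signal units per s, None if not fitted
    residual_rms: float


@dataclass(frozen=True)
class BurstFit:
    """Double-exponential + linear fit of a lag/burst/linear Pi trace.

    ``k_lag > k_burst`` by post-fit relabeling.  The burst amplitude is the
    projected intercept of the linear phase relative to the signal at time
    zero, ``-(A1 + A2)``.  ``degenerate`` flags traces the F-test found
    indistinguishable from a pure line (only ``linear_rate`` is meaningful).
    """

    A1: float
    k_lag: float
    A2: float
    k_burst: float
    linear_rate: float  # uM s^-1 (signal units per s)
    offset: float
    residual_rms: float
    degenerate: bool = False

    @property
    def burst_amplitude(self) -> float:
        return -(self.A1 + self.A2)


@dataclass(frozen=True)
class KobsLine:
    k_on: float  # M^-1 s^-1
    k_off_intercept: float  # s^-1
    slope_stderr: float  # M^-1 s^-1
    intercept_stderr: float  # s^-1


def _rms(resid: np.ndarray) -> float:
    return float(np.sqrt(np.mean(resid**2)))


def _tail_log_rate(t: np.ndarray, decay: np.ndarray, fallback: float) -> float:
    """Rate guess from log-linear regression of a positive decaying signal."""
    mask = decay > max(decay.max(), 0) * 1e-3
    if mask.sum() < 5:
        return fallback
    slope = np.polyfit(t[mask], np.log(decay[mask]), 1)[0]
    return -slope if slope < 0 else fallback


def fit_single_exponential(
    trace: KineticTrace,
    direction: str,
    drift_correct: bool | None = None,
) -> ExponentialFit:
    """Fit a rising or falling single exponential, optionally with drift.

    ``drift_correct=None`` applies the photobleach default: a linear drift
    term is included for falling (dissociation) traces of 30 s or longer,
    where slow mant-ADP bleaching shows up as a linear signal decline.
    """
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    t, y = trace.times, trace.signal
    if t.size < 20:
        raise FitError("need at least 20 points for an exponential fit")
    if drift_correct is None:
        drift_correct = direction == "falling" and t[-1] - t[0] >= 30.0

    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1e-30)
    if span < 1e-8 * scale:
        raise FitError("constant trace: amplitude ~ 0, kobs unidentifiable")
    n_tail = max(t.size // 10, 3)
    head, tail = float(np.mean(y[:n_tail])), float(np.mean(y[-n_tail:]))
    if direction == "rising" and tail < head:
        raise FitError("rising fit requested on a falling trace")
    if direction == "falling" and tail > head:
        raise FitError("falling fit requested on a rising trace")

    # initial guesses: offset from tail, rate from log-linear tail regression
    if direction == "rising":
        c0, a0 = tail, tail - head
        decay = np.clip(tail - y, 0, None)
    else:
        c0, a0 = tail, head - tail
        decay = np.clip(y - tail, 0, None)
    k0 = _tail_log_rate(t, decay, fallback=1.0 / max(t[-1] / 3, 1e-9))

    def model(p: np.ndarray) -> np.ndarray:
        a, lk, c = p[:3]
        d = p[3] if drift_correct else 0.0
        e = np.exp(-np.exp(lk) * t)
        base = a * (1 - e) if direction == "rising" else a * e
        return base + c + d * t

    p0 = [a0, np.log(max(k0, 1e-6)), c0] + ([0.0] if drift_correct else [])
    res = least_squares(lambda p: model(np.asarray(p)) - y, p0, max_nfev=20000)
    if not res.success:
        raise FitError(f"exponential fit did not converge (initial guess {p0})")
    a, lk, c = res.x[:3]
    kobs = float(np.exp(lk))
    resid = model(res.x) - y
    if abs(a) < 10 * _rms(resid) and abs(a) < 1e-3 * scale:
        raise FitError("fitted amplitude indistinguishable from zero")
    return ExponentialFit(
        amplitude=float(a),
        kobs=kobs,
        offset=float(c),
        drift_slope=float(res.x[3]) if drift_correct else None,
        residual_rms=_rms(resid),
    )


def fit_kobs_line(concentrations, kobs_values) -> KobsLine:
    """Ordinary least-squares line through (concentration, kobs) points.

    Concentrations are in µM; the slope is reported in M⁻¹ s⁻¹ so it can be
    read directly as the bimolecular association rate constant.
    """
    conc = np.asarray(concentrations, dtype=float)
    kobs = np.asarray(kobs_values, dtype=float)
    if conc.size < 3:
        raise FitError("need at least 3 concentrations for the kobs line")
    if conc.size != kobs.size:
        raise ValueError("concentrations and kobs_values must have equal length")
    fit = stats.linregress(conc, kobs)
    return KobsLine(
        k_on=per_micromolar_to_per_molar(fit.slope),
        k_off_intercept=float(fit.intercept),
        slope_stderr=per_micromolar_to_per_molar(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
    )


def _linear_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, rss) of an ordinary least-squares line."""
    A = np.vstack([t, np.ones_like(t)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ coef - y
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_burst_linear(trace: KineticTrace, alpha: float = 0.01) -> BurstFit:
    """Fit ``A1 e^{-k_lag t} + A2 e^{-k_burst t} + v t + c`` to a Pi trace.

    Seeding follows a two-stage bootstrap: the linear phase is estimated from
    the last half of the trace, the burst rate from the decay of the residual
    toward that line, and the lag rate starts at 10x the burst rate.  An
    F-test (``alpha``) against the nested pure-linear model decides whether
    the trace supports a burst at all; if not, the result carries
    ``degenerate=True`` with only the linear rate filled in.
    """
    t, y = trace.times, trace.signal
    if t.size < 12:
        raise FitError("burst fit needs at least 12 points")

    half = t >= t[0] + 0.5 * (t[-1] - t[0])
    v0, c0, _ = _linear_fit(t[half], y[half])
    v0 = max(v0, 0.0)
    slope_lin, icpt_lin, rss_lin = _linear_fit(t, y)

    # bootstrap burst-rate guess from the half-life of the gap between the
    # projected linear phase and the signal (robust to noise in the tail)
    gap = (v0 * t + c0) - y
    n_head = max(t.size // 50, 3)
    gap0 = float(np.mean(gap[:n_head]))
    fallback = 2.0 / max(t[-1] - t[0], 1e-9)
    if gap0 > 0:
        below = np.nonzero(gap < 0.5 * gap0)[0]
        t_half = t[below[0]] - t[0] if below.size else 0.5 * (t[-1] - t[0])
        k_b0 = np.log(2.0) / max(t_half, (t[1] - t[0])) if t_half > 0 else fallback
    else:
        k_b0 = fallback

    def model(p: np.ndarray) -> np.ndarray:
        a1, lk1, a2, lk2, v, c = p
        return (a1 * np.exp(-np.exp(lk1) * t) + a2 * np.exp(-np.exp(lk2) * t)
                + v * t + c)

    scale = max(abs(y).max(), 1e-30)
    best = None
    for kb in (k_b0, 0.5 * k_b0, 3.0 * k_b0):
        p0 = [c0, np.log(10 * kb), -2 * c0, np.log(kb), v0, c0]
        lb = [-np.inf, np.log(1e-6), -np.inf, np.log(1e-6), 0.0, -np.inf]
        ub = [np.inf, np.log(1e6), np.inf, np.log(1e6), np.inf, np.inf]
        try:
            r = least_squares(
                lambda p: model(np.asarray(p)) - y, p0, bounds=(lb, ub),
                max_nfev=40000,
            )
        except Exception:  # pragma: no cover - pathological seeds
            continue
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        raise FitError("burst fit failed to converge from all seeds")

    rss_burst = float(2 * best.cost)
    n = t.size
    # nested-model F-test: 4 extra parameters over the 2-parameter line
    df1, df2 = 4, n - 6
    tiny = (1e-12 * scale) ** 2 * n
    if rss_burst < tiny and rss_lin < tiny:
        burst_supported = False  # both perfect: pure line
    elif rss_burst < tiny:
        burst_supported = True
    else:
        F = ((rss_lin - rss_burst) / df1) / (rss_burst / df2)
        burst_supported = F > stats.f.ppf(1 - alpha, df1, df2)

    if not burst_supported or rss_burst > rss_lin:
        return BurstFit(
            A1=float("nan"), k_lag=float("nan"), A2=float("nan"),
            k_burst=float("nan"), linear_rate=max(slope_lin, 0.0),
            offset=icpt_lin, residual_rms=float(np.sqrt(rss_lin / n)),
            degenerate=True,
        )

    a1, lk1, a2, lk2, v, c = best.x
    k_a, k_b = float(np.exp(lk1)), float(np.exp(lk2))
    if k_b > k_a:  # relabel so k_lag > k_burst
        a1, a2, k_a, k_b = a2, a1, k_b, k_a
    return BurstFit(
        A1=float(a1), k_lag=k_a, A2=float(a2), k_burst=k_b,
        linear_rate=float(v), offset=float(c),
        residual_rms=float(np.sqrt(rss_burst / n)),
    )


def kcat_from_slope(
    linear_rate: float, active_sites: int, enzyme_total: float
) -> float:
    """Steady-state turnover per site: ``slope / (sites × [dimer])``.

    Four sites for the wild-type dimer, two for single-site mutants.
    """
    if active_sites not in (2, 4):
        raise ValueError("active_sites must be 2 or 4")
    if enzyme_total <= 0:
        raise ValueError("enzyme_total must be > 0")
    return linear_rate / (active_sites * enzyme_total)
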