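"""Global mechanism fitting across trace series, with profile-chi-square
(confidence-contour) error bounds.

A single parameter set is fit simultaneously to all Pi-release traces of a
concentration series by bounded trust-region least squares on
log-transformed parameters (rates are positive and span decades).  The
distal dissociation constant KD1 is imposed as a link, ``k_minus1 = KD1 ×
k1`` with ``k1`` free, mirroring how the binding parameters are tied
together during mechanism fitting.  Parameter uncertainty is reported two
ways: asymptotic standard errors from the Jacobian, and confidence-contour
bounds — the interval over which the re-optimized chi-square stays below
``threshold_ratio`` times its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .mechanism import build_mechanism, simulate
from .params import MechanismVariant, RateParameterSet
from .tracefit import KineticTrace

__all__ = [
    "FitSpec",
    "FitResult",
    "ContourBound",
    "global_fit",
    "confidence_contours",
]

#: parameters that may float in a global fit
FITTABLE = ("k1", "KD2", "k3", "k4", "k5a", "k5b", "n_sites")

DEFAULT_THRESHOLD_RATIO = 1.1


@dataclass(frozen=True)
class FitSpec:
    """Which parameters float, which are pinned, and how.

    ``free_params`` float (log scale); ``fixed_params`` override the starting
    parameter set and stay pinned; everything else keeps its starting value.
    All parameters are shared (linked) across traces.  ``bounds`` maps a
    parameter name to a (low, high) pair; unlisted free parameters get a wide
    default of x1000 around the start.  ``seed`` drives multistart jitter.
    """

    free_params: tuple[str, ...]
    fixed_params: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    seed: int = 0
    threshold_ratio: float = DEFAULT_THRESHOLD_RATIO
    multistart: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.free_params) - set(FITTABLE)
        if unknown:
            raise ValueError(f"cannot float parameters: {sorted(unknown)}")
        overlap = set(self.free_params) & set(self.fixed_params)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < np.inf):
                raise ValueError(f"bounds for {name} must be finite and positive")


@dataclass(frozen=True)
class ContourBound:
    lower: float
    upper: float
    open_lower: bool = False
    open_upper: bool = False


@dataclass
class FitResult:
    estimates: dict
    stderr: dict
    chi2: float
    dof: int
    converged: bool
    params: RateParameterSet
    contour_bounds: dict = field(default_factory=dict)
    objective_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be >= 0")


def _apply(start: RateParameterSet, names, values, fixed) -> RateParameterSet:
    """Start params + fixed overrides + free values, keeping the KD1 link."""
    updates = dict(fixed)
    updates.update(zip(names, values))
    if "k1" in updates:
        # KD1 link: k_minus1 = KD1[uM] * k1 (k1 in M^-1 s^-1, KD1 uM -> M)
        updates["k_minus1"] = start.KD1 * 1e-6 * updates["k1"]
    return start.with_updates(**updates)


def _residuals_builder(traces, variant, start, names, fixed):
    conds = [tr.condition for tr in traces]

    def residuals(x: np.ndarray) -> np.ndarray:
        params = _apply(start, names, np.exp(x), fixed)
        network = build_mechanism(variant, params)
        out = []
        for tr, cond in zip(traces, conds):
            t = tr.times
            grid = t if t[0] == 0 else np.concatenate([[0.0], t])
            traj = simulate(network, cond, grid, rtol=1e-7, atol=1e-9)
            pi = traj.cumulative_pi if t[0] == 0 else traj.cumulative_pi[1:]
            out.append(pi - tr.signal)
        return np.concatenate(out)

    return residuals


def _log_bounds(spec: FitSpec, names, x0: np.ndarray):
    lb, ub = np.empty_like(x0), np.empty_like(x0)
    for i, name in enumerate(names):
        if name in spec.bounds:
            lo, hi = spec.bounds[name]
        else:
            lo, hi = np.exp(x0[i]) / 1e3, np.exp(x0[i]) * 1e3
        if name == "n_sites":
            hi = min(hi, 8.0)
        lb[i], ub[i] = np.log(lo), np.log(hi)
    return lb, ub


def initial_estimates(
    traces: list[KineticTrace], base: RateParameterSet
) -> RateParameterSet:
    """Seed a global fit from single-trace estimates, the way mechanism
    fitting is bootstrapped in practice: the burst fit of the richest trace
    supplies the hydrolysis-limiting rate (burst rate), the burst site count
    (amplitude per dimer) and the turnover-limiting rate (linear slope per
    site); the Pi-release step starts an order of magnitude above the burst
    rate."""
    from .tracefit import fit_burst_linear

    best = max(traces, key=lambda tr: float(np.max(tr.signal)))
    enzyme = best.condition.enzyme_total
    fit = fit_burst_linear(best)
    if fit.degenerate:
        kcat = fit.linear_rate / (4 * enzyme)
        return base.with_updates(k3=max(4 * kcat, 1e-3),
                                 k5a=max(10 * kcat, 1e-3),
                                 k5b=max(kcat, 1e-3))
    n0 = float(np.clip(fit.burst_amplitude / enzyme, 0.5, 8.0))
    k3_0 = fit.k_burst
    k5_0 = max(fit.linear_rate / (4 * enzyme), 1e-3)
    return base.with_updates(k3=k3_0, k4=10 * k3_0, k5a=2 * k5_0, k5b=k5_0,
                             n_sites=n0)


def global_fit(
    traces: list[KineticTrace],
    variant: MechanismVariant,
    spec: FitSpec,
    start: RateParameterSet,
) -> FitResult:
    """Fit the mechanism simultaneously to a set of Pi-release traces.

    Minimizes the summed squared residual between simulated cumulative Pi and
    every trace, with all parameters shared across traces.  Residuals are
    weighted uniformly per point.  Returns estimates with asymptotic standard
    errors; confidence-contour bounds are filled in separately by
    :func:`confidence_contours`.
    """
    if len(traces) < 2:
        raise ValueError("global fit needs at least 2 traces")
    if len({(tr.condition.enzyme_total, tr.condition.atp_total)
            for tr in traces}) < 2:
        raise ValueError("traces must cover at least 2 distinct conditions")
    for tr in traces:
        if tr.signal_kind != "pi_concentration":
            raise ValueError("global fit expects pi_concentration traces")

    names = tuple(spec.free_params)
    start = _apply(start, (), (), spec.fixed_params)
    if not names:
        # everything pinned: report the goodness of fit of the start set
        resid0 = _residuals_builder(traces, variant, start, (), spec.fixed_params)
        r = resid0(np.empty(0))
        n_points = sum(tr.times.size for tr in traces)
        return FitResult(
            estimates={}, stderr={}, chi2=float(r @ r),
            dof=max(n_points, 1), converged=True, params=start,
            objective_history=[float(r @ r)],
        )
    x0 = np.log([getattr(start, n) for n in names])
    lb, ub = _log_bounds(spec, names, x0)
    resid = _residuals_builder(traces, variant, start, names, spec.fixed_params)

    history: list[float] = []

    def tracked(x: np.ndarray) -> np.ndarray:
        r = resid(x)
        history.append(float(r @ r))
        return r

    rng = np.random.default_rng(spec.seed)
    best = None
    for trial in range(max(spec.multistart, 1)):
        xt = x0 if trial == 0 else np.clip(
            x0 + rng.normal(0.0, 0.3, x0.size), lb, ub
        )
        res = least_squares(
            tracked, np.clip(xt, lb, ub), bounds=(lb, ub), method="trf",
            x_scale="jac", diff_step=1e-3, max_nfev=400 * (len(names) + 1),
        )
        if best is None or res.cost < best.cost:
            best = res

    values = np.exp(best.x)
    chi2 = float(2 * best.cost)
    n_points = sum(tr.times.size for tr in traces)
    dof = max(n_points - len(names), 1)

    # asymptotic standard errors via the log-scale Jacobian (delta method)
    stderr = {}
    try:
        J = best.jac
        cov_log = np.linalg.inv(J.T @ J) * (chi2 / dof)
        sd_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
        stderr = {n: float(v * s) for n, v, s in zip(names, values, sd_log)}
    except np.linalg.LinAlgError:
        stderr = {n: float("nan") for n in names}

    # objective history as the monotone accepted-cost sequence
    accepted = list(np.minimum.accumulate(history)) if history else []

    return FitResult(
        estimates={n: float(v) for n, v in zip(names, values)},
        stderr=stderr,
        chi2=chi2,
        dof=dof,
        converged=bool(best.status > 0),
        params=_apply(start, names, values, spec.fixed_params),
        objective_history=accepted,
    )


def _profile_chi2(x_fixed, i_fixed, x_start, resid, lb, ub, names):
    """Re-optimize the other free parameters at one pinned value."""
    free_idx = [j for j in range(len(names)) if j != i_fixed]
    if not free_idx:
        r = resid(np.array([x_fixed]))
        return float(r @ r), np.array([x_fixed])

    def sub_resid(xs: np.ndarray) -> np.ndarray:
        full = x_start.copy()
        full[free_idx] = xs
        full[i_fixed] = x_fixed
        return resid(full)

    res = least_squares(
        sub_resid, x_start[free_idx], bounds=(lb[free_idx], ub[free_idx]),
        method="trf", x_scale="jac", diff_step=1e-3,
        max_nfev=100 * len(free_idx),
    )
    full = x_start.copy()
    full[free_idx] = res.x
    full[i_fixed] = x_fixed
    return float(2 * res.cost), full


def confidence_contours(
    result: FitResult,
    traces: list[KineticTrace],
    variant: MechanismVariant,
    spec: FitSpec,
    start: RateParameterSet,
    threshold_ratio: float | None = None,
    step_factor: float = 1.3,
    max_steps: int = 9,
    params_subset: tuple[str, ...] | None = None,
) -> dict:
    """Profile-chi-square bounds for every free parameter (or for
    ``params_subset`` of them).

    Each parameter is stepped outward from its estimate on a log grid
    (``step_factor`` per step), re-optimizing all other free parameters at
    every grid point, until the profiled chi-square exceeds
    ``threshold_ratio x chi2_min``; the crossing is located by
    log-interpolation.  A profile still below threshold at the edge of the
    search range is reported as an open bound on that side — the signature
    of an unidentifiable parameter.  Results are stored in
    ``result.contour_bounds`` and returned.
    """
    if not result.converged:
        raise ValueError("confidence contours require a converged fit")
    ratio = threshold_ratio if threshold_ratio is not None else spec.threshold_ratio
    names = tuple(spec.free_params)
    resid = _residuals_builder(traces, variant,
                               _apply(start, (), (), spec.fixed_params),
                               names, spec.fixed_params)
    x_hat = np.log([result.estimates[n] for n in names])
    lb, ub = _log_bounds(spec, names, x_hat)
    threshold = ratio * max(result.chi2, 1e-300)

    profiled = (set(params_subset) if params_subset is not None
                else set(names))
    bounds: dict[str, ContourBound] = {}
    for i, name in enumerate(names):
        if name not in profiled:
            continue
        limits = []
        for sign in (-1, +1):
            x_prev = x_hat[i]
            chi_prev = result.chi2
            warm = x_hat.copy()
            open_side = True
            limit = float(np.exp(np.clip(
                x_hat[i] + sign * max_steps * np.log(step_factor), lb[i], ub[i]
            )))
            for j in range(1, max_steps + 1):
                x_try = x_hat[i] + sign * j * np.log(step_factor)
                x_try = float(np.clip(x_try, lb[i], ub[i]))
                chi, warm = _profile_chi2(x_try, i, warm, resid, lb, ub, names)
                if chi > threshold:
                    # refine the crossing inside the bracket; the profile is
                    # locally convex, so bisection-style root finding on
                    # (chi2 - threshold) locates it accurately
                    from scipy.optimize import brentq

                    warm_ref = warm.copy()

                    def excess(x_val: float) -> float:
                        c, _ = _profile_chi2(x_val, i, warm_ref, resid,
                                             lb, ub, names)
                        return c - threshold

                    if chi > chi_prev and abs(x_try - x_prev) > 1e-12:
                        a, b = sorted((x_prev, x_try))
                        x_cross = brentq(excess, a, b,
                                         xtol=abs(x_try - x_prev) * 0.05,
                                         maxiter=30)
                    else:
                        x_cross = x_try
                    limit = float(np.exp(x_cross))
                    open_side = False
                    break
                x_prev, chi_prev = x_try, chi
                if x_try in (lb[i], ub[i]):
                    break
            limits.append((limit, open_side))
        (lo, open_lo), (hi, open_hi) = limits
        bounds[name] = ContourBound(
            lower=min(lo, result.estimates[name]),
            upper=max(hi, result.estimates[name]),
            open_lower=open_lo, open_upper=open_hi,
        )
    if params_subset is None:
        result.contour_bounds = bounds
    else:
        result.contour_bounds.update(bounds)
    return bounds
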