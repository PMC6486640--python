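"""FRET titration analysis: efficiency, tight-binding isotherms and
breakpoint stoichiometry.

Binding stoichiometry is measured by titrating the dimer (donor tryptophans)
with a mant nucleotide (acceptor) well above the dissociation constant: the
FRET efficiency rises linearly while sites remain free and plateaus once
they are filled, so the intersection of the two slopes (the breakpoint)
divided by the dimer concentration counts the binding sites per dimer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "TitrationIsotherm",
    "BreakpointFit",
    "efret",
    "simulate_isotherm",
    "fit_breakpoint",
    "NoInflectionError",
]


class NoInflectionError(ValueError):
    """Isotherm has no detectable slope change (single line fits as well)."""


@dataclass(frozen=True)
class TitrationIsotherm:
    ligand_total: np.ndarray  # uM, increasing
    efret: np.ndarray  # dimensionless
    enzyme_total: float  # dimer, uM
    replicate_sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        lig = np.asarray(self.ligand_total, dtype=float)
        e = np.asarray(self.efret, dtype=float)
        if lig.shape != e.shape or lig.ndim != 1:
            raise ValueError("ligand_total and efret must be 1-D, equal length")
        if np.any(lig < 0) or np.any(np.diff(lig) <= 0):
            raise ValueError("ligand grid must be non-negative and increasing")
        object.__setattr__(self, "ligand_total", lig)
        object.__setattr__(self, "efret", e)


@dataclass(frozen=True)
class BreakpointFit:
    breakpoint: float  # uM
    slope_initial: float  # per uM
    slope_final: float  # per uM
    stoichiometry: float  # breakpoint / enzyme_total, per dimer
    residual_rms: float


def efret(f_da, f_d):
    """FRET efficiency ``E = 1 - F_DA / F_D`` from background-corrected
    donor+acceptor and donor-only intensities.

    Values are clipped to [0, 1]; scalar inputs return a scalar.  Raises if
    any donor intensity is non-positive.
    """
    f_da_arr = np.asarray(f_da, dtype=float)
    f_d_arr = np.asarray(f_d, dtype=float)
    if np.any(f_d_arr <= 0):
        raise ValueError("donor intensity F_D must be > 0")
    e = 1.0 - f_da_arr / f_d_arr
    if np.any(e < 0) or np.any(e > 1):
        import warnings

        warnings.warn(
            "FRET efficiency outside [0, 1] clipped; check background "
            "correction", RuntimeWarning, stacklevel=2,
        )
    out = np.clip(e, 0.0, 1.0)
    if np.isscalar(f_da) and np.isscalar(f_d):
        return float(out)
    return out


def bound_ligand(ligand_total, site_total: float, kd: float):
    """Bound ligand from the tight-binding quadratic.

    Solves ``B^2 - (L + S + Kd) B + L S = 0`` for the physical root, which
    never exceeds ``min(L, S)``.  ``kd = 0`` gives the stoichiometric limit
    ``min(L, S)`` exactly.
    """
    L = np.asarray(ligand_total, dtype=float)
    S, Kd = float(site_total), float(kd)
    b = L + S + Kd
    disc = np.sqrt(np.clip(b * b - 4.0 * L * S, 0.0, None))
    return 0.5 * (b - disc)


def simulate_isotherm(
    enzyme_total: float,
    stoichiometry: float,
    kd: float,
    efret_max: float,
    ligand_grid,
) -> TitrationIsotherm:
    """Forward model of the titration: efficiency proportional to fractional
    site occupancy, with total sites ``stoichiometry × enzyme_total``."""
    if stoichiometry <= 0:
        raise ValueError("stoichiometry must be > 0")
    if kd < 0:
        raise ValueError("kd must be >= 0")
    grid = np.asarray(ligand_grid, dtype=float)
    sites = stoichiometry * enzyme_total
    bound = bound_ligand(grid, sites, kd)
    return TitrationIsotherm(
        ligand_total=grid, efret=efret_max * bound / sites,
        enzyme_total=enzyme_total,
    )


def _segmented_rss(x: np.ndarray, y: np.ndarray, knot: float):
    """RSS of the continuous two-segment linear model with a knot."""
    A = np.vstack([np.ones_like(x), x, np.clip(x - knot, 0.0, None)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ coef - y
    return float(resid @ resid), coef


def fit_breakpoint(
    isotherm: TitrationIsotherm, alpha: float = 0.01, n_knots: int = 50
) -> BreakpointFit:
    """Two-segment continuous piecewise-linear fit of the isotherm.

    The knot is located by a grid search over ``n_knots`` candidates between
    the 2nd and (n-1)th ligand points, refined by bounded scalar
    minimization.  An F-test (``alpha``) against a single line raises
    :class:`NoInflectionError` when the isotherm has no curvature.
    """
    x, y = isotherm.ligand_total, isotherm.efret
    if x.size < 6:
        raise ValueError("breakpoint fit needs at least 6 titration points")

    lo, hi = x[1], x[-2]
    knots = np.linspace(lo, hi, n_knots)
    rss = np.array([_segmented_rss(x, y, k)[0] for k in knots])
    k_best = knots[int(np.argmin(rss))]
    span = (hi - lo) / (n_knots - 1)
    res = minimize_scalar(
        lambda k: _segmented_rss(x, y, k)[0],
        bounds=(max(lo, k_best - span), min(hi, k_best + span)),
        method="bounded",
    )
    knot = float(res.x)
    rss_seg, coef = _segmented_rss(x, y, knot)

    # single-line null model
    line = stats.linregress(x, y)
    rss_lin = float(np.sum((line.intercept + line.slope * x - y) ** 2))
    n = x.size
    scale = max(np.abs(y).max(), 1e-30)
    tiny = (1e-12 * scale) ** 2 * n
    if rss_seg < tiny and rss_lin < tiny:
        raise NoInflectionError("isotherm is a straight line: no inflection")
    if rss_seg >= tiny:
        F = ((rss_lin - rss_seg) / 2) / (rss_seg / (n - 4))
        if not F > stats.f.ppf(1 - alpha, 2, n - 4):
            raise NoInflectionError(
                "single line fits as well as two segments: no inflection"
            )

    slope_initial = float(coef[1])
    slope_final = float(coef[1] + coef[2])
    return BreakpointFit(
        breakpoint=knot,
        slope_initial=slope_initial,
        slope_final=slope_final,
        stoichiometry=knot / isotherm.enzyme_total,
        residual_rms=float(np.sqrt(rss_seg / n)),
    )
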