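"""Synthetic stopped-flow and titration data with the experiments' statistical
structure.

Every experiment class the mechanism is tested against can be generated here
with no external data: pseudo-first-order mant-nucleotide association,
chase dissociation with photobleach drift, Pi-release trace series through
the phosphate-reporter model, and FRET titrations.  Generators are
deterministic given the :class:`NoiseModel` seed.

The noise model mimics shot averaging: Gaussian noise of
``gaussian_sd_frac`` x full scale per shot, divided by ``sqrt(n_averaged)``
after averaging, plus (for long dissociation traces) a slow linear
photobleach drift of at most ``drift_frac_per_150s`` of full scale per
150 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fret import TitrationIsotherm, simulate_isotherm
from .mechanism import ReactionNetwork, build_mechanism, simulate
from .params import ExperimentCondition, MechanismVariant, RateParameterSet
from .tracefit import KineticTrace
from .units import per_molar_to_per_micromolar

__all__ = [
    "NoiseModel",
    "ReporterModel",
    "gen_association",
    "gen_dissociation",
    "gen_pi_series",
    "gen_titration",
    "two_series_design",
]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian full-scale noise + averaging + photobleach drift."""

    gaussian_sd_frac: float = 0.02
    n_averaged: int = 4
    drift_frac_per_150s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd_frac < 0:
            raise ValueError("gaussian_sd_frac must be >= 0")
        if not 0 <= self.drift_frac_per_150s <= 0.2:
            raise ValueError("drift_frac_per_150s must lie in [0, 0.2]")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")

    @property
    def effective_sd_frac(self) -> float:
        """Residual noise fraction after shot averaging."""
        return self.gaussian_sd_frac / np.sqrt(self.n_averaged)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(
        self, clean: np.ndarray, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        rng = rng if rng is not None else self.rng()
        scale = float(np.abs(clean).max())
        if scale == 0.0:
            return clean.copy()
        return clean + rng.normal(0.0, self.effective_sd_frac * scale, clean.shape)


@dataclass(frozen=True)
class ReporterModel:
    """Fluorescent phosphate-binding-protein reporter.

    The coumarin-labeled phosphate binding protein binds Pi fast (1e8
    M⁻¹ s⁻¹) and tightly (KD 0.1 µM), so by default reporting is treated as
    instantaneous and linear up to saturation; the explicit first-order
    reporter lag is available for cross-checking that approximation.
    ``background_at_zero`` stands in for the residual signal the Pi-mopping
    background system leaves at time zero.
    """

    pbp_total: float = 15.0  # uM
    pbp_kon: float = 1e8  # M^-1 s^-1
    pbp_kd: float = 0.1  # uM
    calibration_gain: float = 1.0  # signal per uM Pi
    background_at_zero: float = 0.0

    def saturated(self, pi_max: float) -> bool:
        return pi_max > 0.9 * self.pbp_total

    def respond(self, times: np.ndarray, pi: np.ndarray, lag: bool) -> np.ndarray:
        """Raw reporter signal for a cumulative-Pi time course."""
        if not lag:
            reported = np.minimum(pi, self.pbp_total)
        else:
            from scipy.integrate import solve_ivp

            kon = per_molar_to_per_micromolar(self.pbp_kon)
            koff = kon * self.pbp_kd

            def rhs(t, y):
                b = y[0]
                free_pi = max(float(np.interp(t, times, pi)) - b, 0.0)
                return [kon * (self.pbp_total - b) * free_pi - koff * b]

            sol = solve_ivp(rhs, (times[0], times[-1]), [0.0], t_eval=times,
                            method="LSODA", rtol=1e-8, atol=1e-10)
            reported = np.clip(sol.y[0], 0.0, self.pbp_total)
        return self.calibration_gain * reported + self.background_at_zero

    def calibrate_back(self, signal: np.ndarray) -> np.ndarray:
        return (signal - self.background_at_zero) / self.calibration_gain


def gen_association(
    k_on: float,
    k_off: float,
    mant_conc: float,
    noise: NoiseModel,
    duration: float,
    enzyme_total: float = 0.1,
    n_points: int = 500,
) -> KineticTrace:
    """Pseudo-first-order mant-nucleotide association trace.

    ``kobs = k_on [mant] + k_off`` (k_on in M⁻¹ s⁻¹); the amplitude is
    proportional to the equilibrium bound fraction of the enzyme.  A warning
    is recorded when the pseudo-first-order condition (mant at least 10x
    enzyme) is violated.
    """
    warnings: tuple[str, ...] = ()
    if mant_conc < 10 * enzyme_total and mant_conc > 0:
        warnings = ("pseudo-first-order condition violated: mant < 10x enzyme",)
    kon_um = per_molar_to_per_micromolar(k_on)
    kobs = kon_um * mant_conc + k_off
    t = np.linspace(0.0, duration, n_points)
    if mant_conc == 0 or kon_um == 0:
        clean = np.zeros_like(t)
    else:
        kd = k_off / kon_um  # uM
        frac_bound = mant_conc / (mant_conc + kd) if (mant_conc + kd) > 0 else 1.0
        clean = frac_bound * (1.0 - np.exp(-kobs * t))
    cond = ExperimentCondition(enzyme_total=enzyme_total, mant_conc=mant_conc)
    return KineticTrace(
        times=t, signal=noise.apply(clean), condition=cond,
        n_averaged=noise.n_averaged, signal_kind="mant_fluorescence",
        warnings=warnings,
    )


def gen_dissociation(
    k_off: float,
    chase: str,
    noise: NoiseModel,
    duration: float,
    chase_conc: float = 2000.0,
    enzyme_total: float = 0.1,
    mant_conc: float = 10.0,
    n_points: int = 1000,
) -> KineticTrace:
    """Chase dissociation trace: falling exponential at ``k_off`` plus the
    linear photobleach drift of the noise model."""
    t = np.linspace(0.0, duration, n_points)
    amplitude = 1.0
    clean = amplitude * np.exp(-k_off * t)
    drift_rate = noise.drift_frac_per_150s * amplitude / 150.0
    clean = clean - drift_rate * t
    cond = ExperimentCondition(
        enzyme_total=enzyme_total, mant_conc=mant_conc,
        chase=chase, chase_conc=chase_conc,
    )
    return KineticTrace(
        times=t, signal=noise.apply(clean), condition=cond,
        n_averaged=noise.n_averaged, signal_kind="mant_fluorescence",
    )


#: enzyme series (µM dimer) at 1 mM ATP and ATP series (µM) at 2 µM dimer
ENZYME_SERIES = (0.125, 0.25, 0.5, 1.0, 2.0)
ATP_SERIES = (10.0, 20.0, 50.0, 100.0, 200.0, 350.0, 500.0, 1000.0, 2000.0)


def two_series_design(
    dna: str = "none", dna_conc: float = 0.0
) -> list[ExperimentCondition]:
    """The full 14-condition design: enzyme titration at 1 mM ATP plus ATP
    titration at 2 µM dimer."""
    conds = [
        ExperimentCondition(enzyme_total=e, atp_total=1000.0, dna=dna,
                            dna_conc=dna_conc)
        for e in ENZYME_SERIES
    ]
    conds += [
        ExperimentCondition(enzyme_total=2.0, atp_total=a, dna=dna,
                            dna_conc=dna_conc)
        for a in ATP_SERIES
    ]
    return conds


def _auto_duration(
    network: ReactionNetwork,
    condition: ExperimentCondition,
    reporter: ReporterModel,
    cap: float = 60.0,
    floor: float = 5.0,
) -> float:
    """Trace length: until projected Pi reaches 90% of reporter capacity,
    clamped to [floor, cap] seconds."""
    t = np.linspace(0.0, cap, 200)
    traj = simulate(network, condition, t, rtol=1e-6, atol=1e-8)
    limit = 0.9 * reporter.pbp_total
    over = traj.cumulative_pi >= limit
    if not over.any():
        return cap
    return float(min(max(t[over][0], floor), cap))


def gen_pi_series(
    variant: MechanismVariant,
    params: RateParameterSet,
    conditions: list[ExperimentCondition],
    noise: NoiseModel,
    reporter: ReporterModel | None = None,
    duration: float | None = None,
    n_points: int = 250,
    reporter_lag: bool = False,
    return_raw: bool = False,
):
    """Simulate a set of Pi-release traces through the reporter model.

    Each condition is integrated, cumulative Pi is passed through the
    reporter (instantaneous linear response by default), full-scale Gaussian
    noise is added on the signal scale, and the traces are calibrated back to
    µM Pi.  Traces whose Pi approaches reporter capacity carry a saturation
    warning.  With ``return_raw=True`` the raw-signal traces are returned as
    a second list.
    """
    reporter = reporter if reporter is not None else ReporterModel()
    network = build_mechanism(variant, params)
    seeds = np.random.SeedSequence(noise.seed).spawn(len(conditions))
    calibrated, raw = [], []
    for cond, seed in zip(conditions, seeds):
        dur = duration if duration is not None else _auto_duration(
            network, cond, reporter
        )
        # log-spaced time base, as acquired on a stopped flow: resolves the
        # ~100 ms lag and burst as well as the linear phase
        t = np.concatenate([[0.0], np.geomspace(1e-3, dur, n_points - 1)])
        traj = simulate(network, cond, t)
        warnings: tuple[str, ...] = ()
        if reporter.saturated(float(traj.cumulative_pi.max())):
            warnings = ("reporter saturation: Pi approaches PBP capacity",)
        raw_clean = reporter.respond(t, traj.cumulative_pi, lag=reporter_lag)
        raw_noisy = noise.apply(raw_clean, np.random.default_rng(seed))
        kwargs = dict(condition=cond, n_averaged=noise.n_averaged,
                      signal_kind="pi_concentration", warnings=warnings)
        calibrated.append(
            KineticTrace(times=t, signal=reporter.calibrate_back(raw_noisy),
                         **kwargs)
        )
        if return_raw:
            raw.append(KineticTrace(times=t, signal=raw_noisy, **kwargs))
    if return_raw:
        return calibrated, raw
    return calibrated


def gen_titration(
    enzyme_total: float = 3.0,
    stoichiometry: float = 2.3,
    kd: float = 0.2,
    efret_max: float = 0.35,
    noise: NoiseModel | None = None,
    ligand_grid=None,
    replicates: int = 3,
) -> TitrationIsotherm:
    """FRET titration with replicate noise (replicates averaged, SEM kept)."""
    noise = noise if noise is not None else NoiseModel()
    grid = (np.asarray(ligand_grid, dtype=float) if ligand_grid is not None
            else np.linspace(0.0, 20.0, 21))
    if stoichiometry == 0:
        clean = np.zeros_like(grid)
        iso_enzyme = enzyme_total
    else:
        iso = simulate_isotherm(enzyme_total, stoichiometry, kd, efret_max, grid)
        clean, iso_enzyme = iso.efret, iso.enzyme_total
    rng = noise.rng()
    scale = float(np.abs(clean).max())
    if scale == 0.0 or noise.gaussian_sd_frac == 0.0:
        reps = np.tile(clean, (replicates, 1))
    else:
        reps = clean + rng.normal(
            0.0, noise.gaussian_sd_frac * scale, (replicates, grid.size)
        )
    mean = reps.mean(axis=0)
    sem = (reps.std(axis=0, ddof=1) / np.sqrt(replicates)
           if replicates > 1 else np.zeros_like(mean))
    return TitrationIsotherm(
        ligand_total=grid, efret=mean, enzyme_total=iso_enzyme,
        replicate_sem=sem,
    )
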