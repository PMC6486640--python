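"""Global mechanism fitting: recovery, identifiability, and contour bounds."""

import numpy as np
import pytest

import uvrkin as uk


@pytest.fixture(scope="module")
def small_fit():
    """A reduced recovery problem reused across tests: 4 traces spanning both
    enzyme and ATP, 3 free parameters, 2% shot noise."""
    variant, truth = uk.variant_preset("wild_type_apo")
    conds = [uk.ExperimentCondition(enzyme_total=e, atp_total=a)
             for e, a in ((2.0, 1000.0), (0.5, 1000.0), (2.0, 100.0),
                          (2.0, 350.0))]
    traces = uk.gen_pi_series(variant, truth, conds, uk.NoiseModel(seed=5),
                              n_points=150)
    spec = uk.FitSpec(free_params=("k3", "k4", "n_sites"), seed=5)
    start = truth.with_updates(k3=2.0, k4=25.0, n_sites=2.2)
    result = uk.global_fit(traces, variant, spec, start)
    return variant, truth, traces, spec, start, result


def test_spec_validation():
    with pytest.raises(ValueError, match="float"):
        uk.FitSpec(free_params=("nope",))
    with pytest.raises(ValueError, match="free and fixed"):
        uk.FitSpec(free_params=("k3",), fixed_params={"k3": 1.0})
    with pytest.raises(ValueError, match="bounds"):
        uk.FitSpec(free_params=("k3",), bounds={"k3": (2.0, 1.0)})


def test_global_fit_input_validation(small_fit):
    variant, truth, traces, spec, start, _ = small_fit
    with pytest.raises(ValueError, match="at least 2"):
        uk.global_fit(traces[:1], variant, spec, truth)
    bad = [
        uk.KineticTrace(times=tr.times, signal=tr.signal,
                        condition=tr.condition,
                        signal_kind="mant_fluorescence")
        for tr in traces[:2]
    ]
    with pytest.raises(ValueError, match="pi_concentration"):
        uk.global_fit(bad, variant, spec, truth)


def test_perfect_start_zero_noise_zero_chi2():
    variant, truth = uk.variant_preset("wild_type_apo")
    conds = [uk.ExperimentCondition(enzyme_total=e, atp_total=1000.0)
             for e in (0.5, 2.0)]
    traces = uk.gen_pi_series(
        variant, truth, conds,
        uk.NoiseModel(gaussian_sd_frac=0.0, n_averaged=1, seed=0),
        n_points=100,
    )
    result = uk.global_fit(traces, variant,
                           uk.FitSpec(free_params=()), truth)
    scale = max(tr.signal.max() for tr in traces) ** 2 * 200
    assert result.chi2 <= 1e-8 * scale


def test_recovery_within_ten_percent(small_fit):
    variant, truth, _, _, _, result = small_fit
    assert result.converged
    for name, est in result.estimates.items():
        assert est == pytest.approx(getattr(truth, name), rel=0.10), name


def test_kd1_link_preserved(small_fit):
    *_, result = small_fit
    assert result.params.KD1 == pytest.approx(1.0, rel=1e-9)


def test_objective_history_monotone(small_fit):
    *_, result = small_fit
    hist = np.array(result.objective_history)
    assert np.all(np.diff(hist) <= 0)
    assert result.chi2 == pytest.approx(hist[-1])


def test_stderr_reported_positive(small_fit):
    *_, result = small_fit
    assert all(sd > 0 for sd in result.stderr.values())


def test_recovery_across_replicate_datasets():
    """Across seeded replicate datasets, median recovery error per free
    parameter stays below 10% and contour intervals cover the truth."""
    variant, truth = uk.variant_preset("wild_type_apo")
    conds = [uk.ExperimentCondition(enzyme_total=e, atp_total=a)
             for e, a in ((2.0, 1000.0), (2.0, 100.0))]
    spec = uk.FitSpec(free_params=("k3", "n_sites"), seed=0)
    errors = {"k3": [], "n_sites": []}
    covered = 0
    n_rep = 8
    for seed in range(n_rep):
        traces = uk.gen_pi_series(variant, truth, conds,
                                  uk.NoiseModel(seed=100 + seed),
                                  n_points=100)
        result = uk.global_fit(traces, variant, spec,
                               truth.with_updates(k3=2.0, n_sites=2.4))
        for name in errors:
            errors[name].append(
                abs(result.estimates[name] - getattr(truth, name))
                / getattr(truth, name)
            )
        cb = uk.confidence_contours(result, traces, variant, spec, truth,
                                    max_steps=6)
        if (cb["k3"].lower <= truth.k3 <= cb["k3"].upper
                and cb["n_sites"].lower <= truth.n_sites <= cb["n_sites"].upper):
            covered += 1
    assert np.median(errors["k3"]) < 0.10
    assert np.median(errors["n_sites"]) < 0.10
    assert covered >= 0.8 * n_rep


def test_contours_bracket_truth(small_fit):
    variant, truth, traces, spec, start, result = small_fit
    cb = uk.confidence_contours(result, traces, variant, spec, start,
                                max_steps=6)
    for name in ("k3", "k4", "n_sites"):
        assert cb[name].lower <= result.estimates[name] <= cb[name].upper
    # Pi-release step: interval brackets the generating 19 s^-1
    assert cb["k4"].lower <= truth.k4 <= cb["k4"].upper
    assert result.contour_bounds is cb


def test_kd2_unidentifiable_from_single_atp_series():
    """With only the enzyme series at one ATP concentration, KD2 enters the
    model solely through the product f2*k3, so its profile is flat: the
    contour must report an open upper bound (mirroring why the ATP titration
    is needed)."""
    variant, truth = uk.variant_preset("wild_type_apo")
    conds = [uk.ExperimentCondition(enzyme_total=e, atp_total=1000.0)
             for e in (0.125, 0.5, 2.0)]
    traces = uk.gen_pi_series(variant, truth, conds, uk.NoiseModel(seed=6),
                              n_points=100)
    spec = uk.FitSpec(free_params=("KD2", "k3"), seed=6)
    result = uk.global_fit(traces, variant, spec, truth)
    cb = uk.confidence_contours(result, traces, variant, spec, truth,
                                max_steps=5)
    assert cb["KD2"].open_upper


def test_uninfluential_parameter_has_open_bounds_both_sides():
    """k5a does not appear in the four-active-site network, so its profile
    is exactly flat."""
    variant, truth = uk.variant_preset("wild_type_apo")
    conds = [uk.ExperimentCondition(enzyme_total=e, atp_total=1000.0)
             for e in (0.5, 2.0)]
    traces = uk.gen_pi_series(variant, truth, conds, uk.NoiseModel(seed=7),
                              n_points=80)
    spec = uk.FitSpec(free_params=("k5a",), seed=7)
    result = uk.global_fit(traces, variant, spec, truth)
    cb = uk.confidence_contours(result, traces, variant, spec, truth,
                                max_steps=4)
    assert cb["k5a"].open_lower and cb["k5a"].open_upper


def test_contours_match_brute_force_grid_scan():
    """Profile-walk interval endpoints for (k4, n_sites) agree within 10%
    with a brute-force 2-D chi-square grid scan oracle.

    The n axis must be sampled far more finely than the k4 axis: n is so
    tightly constrained that coarse spacing would inflate the column minima
    and truncate the oracle's interval.
    """
    variant, truth = uk.variant_preset("wild_type_apo")
    conds = [uk.ExperimentCondition(enzyme_total=2.0, atp_total=1000.0),
             uk.ExperimentCondition(enzyme_total=0.5, atp_total=1000.0)]
    traces = uk.gen_pi_series(variant, truth, conds, uk.NoiseModel(seed=8),
                              n_points=60)
    spec = uk.FitSpec(free_params=("k4", "n_sites"), seed=8)
    result = uk.global_fit(traces, variant, spec, truth)
    cb = uk.confidence_contours(result, traces, variant, spec, truth,
                                step_factor=1.15, max_steps=12)

    from uvrkin.globalfit import _residuals_builder

    resid = _residuals_builder(traces, variant, truth, ("k4", "n_sites"), {})
    k4_hat, n_hat = result.estimates["k4"], result.estimates["n_sites"]
    # the k4 range must extend past the (shallow) upper crossing, and the n
    # axis must be sampled finely enough to track the re-optimized minimum
    k4_grid = np.geomspace(k4_hat / 4.0, k4_hat * 8.0, 41)
    n_grid = np.linspace(n_hat * 0.92, n_hat * 1.08, 81)
    chi = np.empty((k4_grid.size, n_grid.size))
    for i, k4 in enumerate(k4_grid):
        for j, n in enumerate(n_grid):
            r = resid(np.log([k4, n]))
            chi[i, j] = r @ r
    def refined_min(values):
        """Column minimum with parabolic refinement (removes the grid's
        discretization bias, which matters on shallow profile tails)."""
        j = int(np.argmin(values))
        if j in (0, values.size - 1):
            return float(values[j])
        y0, y1, y2 = values[j - 1], values[j], values[j + 1]
        denom = y0 - 2 * y1 + y2
        if denom <= 0:
            return float(y1)
        return float(y1 - (y0 - y2) ** 2 / (8 * denom))

    prof_k4 = np.array([refined_min(chi[i]) for i in range(k4_grid.size)])
    prof_n = np.array([refined_min(chi[:, j]) for j in range(n_grid.size)])
    thr = spec.threshold_ratio * min(prof_k4.min(), prof_n.min(), result.chi2)

    def grid_interval(profile, grid):
        ok = np.nonzero(profile <= thr)[0]
        return grid[ok[0]], grid[ok[-1]]

    lo, hi = grid_interval(prof_k4, k4_grid)
    assert cb["k4"].lower == pytest.approx(lo, rel=0.10)
    assert cb["k4"].upper == pytest.approx(hi, rel=0.10)
    lo, hi = grid_interval(prof_n, n_grid)
    assert cb["n_sites"].lower == pytest.approx(lo, rel=0.10)
    assert cb["n_sites"].upper == pytest.approx(hi, rel=0.10)


def test_contours_require_convergence(small_fit):
    variant, truth, traces, spec, start, result = small_fit
    broken = uk.FitResult(estimates=result.estimates, stderr=result.stderr,
                          chi2=result.chi2, dof=result.dof, converged=False,
                          params=result.params)
    with pytest.raises(ValueError, match="converged"):
        uk.confidence_contours(broken, traces, variant, spec, start)
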