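"""Rayleigh and dual-element regression: exactness, recovery, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dualcsia.core import (
    DeltaValue,
    ExperimentSeries,
    InsufficientDataError,
    InvalidInputError,
    IsotopeMeasurement,
)
from dualcsia.rayleigh import (
    DualElementModel,
    RayleighModel,
    compare_lambdas,
    dual_fit_from_summary,
    fit_lambda,
    fit_rayleigh,
)
from dualcsia.simulate import SimulationConfig, simulate_rayleigh_series

from conftest import F_GRID, ols_slope


def test_noiseless_rayleigh_is_exact(noiseless_series):
    """Exact distillation data recover the generating slope to 1e-9 permil."""
    res_c = fit_rayleigh(noiseless_series, "C")
    assert abs(res_c.epsilon - (-27.5)) < 1e-9
    assert abs(res_c.intercept) < 1e-12
    assert res_c.r_squared == pytest.approx(1.0, abs=1e-12)
    res_cl = fit_rayleigh(noiseless_series, "Cl")
    assert abs(res_cl.epsilon - (-5.3)) < 1e-9


def test_constant_delta_gives_zero_epsilon():
    vials = [
        IsotopeMeasurement(
            f"v{i}", "VC", "VC", f=f, delta_c=DeltaValue(4.2, "C")
        )
        for i, f in enumerate((0.9, 0.5, 0.2))
    ]
    series = ExperimentSeries("s", "VC", "VC", vials, delta0_c=4.2)
    res = fit_rayleigh(series, "C")
    assert res.epsilon == pytest.approx(0.0, abs=1e-12)


def test_rayleigh_matches_independent_ols_oracle(noisy_series):
    """Slope/intercept equal a hand-rolled closed-form OLS on the ln data."""
    res = fit_rayleigh(noisy_series, "C")
    pts = noisy_series.points("C")
    x = np.log([p[0] for p in pts])
    y = 1000.0 * np.log((1.0 + np.array([p[1] for p in pts]) / 1000.0) / (1.0 - 30.0 / 1000.0))
    assert res.epsilon == pytest.approx(ols_slope(x, y), abs=1e-9)
    # t-based CI width: 2 * t_{0.975, n-2} * stderr
    lo, hi = res.ci95
    tcrit = stats.t.ppf(0.975, res.n_points - 2)
    assert hi - lo == pytest.approx(2.0 * tcrit * res.stderr, rel=1e-9)
    assert lo < res.epsilon < hi


def test_ci_contains_truth_for_typical_seed(noisy_series):
    lo, hi = fit_rayleigh(noisy_series, "C").ci95
    assert lo < -27.5 < hi


def test_lambda_identity_when_elements_equal():
    vials = [
        IsotopeMeasurement(
            f"v{i}",
            "1,2-DCA",
            "1,2-DCA",
            f=f,
            delta_c=DeltaValue(d, "C"),
            delta_cl=DeltaValue(d, "Cl"),
        )
        for i, (f, d) in enumerate(((0.9, 1.0), (0.5, 6.0), (0.2, 15.0)))
    ]
    series = ExperimentSeries("s", "1,2-DCA", "1,2-DCA", vials, 0.0, 0.0)
    res = fit_lambda(series)
    assert res.lam == pytest.approx(1.0, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)


def test_lambda_noiseless_matches_brute_force(noiseless_series):
    """Lambda equals the closed-form OLS slope on the exact delta points.

    Mild curvature of delta-space distillation keeps the OLS slope a few
    percent above eps_C/eps_Cl = 5.19 for this design.
    """
    res = fit_lambda(noiseless_series)
    f = np.array(F_GRID)
    d_c = (f ** (-27.5 / 1000.0) - 1.0) * 1000.0
    d_cl = (f ** (-5.3 / 1000.0) - 1.0) * 1000.0
    expected = ols_slope(d_cl, d_c)
    assert res.lam == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(5.3252, abs=1e-3)


@pytest.mark.parametrize("eps_c", [-2.0, -10.0, -27.5, -35.0])
@pytest.mark.parametrize("eps_cl", [-0.4, -2.0, -5.3, -6.0])
def test_lambda_tracks_epsilon_ratio(eps_c, eps_cl):
    """Noiseless Lambda stays within 5% of eps_C/eps_Cl across the ranges."""
    cfg = SimulationConfig(
        epsilon_c=eps_c,
        epsilon_cl=eps_cl,
        delta0_c=0.0,
        delta0_cl=0.0,
        noise_sd=0.0,
        n_replicates=1,
    )
    series = simulate_rayleigh_series(cfg)
    res = fit_lambda(series)
    ratio = eps_c / eps_cl
    assert abs(res.lam - ratio) / abs(ratio) <= 0.05


@given(st.floats(min_value=-50.0, max_value=50.0))
@settings(max_examples=30, deadline=None)
def test_slope_invariant_under_delta_shift(shift):
    """Adding a constant to one element's deltas moves only the intercept."""
    cfg = SimulationConfig(epsilon_c=-27.5, epsilon_cl=-5.3, seed=7)
    series = simulate_rayleigh_series(cfg)
    base = fit_lambda(series)
    shifted_vials = [
        IsotopeMeasurement(
            m.vial_id,
            m.compound,
            m.cultivation_acceptor,
            m.f,
            delta_c=DeltaValue(m.delta_c.value + shift, "C"),
            delta_cl=m.delta_cl,
            replicate=m.replicate,
        )
        for m in series.measurements
    ]
    shifted = ExperimentSeries(
        "s", series.compound, series.cultivation_acceptor, shifted_vials,
        series.delta0_c, series.delta0_cl,
    )
    res = fit_lambda(shifted)
    assert res.lam == pytest.approx(base.lam, abs=1e-9)
    assert res.intercept == pytest.approx(base.intercept + shift, abs=1e-9)


def test_epsilon_recovery_and_ci_coverage():
    """Mean fitted epsilon within 2% of truth; CI coverage near nominal.

    Moderate ensemble here; the full-size recovery study lives in the
    acceptance suite.
    """
    eps_true = -27.5
    fits, covered = [], 0
    n_rep = 200
    for seed in range(n_rep):
        cfg = SimulationConfig(epsilon_c=eps_true, seed=seed)
        series = simulate_rayleigh_series(cfg)
        res = fit_rayleigh(series, "C")
        fits.append(res.epsilon)
        lo, hi = res.ci95
        covered += lo <= eps_true <= hi
    assert abs(np.mean(fits) - eps_true) / abs(eps_true) <= 0.02
    assert 0.90 <= covered / n_rep <= 0.99


def test_insufficient_and_degenerate_designs():
    cfg = SimulationConfig(
        epsilon_c=-27.5, f_grid=(0.5, 0.4), noise_sd=0.0, n_replicates=1
    )
    series = simulate_rayleigh_series(cfg)
    with pytest.raises(InsufficientDataError):
        fit_rayleigh(series, "C")
    with pytest.raises(InsufficientDataError):
        fit_lambda(series)  # only two paired points
    flat = SimulationConfig(
        epsilon_c=-27.5, f_grid=(0.5, 0.5, 0.5), noise_sd=0.0, n_replicates=1
    )
    with pytest.raises(InvalidInputError):
        fit_rayleigh(simulate_rayleigh_series(flat), "C")


def test_missing_delta0_raises():
    vials = [
        IsotopeMeasurement(
            f"v{i}", "VC", "VC", f=f, delta_c=DeltaValue(float(i), "C")
        )
        for i, f in enumerate((0.9, 0.5, 0.2))
    ]
    series = ExperimentSeries("s", "VC", "VC", vials)
    with pytest.raises(InsufficientDataError):
        fit_rayleigh(series, "C")


def test_compare_identical_lambdas_indistinguishable(noisy_series):
    fit = fit_lambda(noisy_series)
    cmp = compare_lambdas(fit, fit)
    assert cmp.verdict == "indistinguishable"
    assert cmp.p_value == pytest.approx(1.0)
    assert cmp.ci_overlap


def test_compare_published_patterns_distinct():
    """Low-Lambda vs high-Lambda published slopes separate cleanly."""
    n = 27  # nine vials, triplicate
    pce = dual_fit_from_summary(3.5, 0.8, n)
    cdce = dual_fit_from_summary(12.2, 2.5, n)
    cmp = compare_lambdas(pce, cdce)
    assert cmp.verdict == "distinct"
    assert cmp.p_value < 0.05
    assert not cmp.ci_overlap


def test_compare_overlapping_lambdas_indistinguishable():
    a = dual_fit_from_summary(5.0, 4.0, 27)
    b = dual_fit_from_summary(6.0, 4.0, 27)
    cmp = compare_lambdas(a, b)
    assert cmp.verdict == "indistinguishable"
    assert cmp.ci_overlap


def test_summaries_mention_key_quantities(noisy_series):
    s = RayleighModel(noisy_series, "C").fit().summary()
    assert "epsilon" in s and "permil" in s and "95% CI" in s
    s2 = DualElementModel(noisy_series).fit().summary()
    assert "Lambda" in s2
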