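"""Synthetic assay generator and isotopologue-resolved oracle."""

import numpy as np
import pytest

from dualcsia.core import InvalidInputError
from dualcsia.rayleigh import fit_rayleigh
from dualcsia.simulate import (
    DEFAULT_F_GRID,
    IsotopologueSystem,
    NotDeterminedError,
    STUDY_EPSILONS,
    SimulationConfig,
    make_study_fixture,
    rayleigh_delta,
    simulate_isotopologues,
    simulate_isotopologues_stochastic,
    simulate_rayleigh_series,
)


def test_closed_form_rayleigh_values():
    assert rayleigh_delta(0.5, -27.5, 0.0) == pytest.approx(19.2444, abs=1e-3)
    assert rayleigh_delta(0.3, 0.0, -30.0) == pytest.approx(-30.0, abs=1e-12)
    # composition at f = 1 equals the starting composition, any epsilon
    assert rayleigh_delta(1.0, -27.5, -30.0) == pytest.approx(-30.0, abs=1e-12)


def test_default_design_is_nine_vials_triplicate():
    cfg = SimulationConfig(epsilon_c=-27.5, epsilon_cl=-5.3)
    series = simulate_rayleigh_series(cfg)
    assert len(series.measurements) == 27
    assert sorted({m.f for m in series.measurements}) == sorted(DEFAULT_F_GRID)
    assert {m.replicate for m in series.measurements} == {1, 2, 3}
    assert all(m.sd_c == 0.5 and m.sd_cl == 0.5 for m in series.measurements)


def test_same_seed_bit_identical():
    cfg = SimulationConfig(epsilon_c=-27.5, epsilon_cl=-5.3, seed=11)
    a = simulate_rayleigh_series(cfg)
    b = simulate_rayleigh_series(cfg)
    for ma, mb in zip(a.measurements, b.measurements):
        assert ma.delta_c.value == mb.delta_c.value
        assert ma.delta_cl.value == mb.delta_cl.value


def test_different_seeds_differ():
    a = simulate_rayleigh_series(SimulationConfig(epsilon_c=-27.5, seed=1))
    b = simulate_rayleigh_series(SimulationConfig(epsilon_c=-27.5, seed=2))
    assert any(
        ma.delta_c.value != mb.delta_c.value
        for ma, mb in zip(a.measurements, b.measurements)
    )


def test_config_validation():
    with pytest.raises(InvalidInputError):
        SimulationConfig(epsilon_c=-27.5, f_grid=(0.5, 1.2))
    with pytest.raises(InvalidInputError):
        SimulationConfig(epsilon_c=-27.5, noise_sd=-0.1)
    with pytest.raises(InvalidInputError):
        SimulationConfig(epsilon_c=-27.5, n_replicates=0)


def test_noise_scaling_of_slope_stderr():
    """Fitted-slope stderr tracks noise_sd / sqrt(n * Var(ln f))."""
    stderrs = {}
    for noise in (0.25, 1.0):
        ses = []
        for seed in range(40):
            cfg = SimulationConfig(epsilon_c=-27.5, noise_sd=noise, seed=seed)
            ses.append(fit_rayleigh(simulate_rayleigh_series(cfg), "C").stderr)
        stderrs[noise] = np.mean(ses)
    x = np.log(np.repeat(DEFAULT_F_GRID, 3))
    for noise, se in stderrs.items():
        predicted = noise / np.sqrt(x.size * x.var())
        assert se / predicted < 1.2 and predicted / se < 1.2


def test_study_fixture_generating_truth_recovered():
    series = make_study_fixture("1,2-DCA", "1,2-DCA", seed=3, noise_sd=0.0)
    assert fit_rayleigh(series, "C").epsilon == pytest.approx(-27.5, abs=1e-9)
    assert fit_rayleigh(series, "Cl").epsilon == pytest.approx(-5.3, abs=1e-9)
    series = make_study_fixture("cDCE", "VC", seed=3, noise_sd=0.0)
    assert fit_rayleigh(series, "C").epsilon == pytest.approx(-14.7, abs=1e-9)
    assert fit_rayleigh(series, "Cl").epsilon == pytest.approx(-1.0, abs=1e-9)


def test_study_fixture_not_determined_rows():
    for compound, acceptor in (("1,2-DCA", "PCE"), ("1,2-DCA", "VC")):
        with pytest.raises(NotDeterminedError):
            make_study_fixture(compound, acceptor)
    with pytest.raises(InvalidInputError):
        make_study_fixture("TCE", "PCE")


def test_study_registry_has_fourteen_populated_rows():
    populated = [k for k, v in STUDY_EPSILONS.items() if v is not None]
    assert len(populated) == 14
    assert sum(v is None for v in STUDY_EPSILONS.values()) == 2


# --- isotopologue oracle -----------------------------------------------------


def _single_position_system(kie, n_positions=1, element="Cl"):
    return IsotopologueSystem(
        element=element,
        n_positions=n_positions,
        reactive_positions=(0,),
        kie_per_position=(kie,) + (1.0,) * (n_positions - 1),
    )


def test_unit_kie_gives_flat_delta():
    system = _single_position_system(1.0, n_positions=2)
    traj = simulate_isotopologues(system, 0.1)
    assert np.allclose(traj.delta_permil, 0.0, atol=1e-9)


@pytest.mark.parametrize("kie", [1.005, 1.013, 1.03])
def test_single_position_oracle_matches_algebra(kie):
    """Trajectory epsilon equals 1000*(1/KIE - 1) for one reactive position."""
    system = _single_position_system(kie)
    traj = simulate_isotopologues(system, 0.1)
    expected = 1000.0 * (1.0 / kie - 1.0)
    assert traj.fitted_epsilon() == pytest.approx(expected, abs=0.1)


def test_nonreacting_position_dilutes_by_x_over_n():
    """Two-carbon molecule, one reactive position: bulk epsilon = 500*(1/K-1)."""
    kie = 1.02
    system = _single_position_system(kie, n_positions=2, element="C")
    traj = simulate_isotopologues(system, 0.1)
    expected = 500.0 * (1.0 / kie - 1.0)
    assert traj.fitted_epsilon() == pytest.approx(expected, abs=0.1)


def test_vc_chlorine_streitwieser_scale():
    """A position KIE at the chlorine limit maps to eps_Cl ~ -12.8 permil."""
    traj = simulate_isotopologues(_single_position_system(1.013), 0.1)
    assert traj.fitted_epsilon() == pytest.approx(-12.833, abs=0.1)


def test_oracle_trajectory_is_linear_in_log_space():
    system = _single_position_system(1.03)
    traj = simulate_isotopologues(system, 0.1, n_points=40)
    y = np.log(1.0 + traj.delta_permil / 1000.0)
    x = np.log(traj.f)
    slope, intercept = np.polyfit(x, y, 1)
    residual = y - (slope * x + intercept)
    assert np.abs(residual).max() * 1000.0 <= 0.1  # permil


def test_mass_conservation_every_step():
    system = IsotopologueSystem(
        element="Cl",
        n_positions=2,
        reactive_positions=(0, 1),
        kie_per_position=(1.01, 1.01),
        heavy_abundance=0.24,
        max_heavy=2,
    )
    traj = simulate_isotopologues(system, 0.2)
    totals = traj.counts + traj.reacted
    assert np.allclose(totals, totals[0], atol=1e-12)


def test_dilute_label_insensitivity():
    """At natural 13C-level abundance (~1.1%) the bulk trajectory matches
    the a -> 0 limit to 0.01 permil; the residual dependence is O(a)
    (heavy classes perturb both the light-atom pool and f itself), so at
    5% abundance the deviation grows to a few hundredths of a permil."""
    deltas = {}
    for abundance in (0.0001, 0.011, 0.05):
        system = IsotopologueSystem(
            element="C",
            n_positions=1,
            reactive_positions=(0,),
            kie_per_position=(1.02,),
            heavy_abundance=abundance,
        )
        deltas[abundance] = simulate_isotopologues(system, 0.1).delta_permil
    assert np.allclose(deltas[0.011], deltas[0.0001], atol=0.01)
    assert np.allclose(deltas[0.05], deltas[0.0001], atol=0.06)


def test_concerted_channel_rule_product_of_kies():
    """Single concerted channel: both reactive bonds break in one step, so a
    heavy atom at either position slows the whole molecule by its KIE."""
    kie = 1.02
    system = IsotopologueSystem(
        element="Cl",
        n_positions=2,
        reactive_positions=(0, 1),
        kie_per_position=(kie, kie),
        channel_rule="single_concerted_channel",
        heavy_abundance=1e-4,  # dilute limit, where the mapping is exact
    )
    traj = simulate_isotopologues(system, 0.1)
    # each singly-heavy class reacts at k/KIE -> position epsilon 1/K-1,
    # both positions reactive: bulk epsilon = 1000*(1/K-1)
    assert traj.fitted_epsilon() == pytest.approx(1000.0 * (1.0 / kie - 1.0), abs=0.1)


def test_stochastic_mode_agrees_with_deterministic():
    """Strong-KIE, abundant-label regime where per-molecule sampling noise
    is small relative to the signal."""
    system = IsotopologueSystem(
        element="Cl",
        n_positions=1,
        reactive_positions=(0,),
        kie_per_position=(1.5,),
        heavy_abundance=0.24,
    )
    f_actual, delta = simulate_isotopologues_stochastic(
        system, 0.3, n_molecules=200_000, seed=5
    )
    traj = simulate_isotopologues(system, 0.3)
    assert f_actual == pytest.approx(0.3, abs=1e-3)
    assert delta == pytest.approx(traj.delta_permil[-1], abs=40.0)


def test_isotopologue_config_validation():
    with pytest.raises(InvalidInputError):
        IsotopologueSystem("C", 2, (0,), (0.0, 1.0))
    with pytest.raises(InvalidInputError):
        IsotopologueSystem("C", 2, (5,), (1.0, 1.0))
    system = _single_position_system(1.01)
    with pytest.raises(InvalidInputError):
        simulate_isotopologues(system, 1.5)
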