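"""Forward-model tests: builders, Bloch-McConnell propagation, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spinex.exchange as ex
from helpers import (
    brute_force_cpmg,
    carver_richards_exact,
    cest_ode,
    lumpable_asymmetric_dimer_3state,
)

N15_600 = 60.8  # 15N Larmor frequency (MHz) at a 600 MHz 1H spectrometer


# ---------------------------------------------------------------------------
# unit conversions and builders


@pytest.mark.parametrize("dppm, freq, expected", [
    (0.0, 60.8, 0.0),
    (1.0, 60.8, 381.97),
    (-7.3, 60.8, -2788.7),
])
def test_ppm_to_rad(dppm, freq, expected):
    assert ex.ppm_to_rad(dppm, freq) == pytest.approx(expected, abs=0.1)


def test_ppm_to_rad_rejects_bad_input():
    with pytest.raises(ValueError):
        ex.ppm_to_rad(np.nan, 60.8)
    with pytest.raises(ValueError):
        ex.ppm_to_rad(1.0, -5.0)


def test_build_two_state_rates():
    m = ex.build_two_state(0.03, 0.003, shifts=[0.0, -7.3])
    k_ge, k_eg = m.rate_matrix[1, 0], m.rate_matrix[0, 1]
    assert k_eg == pytest.approx(333.3, abs=0.1)
    assert k_ge == pytest.approx(10.31, abs=0.01)
    assert k_ge + k_eg == pytest.approx(343.6, abs=0.1)


def test_build_two_state_limits_and_errors():
    m0 = ex.build_two_state(0.0, 0.003, shifts=[0.0, 1.0])
    assert m0.rate_matrix[1, 0] == 0.0  # ground-only model
    with pytest.raises(ValueError):
        ex.build_two_state(0.6, 0.003, shifts=[0.0, 1.0])
    with pytest.raises(ValueError):
        ex.build_two_state(0.03, -1.0, shifts=[0.0, 1.0])


@given(p_e=st.floats(1e-4, 0.49), tau=st.floats(1e-4, 0.1))
@settings(deadline=None, max_examples=50)
def test_two_state_detailed_balance_by_construction(p_e, tau):
    m = ex.build_two_state(p_e, tau, shifts=[0.0, 1.0])
    k = m.rate_matrix
    assert m.populations[0] * k[1, 0] == pytest.approx(
        m.populations[1] * k[0, 1], rel=1e-9)


def test_build_three_state_edge_rate_sum():
    # for the on-pathway chain the N-I edge rates sum to k_AB,ex
    m = ex.build_three_state(1, p_h=0.02, p_i=0.01, k_ab_ex=1400.0,
                             k_bc_ex=500.0, shifts=[0.0, -1.0, -10.0])
    k = m.rate_matrix
    assert k[1, 0] + k[0, 1] == pytest.approx(1400.0, rel=1e-12)
    # detailed balance on both edges
    p = m.populations
    assert p[0] * k[1, 0] == pytest.approx(p[1] * k[0, 1], rel=1e-9)
    assert p[1] * k[2, 1] == pytest.approx(p[2] * k[1, 2], rel=1e-9)


def test_three_state_rejects_bad_populations():
    with pytest.raises(ValueError):
        ex.build_three_state(1, p_h=0.6, p_i=0.5, k_ab_ex=100.0,
                             k_bc_ex=100.0, shifts=[0, 0, 0])


def test_three_state_pi_zero_collapses_to_two_state(cpmg_ladder):
    # off-pathway scheme I-N-H with an empty intermediate is exactly the
    # two-state N<->H model
    nus, t = cpmg_ladder
    offs = np.arange(-11.0, 3.01, 0.5)
    m3 = ex.build_three_state(2, p_h=0.02, p_i=0.0, k_ab_ex=300.0,
                              k_bc_ex=900.0, shifts=[0.0, -1.0, -8.0],
                              r1=1.0, r2=(10.0, 11.0, 12.0))
    m2 = ex.build_two_state(0.02, 1.0 / (0.98 * 900.0), shifts=[0.0, -8.0],
                            r1=1.0, r2=(10.0, 12.0))
    e = ex.CESTExperiment(31.0, 0.35, offs, N15_600)
    d = np.max(np.abs(ex.simulate_cest(m3, e).intensity_ratio
                      - ex.simulate_cest(m2, e).intensity_ratio))
    assert d < 1e-8


def test_three_state_scheme_relabel_equivalence(cpmg_ladder):
    # chains N-I-H and N-H-I describe the same kinetics once the two minor
    # states swap labels: observable-state spectra must coincide
    nus, t = cpmg_ladder
    m1 = ex.build_three_state(1, p_h=0.02, p_i=0.01, k_ab_ex=300.0,
                              k_bc_ex=900.0, shifts=[0.0, -1.0, -8.0],
                              r1=1.0, r2=(10.0, 11.0, 12.0))
    m3 = ex.build_three_state(3, p_h=0.01, p_i=0.02, k_ab_ex=300.0,
                              k_bc_ex=900.0, shifts=[0.0, -8.0, -1.0],
                              r1=1.0, r2=(10.0, 12.0, 11.0))
    e = ex.CPMGExperiment(nus, t, N15_600)
    assert np.max(np.abs(ex.simulate_cpmg(m1, e).r2_eff
                         - ex.simulate_cpmg(m3, e).r2_eff)) < 1e-9


def test_reduce_asymmetric_dimer_populations():
    m = ex.reduce_asymmetric_dimer(k_md=13.4 / 1.27, k_dm=625.0,
                                   monomer_conc=1.27, omega_m=0.0,
                                   omega_d1=1.0)
    assert m.populations[1] == pytest.approx(0.021, abs=0.0005)
    k_ex = m.rate_matrix[1, 0] + m.rate_matrix[0, 1]
    assert k_ex == pytest.approx(638.4, rel=1e-6)
    m0 = ex.reduce_asymmetric_dimer(0.0, 625.0, 1.0, 0.0, 1.0)
    assert m0.populations[1] == 0.0


def test_reduced_dimer_matches_three_state_oracle(cpmg_ladder):
    nus, t = cpmg_ladder
    red = ex.reduce_asymmetric_dimer(k_md=13.4, k_dm=625.0, monomer_conc=1.0,
                                     omega_m=0.0, omega_d1=1.0, r2=10.0)
    sim = ex.simulate_cpmg(red, ex.CPMGExperiment(nus, t, N15_600)).r2_eff
    oracle = lumpable_asymmetric_dimer_3state(13.4, 625.0, 1.0, 10.0, nus, t,
                                              N15_600)
    assert np.max(np.abs(sim - oracle)) < 1e-6


# ---------------------------------------------------------------------------
# CEST simulation


def test_cest_far_off_resonance_r1_decay():
    m = ex.build_two_state(0.03, 0.003, shifts=[0.0, -7.3], r1=1.0, r2=10.0)
    e = ex.CESTExperiment(31.0, 0.35, np.array([20.0]), N15_600)
    assert ex.simulate_cest(m, e).intensity_ratio[0] == pytest.approx(
        np.exp(-1.0 * 0.35), abs=0.01)


def test_cest_no_exchange_single_dip():
    m = ex.build_two_state(0.0, 0.003, shifts=[0.0, -7.3], r1=0.0, r2=10.0)
    offs = np.arange(-12.0, 4.01, 0.25)
    y = ex.simulate_cest(m, ex.CESTExperiment(31.0, 0.35, offs, N15_600)
                         ).intensity_ratio
    far = np.abs(offs) > 6.0
    assert np.all(y[far] > 0.97)  # flat baseline away from resonance
    assert abs(offs[np.argmin(y)]) <= 0.5  # single dip at the ground shift


@pytest.mark.parametrize("k_ex, tol_ppm", [(30.0, 0.05), (344.0, 0.25)])
def test_cest_two_dip_geometry(k_ex, tol_ppm):
    """A sparsely populated state produces a second dip near ground + dw.

    The apparent dip is displaced toward the ground resonance by roughly
    k_EG^2/dw, negligible in slow exchange but ~0.1-0.2 ppm at
    k_ex ~ 344 s^-1; the tolerance reflects that physics.
    """
    m = ex.build_two_state(0.03, 1.0 / (0.97 * k_ex), shifts=[0.0, -7.3],
                           r1=1.0, r2=10.0)
    offs = np.arange(-12.0, 4.01, 0.1)
    y = ex.simulate_cest(m, ex.CESTExperiment(31.0, 0.35, offs, N15_600)
                         ).intensity_ratio
    minor_region = offs < -4.0
    minor_pos = offs[minor_region][np.argmin(y[minor_region])]
    assert minor_pos == pytest.approx(-7.3, abs=tol_ppm)
    assert y[minor_region].min() < 0.9  # a real dip, not baseline


def test_cest_matches_ode_oracle():
    offs = np.linspace(-8.6, -7.9, 8)
    m = ex.build_two_state(0.03, 1.0 / (0.97 * 344.0), shifts=[0.0, -8.3],
                           r1=1.0, r2=10.0)
    sim = ex.simulate_cest(m, ex.CESTExperiment(31.0, 0.35, offs, N15_600)
                           ).intensity_ratio
    ode = cest_ode(-8.3, 344.0, 0.03, offs, 31.0, N15_600, 1.0, 10.0, 0.35)
    assert np.max(np.abs(sim - ode)) < 1e-8


def test_cest_mirror_symmetry():
    offs = np.arange(-10.0, 10.01, 0.5)
    e = ex.CESTExperiment(31.0, 0.35, offs, N15_600)
    m_plus = ex.build_two_state(0.03, 0.005, shifts=[0.0, 6.0], r1=1.0, r2=10.0)
    m_minus = ex.build_two_state(0.03, 0.005, shifts=[0.0, -6.0], r1=1.0, r2=10.0)
    y_plus = ex.simulate_cest(m_plus, e).intensity_ratio
    y_minus = ex.simulate_cest(m_minus, e).intensity_ratio
    assert np.max(np.abs(y_plus - y_minus[::-1])) < 1e-9


def test_population_conservation_exchange_only():
    # the exchange generator alone preserves total magnetization over 1 s
    import scipy.linalg

    m = ex.build_three_state(1, 0.05, 0.02, 500.0, 1500.0,
                             shifts=[0.0, -1.0, -8.0], r1=0.0, r2=0.0)
    mt = scipy.linalg.expm(m.rate_matrix * 1.0) @ m.populations
    assert abs(mt.sum() - 1.0) < 1e-10
    # and the populations themselves are stationary
    assert np.max(np.abs(mt - m.populations)) < 1e-10


# ---------------------------------------------------------------------------
# CPMG simulation


def test_cpmg_no_exchange_flat(cpmg_ladder):
    nus, t = cpmg_ladder
    m = ex.build_two_state(0.0, 0.003, shifts=[0.0, -7.3], r2=[10.0, 12.0])
    r = ex.simulate_cpmg(m, ex.CPMGExperiment(nus, t, N15_600)).r2_eff
    assert np.max(np.abs(r - 10.0)) < 1e-9


@pytest.mark.parametrize("p_e, k_ex, dw_ppm", [
    (0.01, 100.0, 0.5), (0.01, 5000.0, 10.0),
    (0.03, 344.0, 7.3), (0.05, 1000.0, 2.0), (0.05, 5000.0, 0.5),
])
def test_cpmg_matches_exact_closed_form(cpmg_ladder, p_e, k_ex, dw_ppm):
    """Numerical propagation vs the exact two-site echo-train closed form."""
    nus, t = cpmg_ladder
    m = ex.build_two_state(p_e, 1.0 / ((1 - p_e) * k_ex),
                           shifts=[0.0, dw_ppm], r2=[10.0, 12.0])
    sim = ex.simulate_cpmg(m, ex.CPMGExperiment(nus, t, N15_600)).r2_eff
    oracle = carver_richards_exact(nus, t, p_e, k_ex,
                                   ex.ppm_to_rad(dw_ppm, N15_600), 10.0, 12.0)
    assert np.max(np.abs(sim - oracle)) <= 0.1


def test_cpmg_three_state_matches_brute_force(cpmg_ladder):
    nus, t = cpmg_ladder
    m = ex.build_three_state(1, 0.02, 0.01, 300.0, 900.0,
                             shifts=[0.0, -1.0, -8.0], r2=(10.0, 11.0, 12.0))
    sim = ex.simulate_cpmg(m, ex.CPMGExperiment(nus, t, N15_600)).r2_eff
    oracle = brute_force_cpmg(m.rate_matrix, m.populations, m.shifts, m.r2,
                              nus, t, N15_600)
    assert np.max(np.abs(sim - oracle)) < 1e-9


def test_cpmg_slow_exchange_endpoints_match_rex_formula(cpmg_ladder):
    # k_ex/dw = 344/2788 ~ 0.12: slow exchange, endpoints within 15% of the
    # closed-form exchange broadening
    nus, t = cpmg_ladder
    p_e, k_ex = 0.03, 344.0
    m = ex.build_two_state(p_e, 1.0 / ((1 - p_e) * k_ex),
                           shifts=[0.0, -7.3], r2=10.0)
    r = ex.simulate_cpmg(m, ex.CPMGExperiment(nus, t, N15_600)).r2_eff
    rex_sim = r[0] - r[-1]
    rex_cf = ex.rex_closed_form(p_e, k_ex, ex.ppm_to_rad(-7.3, N15_600))
    assert rex_sim == pytest.approx(rex_cf, rel=0.15)


# ---------------------------------------------------------------------------
# closed-form R_ex


def test_rex_closed_form_values():
    assert ex.rex_closed_form(0.02, 100.0, 2000.0) == pytest.approx(1.955, abs=0.005)
    assert ex.rex_closed_form(0.3, 500.0, 0.0) == 0.0


def test_rex_closed_form_slow_limit_field_independent():
    # k_ex << dw: R_ex -> p_G p_E k_ex regardless of the static field
    lo = ex.rex_closed_form(0.02, 50.0, ex.ppm_to_rad(8.0, 60.8))
    hi = ex.rex_closed_form(0.02, 50.0, ex.ppm_to_rad(8.0, 81.1))
    limit = 0.98 * 0.02 * 50.0
    assert lo == pytest.approx(limit, rel=0.01)
    assert hi == pytest.approx(limit, rel=0.01)
    assert lo == pytest.approx(hi, rel=0.01)


# ---------------------------------------------------------------------------
# type invariants


def test_experiment_validation():
    with pytest.raises(ValueError):
        ex.CESTExperiment(-1.0, 0.35, np.array([0.0, 1.0]), 60.8)
    with pytest.raises(ValueError):
        ex.CESTExperiment(31.0, 0.35, np.array([0.0, 2.0, 1.0]), 60.8)
    with pytest.raises(ValueError):  # non-integral cycle count
        ex.CPMGExperiment(np.array([50.0]), 0.03, 60.8)
    with pytest.raises(ValueError):
        ex.Condition(-1.0, 25.0, 600.0)
    with pytest.raises(ValueError):
        ex.Condition(1.0, 150.0, 600.0)


def test_model_validation_catches_broken_balance():
    k = np.array([[-10.0, 5.0], [10.0, -5.0]])  # inconsistent with 3%/97%
    with pytest.raises(ValueError, match="detailed balance"):
        ex.ExchangeModel(("G", "E"), np.array([0.97, 0.03]),
                         np.array([0.0, 1.0]), np.ones(2), np.ones(2) * 10,
                         k)
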