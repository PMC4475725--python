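"""Fitting tests: two-state fits, staged three-state protocol, dip utilities."""

import numpy as np
import pytest

import spinex.exchange as ex
import spinex.fitting as ft

N15_600 = 60.8
N15_800 = 81.06


def make_cpmg_profiles(p_e, tau_e, dws, sigma, rng, fields=(N15_600, N15_800),
                       r2_base=10.0, t=0.03, builder=None):
    nus = np.array([1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 20, 24, 30]) / t
    profs = []
    for fn in fields:
        e = ex.CPMGExperiment(nus, t, fn)
        for j, (rid, dw) in enumerate(dws.items()):
            if builder is None:
                m = ex.build_two_state(p_e, tau_e, shifts=[0.0, dw],
                                       r2=r2_base + j)
            else:
                m = builder(dw, r2_base + j)
            p = ex.simulate_cpmg(m, e, residue_id=rid)
            if sigma:
                p.r2_eff = p.r2_eff + rng.normal(0, sigma, len(nus))
            p.errors = np.full(len(nus), max(sigma, 1e-3))
            profs.append(p)
    return profs


# ---------------------------------------------------------------------------
# two-state fitting


def test_noiseless_two_state_recovery_exact():
    rng = np.random.default_rng(0)
    profs = make_cpmg_profiles(0.025, 0.004, {"A": 1.2, "B": 0.7}, 0.0, rng)
    fit = ft.fit_two_state(profs, init={"dw": 1.0})
    k_ex_true = 1.0 / ((1 - 0.025) * 0.004)
    assert fit.params["p_e"] == pytest.approx(0.025, rel=1e-4)
    assert fit.params["k_ex"] == pytest.approx(k_ex_true, rel=1e-4)
    assert abs(fit.params["dw[A]"]) == pytest.approx(1.2, rel=1e-4)


def test_process_iii_like_recovery_within_2_sigma():
    # ~3.3% populated state with a 6.0 ms lifetime at bench noise
    rng = np.random.default_rng(7)
    profs = make_cpmg_profiles(0.033, 0.006,
                               {f"R{i}": d for i, d in
                                enumerate(np.linspace(0.5, 1.5, 5))},
                               0.2, rng)
    fit = ft.fit_two_state(profs, init={"dw": 1.0})
    assert abs(fit.params["p_e"] - 0.033) <= 2 * max(fit.errors["p_e"], 1e-3)
    assert fit.chi2_red < 1.5


def test_incompatible_processes_joint_fit_fails_loudly():
    # one probe on a slow large-shift process, one on a fast small-shift
    # process: a single shared (p_e, k_ex) cannot fit both
    rng = np.random.default_rng(3)
    a = make_cpmg_profiles(0.03, 0.003, {"A": 8.0}, 0.02, rng)
    b = make_cpmg_profiles(0.021, 0.0016, {"B": 1.0}, 0.02, rng)
    fit = ft.fit_two_state(a + b, init={"dw": {"A": 8.0, "B": 1.0}})
    assert fit.chi2_red > 5.0


def test_covariance_errors_calibrate():
    """Empirical scatter of fitted p_e over noise replicates is within a
    factor 1.5 of the reported covariance sigma."""
    fitted, sigmas = [], []
    for i in range(200):
        rng = np.random.default_rng(1000 + i)
        profs = make_cpmg_profiles(0.03, 0.004, {"A": 1.5}, 0.2, rng)
        f = ft.TwoStateFitter(init={"dw": 1.5, "k_ex": 250.0},
                              n_starts=2).fit(profs)
        fitted.append(f.p_e_)
        sigmas.append(f.result_.errors["p_e"])
    emp = np.std(fitted)
    rep = np.median(sigmas)
    assert rep / 1.5 <= emp <= rep * 1.5


def test_parameter_recovery_ensemble():
    """>= 90% of two-state fits across realistic parameter draws recover
    (p_e, k_ex) within 3 sigma at bench noise."""
    rng = np.random.default_rng(42)
    ok = 0
    n = 100
    for i in range(n):
        p_e = rng.uniform(0.01, 0.05)
        tau = rng.uniform(0.001, 0.015)
        dw = rng.uniform(0.5, 10.0)
        k_ex = 1.0 / ((1 - p_e) * tau)
        profs = make_cpmg_profiles(p_e, tau, {"A": dw}, 0.2, rng)
        try:
            f = ft.TwoStateFitter(init={"dw": min(dw, 3.0)},
                                  n_starts=3).fit(profs)
        except RuntimeError:
            continue
        sig_p = max(f.result_.errors["p_e"], 1e-6)
        sig_k = max(f.result_.errors["k_ex"], 1e-3)
        if (abs(f.p_e_ - p_e) <= 3 * sig_p
                and abs(f.k_ex_ - k_ex) <= 3 * sig_k):
            ok += 1
    assert ok >= 0.9 * n


def test_chi2_red_near_unity_when_correctly_specified():
    rng = np.random.default_rng(5)
    profs = make_cpmg_profiles(0.03, 0.005,
                               {f"R{i}": d for i, d in
                                enumerate(np.linspace(0.8, 1.5, 5))},
                               0.2, rng)
    fit = ft.fit_two_state(profs, init={"dw": 1.0})
    assert fit.n_data - fit.n_params >= 100
    assert 0.7 <= fit.chi2_red <= 1.4


# ---------------------------------------------------------------------------
# grid search and refinement


def test_grid_presets_match_protocol():
    g1 = ft.GridSpec.preset("process_I")
    assert len(g1.k_ab_axis) == len(g1.k_bc_axis) == 11
    assert g1.k_ab_axis[0] == pytest.approx(10.0)
    assert g1.k_ab_axis[-1] == pytest.approx(2016.0)
    assert len(g1.p_h_axis) == 16
    assert g1.p_h_axis[0] == pytest.approx(0.005)
    assert g1.p_h_axis[-1] == pytest.approx(0.23)
    g2 = ft.GridSpec.preset("process_II")
    assert g2.shape == (10, 10, 16, 16)
    assert g2.p_h_axis[0] == pytest.approx(0.005)
    assert g2.p_h_axis[-1] == pytest.approx(0.14)
    assert g2.k_ab_axis[0] == pytest.approx(10.0)
    assert g2.k_ab_axis[-1] == pytest.approx(11529.0)
    with pytest.raises(ValueError):
        ft.GridSpec.preset("nope")


@pytest.fixture(scope="module")
def planted_grid_data():
    t = 0.03
    nus = np.array([1, 2, 4, 8, 15, 30]) / t
    grid = ft.GridSpec(p_h_axis=[0.01, 0.02], p_i_axis=[0.005, 0.01],
                       k_ab_axis=[100.0, 200.0], k_bc_axis=[500.0, 1000.0])
    dw_nh = {"T135": -10.0}
    profs = []
    for fn in (N15_600, N15_800):
        e = ex.CPMGExperiment(nus, t, fn)
        m = ex.build_three_state(1, 0.02, 0.01, 200.0, 1000.0,
                                 shifts=[0.0, -3.0, -10.0], r1=1.0,
                                 r2=(10.0, 11.0, 12.0))
        p = ex.simulate_cpmg(m, e, residue_id="T135")
        p.errors = np.full(len(nus), 0.05)
        profs.append(p)
    return profs, grid, dw_nh


def test_grid_search_finds_planted_node(planted_grid_data):
    profs, grid, dw_nh = planted_grid_data
    surf = ft.grid_search_three_state(profs, grid, dw_nh, schemes=(1,))[1]
    idx = np.unravel_index(np.argmin(surf.total), surf.total.shape)
    assert grid.p_h_axis[idx[0]] == 0.02
    assert grid.p_i_axis[idx[1]] == 0.01
    assert grid.k_ab_axis[idx[2]] == 200.0
    assert grid.k_bc_axis[idx[3]] == 1000.0
    # summed surface equals the sum of per-residue surfaces
    total = np.sum([surf.per_residue[r] for r in surf.per_residue], axis=0)
    assert np.array_equal(total, surf.total)


def test_refinement_recovers_planted_truth(planted_grid_data):
    profs, grid, dw_nh = planted_grid_data
    surf = ft.grid_search_three_state(profs, grid, dw_nh, schemes=(1,))[1]
    res = ft.refine_three_state(profs, surf.top_seeds(1), dw_nh, scheme=1)
    assert res.params["p_h"] == pytest.approx(0.02, rel=1e-3)
    assert res.params["p_i"] == pytest.approx(0.01, rel=1e-3)
    assert res.params["k_bc_ex"] == pytest.approx(1000.0, rel=1e-3)
    # tau_H = 1/k_off,H with k_off,H = k_BC,ex * p_I/(p_H + p_I)
    assert res.lifetimes["tau_h"] == pytest.approx(0.003, rel=1e-3)


def test_refinement_is_idempotent(planted_grid_data):
    profs, grid, dw_nh = planted_grid_data
    seeds = [{"p_h": 0.02, "p_i": 0.01, "k_ab_ex": 200.0, "k_bc_ex": 1000.0,
              "dw_ni": -3.0}]
    r1 = ft.refine_three_state(profs, seeds, dw_nh, scheme=1)
    r2 = ft.refine_three_state(profs, seeds, dw_nh, scheme=1)
    assert r1.params == r2.params
    assert r1.chi2_red == r2.chi2_red


def test_two_state_data_pins_grid_to_population_floor(cpmg_ladder):
    # data with no hidden intermediate, searched with the chain where the
    # hidden state dangles off the excited state: the surface minimum sits
    # at the smallest allowed p_I with the true (p_H, k_AB,ex), and the
    # superfluous hidden edge leaves the surface flat in k_BC,ex
    nus, t = cpmg_ladder
    e = ex.CPMGExperiment(nus, t, N15_600)
    m = ex.build_two_state(0.02, 0.002, shifts=[0.0, -8.0], r2=10.0)
    p = ex.simulate_cpmg(m, e, residue_id="X")
    p.errors = np.full(len(nus), 0.05)
    kex_true = 1.0 / ((1 - 0.02) * 0.002)
    grid = ft.GridSpec(p_h_axis=[0.01, 0.02, 0.04], p_i_axis=[0.005, 0.05],
                       k_ab_axis=[200.0, kex_true, 1000.0],
                       k_bc_axis=[100.0, 1000.0])
    surf = ft.grid_search_three_state([p], grid, {"X": -8.0}, schemes=(3,))[3]
    idx = np.unravel_index(np.argmin(surf.total), surf.total.shape)
    assert grid.p_i_axis[idx[1]] == 0.005
    assert grid.p_h_axis[idx[0]] == 0.02
    assert grid.k_ab_axis[idx[2]] == kex_true
    assert np.ptp(surf.total[idx[0], idx[1], idx[2], :]) < 0.15


def test_seed_ranking_tiebreak():
    grid = ft.GridSpec(p_h_axis=[0.01], p_i_axis=[0.01],
                       k_ab_axis=[10.0, 100.0], k_bc_axis=[10.0, 100.0])
    total = np.zeros(grid.shape)  # all ties
    surf = ft.Chi2Surface(grid=grid, scheme=1, per_residue={}, total=total)
    seeds = surf.top_seeds(4)
    assert seeds[0]["k_ab_ex"] == 10.0 and seeds[0]["k_bc_ex"] == 10.0
    assert seeds[1]["k_ab_ex"] == 10.0 and seeds[1]["k_bc_ex"] == 100.0


# ---------------------------------------------------------------------------
# lifetimes


def test_state_lifetime_from_fit_params():
    params = {"p_h": 0.02, "p_i": 0.01, "k_ab_ex": 500.0, "k_bc_ex": 1000.0}
    res = ft.FitResult(params=params, errors={}, chi2_red=1.0, n_data=10,
                       n_params=4, model_kind="three_state", scheme=1)
    # k_off,H = 1000 * 0.01/0.03 = 333.3 -> tau_H = 3.0 ms
    assert ft.state_lifetime(res, "H") == pytest.approx(0.003, rel=1e-9)


def test_state_lifetime_from_model_and_scaling():
    m = ex.build_two_state(0.03, 1.0 / 76.9, shifts=[0.0, 1.0])
    assert ft.state_lifetime(m, "E") == pytest.approx(0.013, rel=1e-3)
    # doubling every rate halves every lifetime
    m2 = ex.build_two_state(0.03, 0.5 / 76.9, shifts=[0.0, 1.0])
    for s in ("G", "E"):
        assert ft.state_lifetime(m2, s) == pytest.approx(
            ft.state_lifetime(m, s) / 2, rel=1e-12)
    with pytest.raises(ValueError):
        ft.state_lifetime(ex.build_two_state(0.0, 1.0, shifts=[0.0, 0.0]), "G")


# ---------------------------------------------------------------------------
# dip utilities


def cest_profile(p_e, k_ex, dw, b1, noise=0.0, seed=0, step=0.4, r2=10.0):
    offs = np.arange(min(dw, 0) - 3.5, max(dw, 0) + 3.51, step)
    m = ex.build_two_state(p_e, 1.0 / ((1 - p_e) * k_ex), shifts=[0.0, dw],
                           r1=1.0, r2=r2)
    p = ex.simulate_cest(m, ex.CESTExperiment(b1, 0.35, offs, N15_600))
    if noise:
        rng = np.random.default_rng(seed)
        p.intensity_ratio = p.intensity_ratio + rng.normal(0, noise, len(offs))
        p.errors = np.full(len(offs), noise)
    return p


def test_dip_extraction_slow_exchange_accuracy():
    # slow exchange: apparent dips sit at the state shifts and the recovered
    # separation reproduces the planted 8.3 ppm
    p = cest_profile(0.03, 30.0, -8.3, b1=15.0)
    dips = ft.extract_dips(p, 2)
    assert abs(dips.minor_shift) == pytest.approx(8.3, abs=0.05)
    assert dips.major == pytest.approx(0.0, abs=0.02)


def test_dip_extraction_with_noise():
    p = cest_profile(0.03, 30.0, -8.3, b1=15.0, noise=0.005, seed=3)
    dips = ft.extract_dips(p, 2)
    assert abs(dips.minor_shift) == pytest.approx(8.3, abs=0.1)


def test_dip_extraction_faster_exchange_displacement():
    # at k_ex = 344 s^-1 the minor dip is physically displaced toward the
    # ground resonance by ~0.2 ppm; the extractor reports what is in the data
    p = cest_profile(0.03, 344.0, -8.3, b1=31.0)
    dips = ft.extract_dips(p, 2)
    assert abs(dips.minor_shift) == pytest.approx(8.1, abs=0.1)


def test_dip_extraction_single_dip_merges():
    p = cest_profile(0.0, 100.0, -8.3, b1=31.0, r2=25.0)
    dips = ft.extract_dips(p, 2)
    if dips.merged:
        assert len(dips.positions) == 1
    else:
        # any surviving second component is a vanishing lineshape artifact
        assert dips.amplitudes[1] < 0.05 * dips.amplitudes[0]
    assert dips.positions[0] == pytest.approx(0.0, abs=0.05)


def test_estimate_cest_noise():
    offs = np.linspace(-10, 10, 41)
    e = ex.CESTExperiment(31.0, 0.35, offs, N15_600)
    flat = ex.CESTProfile("x", "15N", np.full(41, 0.8), np.zeros(41), e)
    assert ft.estimate_cest_noise(flat, np.ones(41, bool)) < 1e-10
    rng = np.random.default_rng(2)
    noisy = ex.CESTProfile("x", "15N",
                           0.8 + rng.normal(0, 0.01, 41), np.zeros(41), e)
    mask = np.zeros(41, bool)
    mask[:30] = True
    est = ft.estimate_cest_noise(noisy, mask)
    assert 0.007 <= est <= 0.013
    # invariant to an additive baseline offset (linear trend removed)
    shifted = ex.CESTProfile("x", "15N", noisy.intensity_ratio + 0.1,
                             np.zeros(41), e)
    assert ft.estimate_cest_noise(shifted, mask) == pytest.approx(est, rel=1e-9)
    with pytest.raises(ValueError):
        ft.estimate_cest_noise(flat, np.zeros(41, bool))


def test_duplicate_errors():
    # identical duplicates: pooled sigma collapses to the floor
    assert ft.duplicate_errors([[5.0, 5.0], [3.0, 3.0]], floor=0.01) == 0.01
    # planted sigma recovered within sampling bounds
    rng = np.random.default_rng(9)
    groups = [rng.normal(10.0, 0.05, 2) for _ in range(40)]
    est = ft.duplicate_errors(groups)
    assert 0.035 <= est <= 0.065
    # propagation to R_2,eff: sigma_R = sigma_I / (I T)
    i = np.array([0.5, 1.0])
    out = ft.duplicate_errors([[1.0, 1.1]], intensities=i, t_cpmg=0.03)
    sig_i = ft.duplicate_errors([[1.0, 1.1]])
    assert np.allclose(out, sig_i / (i * 0.03))
    with pytest.raises(ValueError):
        ft.duplicate_errors([[1.0]])


def test_single_duplicate_group_warns():
    with pytest.warns(UserWarning):
        ft.duplicate_errors([[1.0, 1.2]])
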