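"""Power analytics vs exact-density and Monte Carlo oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, special, stats

from nutripair import (
    DataError,
    DegenerateDataError,
    PowerSimConfig,
    empirical_power_joint,
    inflation_table,
    power_corr_analytic,
    power_curves,
    power_loss_at_target,
    sample_size_inflation,
    simulate_outcome,
)
from nutripair.power import _critical_r


def exact_corr_density(r: float, rho: float, n: int) -> float:
    """Density of the sample correlation under bivariate normality
    (Hotelling's hypergeometric form); independent oracle for power."""
    c = (
        (n - 2)
        * special.gamma(n - 1)
        * (1 - rho**2) ** ((n - 1) / 2)
        / (np.sqrt(2 * np.pi) * special.gamma(n - 0.5))
    )
    return (
        c
        * (1 - r**2) ** ((n - 4) / 2)
        * (1 - rho * r) ** ((3 - 2 * n) / 2)
        * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)
    )


def exact_power(rho: float, n: int, alpha: float = 0.05) -> float:
    rc = _critical_r(n, alpha)
    upper, _ = integrate.quad(exact_corr_density, rc, 1, args=(rho, n), limit=200)
    lower, _ = integrate.quad(exact_corr_density, -1, -rc, args=(rho, n), limit=200)
    return upper + lower


def make_correlated_pair(n: int, r: float, seed: int = 0):
    """Vectors whose sample correlation is exactly r (orthogonalized)."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = rng.standard_normal(n)
    z2 -= z1 * (z1 @ z2) / (z1 @ z1)
    z2 = (z2 - z2.mean()) / z2.std()
    return z1, r * z1 + np.sqrt(1 - r * r) * z2


def test_power_at_null_equals_test_size():
    assert power_corr_analytic(0.0, 50) == pytest.approx(0.05)
    assert power_corr_analytic(0.0, 500, alpha=0.01) == pytest.approx(0.01)


def test_power_tends_to_one_at_strong_correlation():
    assert power_corr_analytic(0.999, 50) > 0.9999
    assert power_corr_analytic(0.387, 5000) > 0.9999


def test_rho_out_of_domain_raises():
    with pytest.raises(ValueError):
        power_corr_analytic(1.0, 50)


def test_fisher_z_power_close_to_exact_density_integral():
    """The Fisher-z approximation tracks numerical integration of the exact
    sample-correlation density to within 0.02 at n = 50."""
    total, _ = integrate.quad(exact_corr_density, -1, 1, args=(0.387, 50), limit=200)
    assert total == pytest.approx(1.0, abs=1e-9)
    for rho in (0.1, 0.25, 0.387):
        assert power_corr_analytic(rho, 50) == pytest.approx(exact_power(rho, 50), abs=0.02)


def test_simulate_outcome_null_and_target_correlation():
    rng = np.random.default_rng(11)
    n = 400
    x = rng.normal(50.0, 8.0, n)
    null_corrs = [
        abs(stats.pearsonr(x, simulate_outcome(x, 0.0, rng)).statistic) for _ in range(200)
    ]
    assert np.mean(null_corrs) < 3 / np.sqrt(n)

    reps, rho = 200, 0.5
    corrs = [
        stats.pearsonr(x, simulate_outcome(x, rho, rng)).statistic for _ in range(reps)
    ]
    se = (1 - rho**2) / np.sqrt(n)  # delta-method SE of a sample correlation
    assert abs(np.mean(corrs) - rho) < 3 * se / np.sqrt(reps)


def test_simulate_outcome_is_seed_deterministic():
    x = np.arange(10.0)
    a = simulate_outcome(x, 0.3, np.random.default_rng(5))
    b = simulate_outcome(x, 0.3, np.random.default_rng(5))
    np.testing.assert_array_equal(a, b)
    with pytest.raises(DegenerateDataError):
        simulate_outcome(np.full(10, 3.0), 0.3, np.random.default_rng(5))


def test_identical_measures_have_identical_power():
    x = np.random.default_rng(8).normal(0.0, 1.0, 60)
    curve = power_curves(x, x.copy(), PowerSimConfig(reps=200, seed=3))
    np.testing.assert_array_equal(curve.power_n, curve.power_m)
    assert curve.r_nm == pytest.approx(1.0)


def test_empirical_power_tracks_analytic_on_grid_subset():
    """Spot check of the Monte Carlo rejection fractions against the
    Fisher-z curve at generous (3 SE + approximation slack) tolerance."""
    n, r = 80, 0.9
    nv, mv = make_correlated_pair(n, r, seed=12)
    cfg = PowerSimConfig(
        rho_grid=np.array([0.1, 0.2, 0.3, 0.4, 0.5]), reps=1500, seed=9
    )
    curve = power_curves(nv, mv, cfg)
    for i, rho in enumerate(cfg.rho_grid):
        pn = power_corr_analytic(rho, n)
        pm = power_corr_analytic(rho * r, n)
        tol = 3 * np.sqrt(max(pn * (1 - pn), 1e-4) / cfg.reps) + 0.01
        assert curve.power_n[i] == pytest.approx(pn, abs=tol)
        assert curve.power_m[i] == pytest.approx(pm, abs=tol)


def test_power_m_never_exceeds_power_n_analytically():
    for r in (0.5, 0.8, 0.96):
        curve = power_curves(config=PowerSimConfig(mode="analytic"), r_nm=r, n=50)
        assert np.all(curve.power_m <= curve.power_n + 1e-12)


def test_power_loss_zero_for_perfect_agreement():
    curve = power_curves(config=PowerSimConfig(mode="analytic"), r_nm=1.0, n=50)
    assert power_loss_at_target(curve) == pytest.approx(0.0, abs=1e-12)


def test_power_loss_matches_root_finding_oracle():
    """Interpolated grid loss equals the closed-form loss at the brentq
    solution of power(rho*, n) = target."""
    from scipy.optimize import brentq

    r, n, target = 0.96, 50, 0.80
    curve = power_curves(config=PowerSimConfig(mode="analytic"), r_nm=r, n=n)
    loss = power_loss_at_target(curve, target)
    rho_star = brentq(lambda q: power_corr_analytic(q, n) - target, 1e-9, 0.999)
    expected = 100.0 * (target - power_corr_analytic(rho_star * r, n))
    assert loss == pytest.approx(expected, abs=0.05)


def test_power_loss_monotone_in_agreement():
    losses = []
    for r in (0.5, 0.8, 0.9, 0.96):
        curve = power_curves(config=PowerSimConfig(mode="analytic"), r_nm=r, n=50)
        losses.append(power_loss_at_target(curve))
    assert losses == sorted(losses, reverse=True)


def test_unreachable_target_power_names_maximum():
    curve = power_curves(config=PowerSimConfig(mode="analytic"), r_nm=0.9, n=10)
    with pytest.raises(DataError, match="maximum attained"):
        power_loss_at_target(curve, 0.99)


def test_inflation_zero_at_perfect_agreement():
    for n in (50, 100, 500):
        assert sample_size_inflation(1.0, n) == 0.0


def test_inflation_matches_exhaustive_search_with_exact_density():
    """n' from the analytic scan agrees with an exhaustive integer search
    driven by the exact-density power, to within one sample."""
    from scipy.optimize import brentq

    r, n, target = 0.96, 50, 0.80
    got = sample_size_inflation(r, n, target)
    rho_star = brentq(lambda q: power_corr_analytic(q, n) - target, 1e-9, 0.999)
    n_prime = n
    while exact_power(rho_star * r, n_prime) < target:
        n_prime += 1
    expected = 100.0 * (n_prime - n) / n
    assert abs(got - expected) <= 100.0 / n + 1e-9


def test_empirical_inflation_agrees_with_analytic():
    got = sample_size_inflation(0.9, 50, mode="empirical", reps=4000, seed=2)
    analytic = sample_size_inflation(0.9, 50)
    assert got == pytest.approx(analytic, abs=8.0)  # +-4 samples at n=50


def test_joint_simulator_is_unbiased_for_exact_power():
    rng = np.random.default_rng(17)
    p_hat = empirical_power_joint(0.387, 1.0, 50, 4000, 0.05, rng)
    p_exact = exact_power(0.387, 50)
    assert abs(p_hat - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 4000)


def test_inflation_table_shape_and_values():
    table = inflation_table({"energy": 0.96, "sodium": 0.53}, n_list=(50, 500))
    assert list(table["n"]) == [50, 500]
    assert table.loc[0, "energy"] == pytest.approx(sample_size_inflation(0.96, 50))
    assert (table["sodium"] > table["energy"]).all()
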