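"""Statistical layer: F-test, gating, noise decomposition, plate correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from utr3end import io, simulate, stats


# ---------------------------------------------------------------------------
# Nested regression F-test
# ---------------------------------------------------------------------------


def _brute_force_fit(y, X):
    """Independent least squares via explicit normal equations."""
    A = np.column_stack([np.ones(len(y)), X]) if X is not None and X.size else \
        np.ones((len(y), 1))
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    return float(resid @ resid), A.shape[1]


def _brute_force_ftest(y, Xr, Xf):
    from scipy import stats as sps

    rss_r, df_r = _brute_force_fit(y, Xr)
    rss_f, df_f = _brute_force_fit(y, Xf)
    delta = df_f - df_r
    F = ((rss_r - rss_f) / delta) / (rss_f / (len(y) - df_f))
    return F, float(sps.f.sf(F, delta, len(y) - df_f))


def test_perfect_full_fit_has_tiny_p():
    rng = np.random.default_rng(0)
    x1, x2 = rng.normal(size=50), rng.normal(size=50)
    y = x1 + x2
    fit = stats.nested_regression_ftest(y, x1, np.column_stack([x1, x2]))
    assert fit.p < 1e-10
    assert fit.rss_full <= 1e-18


def test_hand_example_matches_brute_force_oracle():
    x1 = np.array([1.0, 2, 3, 4, 5])
    x2 = np.array([0.0, 0, 0, 0, 1])
    # y = x1 + x2 exactly: the full model is a perfect fit, so both routes
    # must agree the improvement is overwhelming.
    y = np.array([1.0, 2, 3, 4, 6])
    fit = stats.nested_regression_ftest(y, x1, np.column_stack([x1, x2]))
    assert fit.p < 1e-12 and fit.rss_full < 1e-18
    # a perturbed response keeps the fit imperfect: F and p must match the
    # normal-equations oracle to high precision.
    y2 = np.array([1.0, 2.2, 2.9, 4.1, 6.3])
    fit2 = stats.nested_regression_ftest(y2, x1, np.column_stack([x1, x2]))
    F, p = _brute_force_ftest(y2, x1, np.column_stack([x1, x2]))
    assert fit2.F == pytest.approx(F, rel=1e-10)
    assert fit2.p == pytest.approx(p, rel=1e-10)


def test_random_instances_match_brute_force_and_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    for _ in range(100):
        n = int(rng.integers(10, 40))
        Xf = rng.normal(size=(n, 3))
        Xr = Xf[:, :2]
        y = Xf @ rng.normal(size=3) + rng.normal(size=n)
        fit = stats.nested_regression_ftest(y, Xr, Xf)
        F, p = _brute_force_ftest(y, Xr, Xf)
        assert fit.F == pytest.approx(F, rel=1e-8)
        assert fit.p == pytest.approx(p, rel=1e-8)
    # one independent cross-check against statsmodels' nested-model F-test
    full = sm.OLS(y, sm.add_constant(Xf)).fit()
    red = sm.OLS(y, sm.add_constant(Xr)).fit()
    F_sm, p_sm, _ = full.compare_f_test(red)
    assert fit.F == pytest.approx(F_sm, rel=1e-8)
    assert fit.p == pytest.approx(p_sm, rel=1e-8)


def test_invariants_of_fit_result():
    rng = np.random.default_rng(2)
    Xf = rng.normal(size=(30, 2))
    y = rng.normal(size=30)
    fit = stats.nested_regression_ftest(y, Xf[:, :1], Xf)
    assert fit.rss_full <= fit.rss_reduced
    assert fit.r2_full >= fit.r2_reduced
    assert fit.F >= 0
    assert 0 < fit.p <= 1


def test_collinear_design_and_zero_delta_df_are_errors():
    rng = np.random.default_rng(3)
    x = rng.normal(size=20)
    with pytest.raises(io.ValidationError, match="collinear"):
        stats.nested_regression_ftest(
            rng.normal(size=20), x, np.column_stack([x, 2 * x])
        )
    with pytest.raises(io.ValidationError, match="delta df"):
        stats.nested_regression_ftest(rng.normal(size=20), x, x[:, None])


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------


def test_planted_spores_are_removed():
    pop, spores = simulate.simulate_cell_population(
        10, 100, 20_000, spore_frac=0.05, seed=5
    )
    gated, report = stats.gate_cells(pop)
    # At least 90% of spore-flagged cells disappear.
    n_spores_left = gated.n_cells - (~spores).sum() + (
        report.n_before - report.n_after - spores.sum()
    )
    from utr3end.stats import _scatter_keep

    keep = _scatter_keep(pop.fsc, 2.5) & _scatter_keep(pop.ssc, 2.5)
    assert (~keep[spores]).mean() >= 0.90


def test_homogeneous_population_loses_only_calibrated_tail():
    # Monte-Carlo calibration: for the generator's lognormal scatter and the
    # median +- 2.5 scaled-MAD gate, ~5% of cells sit outside on two channels.
    pop, _ = simulate.simulate_cell_population(10, 100, 50_000, seed=6)
    _, report = stats.gate_cells(pop)
    removed = 1 - report.n_after / report.n_before
    assert removed <= 0.07


def test_identical_scatter_removes_nothing():
    pop = io.CellPopulation(
        "s", 0.1,
        fsc=np.full(1000, 5.0), ssc=np.full(1000, 2.0),
        yfp=np.abs(np.random.default_rng(7).normal(100, 10, 1000)),
        mcherry=np.full(1000, 50.0),
    )
    gated, report = stats.gate_cells(pop)
    assert report.n_after == 1000


def test_over_gating_raises():
    pop, _ = simulate.simulate_cell_population(10, 100, 600, seed=8)
    with pytest.raises(io.ValidationError, match="over-gated"):
        stats.gate_cells(pop, stats.GateSpec(k=0.01, min_cells=500))


# ---------------------------------------------------------------------------
# Noise statistics
# ---------------------------------------------------------------------------


def test_hand_computed_noise_stats():
    pop = io.CellPopulation("s", 0.1, [1, 1], [1, 1], [10.0, 20.0], [1, 1])
    ns = stats.population_noise_stats(pop)
    assert ns.mean == pytest.approx(15.0)
    assert ns.variance == pytest.approx(50.0)  # unbiased (n-1)
    assert ns.noise == pytest.approx(50 / 225)
    assert ns.noise_strength == pytest.approx(50 / 15)
    assert ns.burst_frequency == pytest.approx(225 / 50)
    assert ns.burst_size == pytest.approx(50 / 15)


def test_gamma_population_recovers_burst_parameters():
    pop, _ = simulate.simulate_cell_population(10, 100, 100_000, seed=9)
    ns = stats.population_noise_stats(pop)
    assert ns.burst_frequency == pytest.approx(10, rel=0.05)
    assert ns.burst_size == pytest.approx(100, rel=0.05)


@given(st.floats(min_value=0.1, max_value=100.0))
@settings(max_examples=50, deadline=None)
def test_noise_identities_and_scale_covariance(g):
    rng = np.random.default_rng(10)
    base = np.abs(rng.normal(50, 10, 500)) + 1.0
    pop = io.CellPopulation("s", 0.1, base, base, base, base)
    ns = stats.population_noise_stats(pop)
    scaled = io.CellPopulation("s", 0.1, base, base, g * base, base)
    ns_g = stats.population_noise_stats(scaled)
    # identities hold to machine precision
    assert ns.noise_strength == pytest.approx(ns.noise * ns.mean, rel=1e-12)
    assert ns.burst_frequency * ns.burst_size == pytest.approx(ns.mean, rel=1e-12)
    # gain covariance: mean and noise strength scale, noise is invariant
    assert ns_g.mean == pytest.approx(g * ns.mean, rel=1e-9)
    assert ns_g.noise == pytest.approx(ns.noise, rel=1e-9)
    assert ns_g.noise_strength == pytest.approx(g * ns.noise_strength, rel=1e-9)


def test_non_positive_mean_is_an_error():
    pop = io.CellPopulation("s", 0.1, [1, 1], [1, 1], [0.0, 0.0], [1, 1])
    with pytest.raises(io.ValidationError, match="mean"):
        stats.population_noise_stats(pop)


# ---------------------------------------------------------------------------
# Plate correction
# ---------------------------------------------------------------------------


def _noise_stats(mean, noise, strain="s", plate=None):
    var = noise * mean**2
    return stats.NoiseStats(
        strain_id=strain, condition=0.1, n_cells=1000, mean=mean, variance=var,
        noise=noise, noise_strength=noise * mean,
        burst_frequency=1 / noise, burst_size=noise * mean, plate=plate,
    )


def test_plate_correction_hand_example():
    # reference grand mean 100 over two plates (120, 80): plate B has c_p = 1.25
    table = {
        "A": {"ref": _noise_stats(120, 0.1), "s": _noise_stats(60, 0.2)},
        "B": {"ref": _noise_stats(80, 0.1), "s": _noise_stats(40, 0.2)},
    }
    out = stats.plate_correct(table, "ref")
    assert out["B"]["s"].mean == pytest.approx(40 * 1.25)
    assert out["B"]["s"].noise == pytest.approx(0.2 / 1.25)
    # noise strength invariant: nu' = eta'^2 * mu' = eta^2 * mu
    assert out["B"]["s"].noise_strength == pytest.approx(0.2 * 40)


def test_plate_correction_identity_when_no_effect():
    table = {"A": {"ref": _noise_stats(100, 0.1), "s": _noise_stats(40, 0.2)}}
    out = stats.plate_correct(table, "ref")
    assert out["A"]["s"].mean == pytest.approx(40)
    assert out["A"]["s"].noise == pytest.approx(0.2)


def test_plate_correction_aligns_planted_plate_factor():
    """The same strain measured on two plates differing by a multiplicative
    factor comes out with matching corrected means."""
    rng_seeds = (11, 12)
    factor = 1.4
    table = {}
    for plate, seed in zip(("P1", "P2"), rng_seeds):
        scale = factor if plate == "P2" else 1.0
        ref_pop, _ = simulate.simulate_cell_population(
            20, 50, 50_000, seed=seed, strain_id="ref"
        )
        s_pop, _ = simulate.simulate_cell_population(
            10, 100, 50_000, seed=seed + 100, strain_id="s"
        )
        ref_pop.yfp *= scale
        s_pop.yfp *= scale
        table[plate] = {
            "ref": stats.population_noise_stats(ref_pop, plate=plate),
            "s": stats.population_noise_stats(s_pop, plate=plate),
        }
    out = stats.plate_correct(table, "ref")
    m1, m2 = out["P1"]["s"].mean, out["P2"]["s"].mean
    assert m2 == pytest.approx(m1, rel=0.03)


def test_missing_reference_names_the_plate():
    table = {"P9": {"s": _noise_stats(40, 0.2)}}
    with pytest.raises(io.ValidationError, match="P9"):
        stats.plate_correct(table, "ref")


# ---------------------------------------------------------------------------
# Orientation comparison
# ---------------------------------------------------------------------------


def _oriented(expr_t, expr_c):
    cons = []
    for i, e in enumerate(expr_t):
        cons.append(io.Construct(f"t{i}", "ACGT" * 30, orientation="tandem",
                                 intergenic_length=120, expression=float(e)))
    for i, e in enumerate(expr_c):
        cons.append(io.Construct(f"c{i}", "ACGT" * 30, orientation="convergent",
                                 intergenic_length=120, expression=float(e)))
    return cons


def test_identical_groups_give_maximal_pvalues():
    vals = np.linspace(1, 2, 20)
    rep = stats.orientation_group_compare(_oriented(vals, vals))
    assert rep.ks_p == pytest.approx(1.0)
    assert rep.ranksum_p > 0.99


def test_strongly_shifted_groups_are_detected():
    rng = np.random.default_rng(13)
    a = rng.normal(10, 1, 60)
    b = rng.normal(15, 1, 60)  # 5 sigma apart
    rep = stats.orientation_group_compare(_oriented(a, b))
    assert rep.ranksum_p < 1e-6
    assert rep.ks_p < 1e-6


def test_covariate_equal_to_expression_has_unit_rho():
    vals = np.linspace(1, 3, 15)
    cons = _oriented(vals, vals[::-1])
    cov = {"downstream_expression": {c.gene_id: c.expression for c in cons}}
    rep = stats.orientation_group_compare(cons, covariates=cov)
    rho, p = rep.covariate_rho["tandem"]["downstream_expression"]
    assert rho == pytest.approx(1.0)


def test_constant_covariate_is_undefined_marker():
    vals = np.linspace(1, 3, 15)
    rep = stats.orientation_group_compare(_oriented(vals, vals))
    rho, _ = rep.covariate_rho["tandem"]["intergenic_length"]
    assert np.isnan(rho)
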