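import math

import numpy as np
import pytest
from scipy import stats

from coldqtl import (
    STUCK,
    DensityCurve,
    FermentationSummary,
    GrowthCurve,
    PhenotypePanel,
    compare_to_control,
    fit_gompertz,
    generations,
    gompertz_y,
    heritability,
    is_stuck,
    preprocess_curve,
    relative_t100,
    t100,
    transgression,
)

E = math.e


# ---------------------------------------------------------------------------
# preprocessing


def test_constant_od_gives_zero_y():
    t = np.arange(5.0)
    _, y = preprocess_curve(GrowthCurve(t, np.full(5, 0.1)))
    np.testing.assert_allclose(y, 0.0)


def test_doubling_gives_t_ln2():
    t = np.arange(6.0)
    od = 0.1 * 2.0**t
    _, y = preprocess_curve(GrowthCurve(t, od))
    np.testing.assert_allclose(y, t * math.log(2), rtol=1e-12)


def test_blank_subtraction_identity():
    t = np.arange(6.0)
    signal = 0.1 * np.exp(0.3 * t)
    with_blank = GrowthCurve(t, signal + 0.05, blank=np.full(6, 0.05))
    without = GrowthCurve(t, signal)
    _, ya = preprocess_curve(with_blank)
    _, yb = preprocess_curve(without)
    np.testing.assert_allclose(ya, yb, rtol=1e-12)


def test_nonpositive_after_subtraction_lists_times():
    t = np.arange(4.0)
    curve = GrowthCurve(t, np.array([0.1, 0.04, 0.2, 0.3]), blank=np.full(4, 0.05))
    with pytest.raises(ValueError, match="t=1"):
        preprocess_curve(curve)


def test_curve_validation():
    with pytest.raises(ValueError):
        GrowthCurve(np.arange(3.0), np.ones(3))  # < 4 points
    with pytest.raises(ValueError):
        GrowthCurve(np.array([0.0, 1.0, 1.0, 2.0]), np.ones(4))  # not increasing


# ---------------------------------------------------------------------------
# Gompertz model


def test_value_at_lag_time():
    # t = lam makes the inner bracket 1: y = D * exp(-e)
    assert gompertz_y(5.0, D=2.0, mu_max=0.3, lam=5.0) == pytest.approx(2.0 * math.exp(-E))


def test_asymptote():
    y = gompertz_y(5.0 + 1e6, D=2.5, mu_max=0.3, lam=5.0)
    assert abs(y - 2.5) < 1e-12 * 2.5


def test_monotone_in_t_and_D():
    t = np.linspace(0, 100, 500)
    y = gompertz_y(t, 2.0, 0.3, 5.0)
    assert np.all(np.diff(y) >= 0)  # non-decreasing everywhere (float plateau)
    mid = (t > 2) & (t < 30)
    assert np.all(np.diff(y[mid]) > 0)  # strictly increasing off the plateau
    assert np.all(gompertz_y(t, 2.5, 0.3, 5.0) >= y)


def test_max_slope_equals_mu_max():
    D, mu, lam = 2.5, 0.3, 5.0
    t = np.linspace(0, 60, 600_001)
    y = gompertz_y(t, D, mu, lam)
    slope = np.diff(y) / np.diff(t)
    assert abs(slope.max() - mu) / mu < 1e-4


def test_nonpositive_D_rejected():
    with pytest.raises(ValueError):
        gompertz_y(1.0, D=0.0, mu_max=0.3, lam=5.0)


# ---------------------------------------------------------------------------
# fitting


def test_noise_free_recovery():
    t = np.arange(0, 96.5, 0.5)
    y = gompertz_y(t, 2.5, 0.3, 5.0)
    fit = fit_gompertz(t, y)
    assert fit.converged
    assert fit.D == pytest.approx(2.5, rel=1e-6)
    assert fit.mu_max == pytest.approx(0.3, rel=1e-6)
    assert fit.lam == pytest.approx(5.0, rel=1e-6)


@pytest.mark.parametrize("D,mu,lam", [(1.0, 0.05, 0.0), (3.0, 0.5, 20.0), (1.5, 0.12, 8.0)])
def test_recovery_across_grid(D, mu, lam):
    t = np.arange(0, 120.0, 0.5)
    fit = fit_gompertz(t, gompertz_y(t, D, mu, lam))
    assert fit.converged
    for got, true in ((fit.D, D), (fit.mu_max, mu), (fit.lam, lam)):
        assert abs(got - true) <= 1e-5 * max(abs(true), 1.0)


def test_noisy_recovery():
    t = np.arange(0, 96.5, 0.5)
    clean = gompertz_y(t, 2.5, 0.3, 5.0)
    rel_err = {"D": [], "mu": [], "lam": []}
    for seed in range(20):
        rng = np.random.default_rng(seed)
        fit = fit_gompertz(t, clean + rng.normal(0, 0.01, size=len(t)))
        rel_err["D"].append(abs(fit.D - 2.5) / 2.5)
        rel_err["mu"].append(abs(fit.mu_max - 0.3) / 0.3)
        rel_err["lam"].append(abs(fit.lam - 5.0) / 5.0)
    for v in rel_err.values():
        assert np.mean(v) < 0.05


def test_degenerate_curve_rejected():
    t = np.arange(0, 10.0)
    with pytest.raises(ValueError, match="degenerate"):
        fit_gompertz(t, np.zeros(10))


# ---------------------------------------------------------------------------
# heritability / transgression


def test_heritability_perfect():
    panel = PhenotypePanel(np.array([1.0, 2, 3, 4]), np.array([2.0, 2.0]), np.array([3.0, 3.0]))
    assert heritability(panel) == pytest.approx(100.0)


def test_heritability_formula_65():
    # segregant sample variance exactly 100; pooled parental variance exactly 35
    seg = np.array([-10.0, 0.0, 10.0])  # var (ddof=1) = 100
    d = math.sqrt(35.0 / 2.0)  # two-point sample var = 2 d^2 = 35
    panel = PhenotypePanel(seg, np.array([1 - d, 1 + d]), np.array([2 - d, 2 + d]))
    assert panel.pooled_parental_variance() == pytest.approx(35.0)
    assert heritability(panel) == pytest.approx(65.0)


def test_heritability_null_simulation():
    import warnings

    h2s = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        seg = rng.normal(0, 1, 200)
        panel = PhenotypePanel(seg, rng.normal(0, 1, 10), rng.normal(0, 1, 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # negative estimates are expected here
            h2s.append(heritability(panel))
    assert abs(np.mean(h2s)) < 15.0


def test_heritability_negative_flagged():
    panel = PhenotypePanel(np.array([0.0, 0.1, -0.1]), np.array([-5.0, 5.0]), np.array([-5.0, 5.0]))
    with pytest.warns(UserWarning, match="negative"):
        assert heritability(panel) < 0


def test_heritability_zero_variance_rejected():
    panel = PhenotypePanel(np.array([1.0, 1.0]), np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        heritability(panel)


def test_heritability_shift_scale_invariant():
    rng = np.random.default_rng(0)
    seg, pa, pb = rng.normal(2, 1, 50), rng.normal(1, 0.3, 5), rng.normal(3, 0.3, 5)
    h0 = heritability(PhenotypePanel(seg, pa, pb))
    h_shift = heritability(PhenotypePanel(seg + 7, pa + 7, pb + 7))
    h_scale = heritability(PhenotypePanel(seg * 3, pa * 3, pb * 3))
    assert h_shift == pytest.approx(h0, rel=1e-9)
    assert h_scale == pytest.approx(h0, rel=1e-9)


def test_transgression_none_between_parents():
    panel = PhenotypePanel(np.array([1.4, 1.5, 1.6]), np.array([1.0, 1.0]), np.array([2.0, 2.0]))
    res = transgression(panel)
    assert (res.n_high, res.n_low, res.frac_high, res.frac_low) == (0, 0, 0.0, 0.0)


def test_transgression_constructed_fractions():
    """48/300 above and 2/300 below -> 16% and 0.667%."""
    d = 0.05
    pa = np.array([1.0 - d, 1.0 + d])  # pooled var with pb: d^2 * 2 -> sigma
    pb = np.array([2.0 - d, 2.0 + d])
    sigma = math.sqrt((2 * d**2 + 2 * d**2) / 2)
    hi_thr = 2.0 + 2 * sigma
    lo_thr = 1.0 - 2 * sigma
    seg = np.concatenate([
        np.full(48, hi_thr + 0.01), np.full(2, lo_thr - 0.01), np.full(250, 1.5)])
    res = transgression(PhenotypePanel(seg, pa, pb))
    assert (res.n_high, res.n_low) == (48, 2)
    assert res.frac_high == pytest.approx(0.16)
    assert res.frac_low == pytest.approx(2 / 300)


def test_transgression_boundary_inclusive():
    d = 0.1
    pa, pb = np.array([1.0 - d, 1.0 + d]), np.array([2.0 - d, 2.0 + d])
    # rebuild the threshold with the implementation's own float operations
    pooled = ((len(pa) - 1) * pa.var(ddof=1) + (len(pb) - 1) * pb.var(ddof=1)) / (len(pa) + len(pb) - 2)
    hi_thr = max(pa.mean(), pb.mean()) + 2 * math.sqrt(pooled)
    seg = np.array([hi_thr, 1.5])  # exactly at the threshold: counted ("at least")
    assert transgression(PhenotypePanel(seg, pa, pb)).n_high == 1


def test_transgression_monotone_in_sigma():
    rng = np.random.default_rng(1)
    seg = rng.normal(1.5, 0.5, 300)
    counts = []
    for d in (0.01, 0.05, 0.2):
        pa = np.array([1.0 - d, 1.0 + d])
        pb = np.array([2.0 - d, 2.0 + d])
        res = transgression(PhenotypePanel(seg, pa, pb))
        counts.append(res.n_high + res.n_low)
    assert counts[0] >= counts[1] >= counts[2]


# ---------------------------------------------------------------------------
# generations


@pytest.mark.parametrize("n0,nt,expected", [(0.2, 0.4, 1.0), (0.2, 0.2, 0.0), (0.2, 12.8, 6.0)])
def test_generations(n0, nt, expected):
    assert generations(n0, nt) == pytest.approx(expected)


def test_generations_invalid():
    with pytest.raises(ValueError):
        generations(0.0, 1.0)
    with pytest.raises(ValueError):
        generations(1.0, -1.0)


# ---------------------------------------------------------------------------
# fermentation endpoints


def test_t100_linear_crossing():
    curve = DensityCurve(np.array([0.0, 135.0]), np.array([1100.0, 995.0]))
    assert t100(curve) == pytest.approx(135.0)


def test_t100_midpoint_interpolation():
    curve = DensityCurve(np.array([100.0, 110.0]), np.array([1000.0, 990.0]))
    assert t100(curve) == pytest.approx(105.0)


def test_t100_stuck():
    curve = DensityCurve(np.array([0.0, 100.0, 500.0]), np.array([1100.0, 1020.0, 1010.0]))
    assert is_stuck(t100(curve))


def test_t100_already_complete_rejected():
    with pytest.raises(ValueError):
        t100(DensityCurve(np.array([0.0, 10.0]), np.array([990.0, 980.0])))


def test_t100_redundant_points_invariant():
    t = np.array([0.0, 100.0])
    d = np.array([1100.0, 900.0])
    coarse = t100(DensityCurve(t, d))
    tf = np.linspace(0, 100, 51)
    df = np.interp(tf, t, d)
    fine = t100(DensityCurve(tf, df))
    assert fine == pytest.approx(coarse, abs=1e-9)


def test_relative_t100():
    control = FermentationSummary(135.0)
    assert relative_t100(control, control) == pytest.approx(1.0)
    assert relative_t100(FermentationSummary(270.0), control) == pytest.approx(2.0)
    assert is_stuck(relative_t100(FermentationSummary(STUCK), control))
    with pytest.raises(ValueError):
        relative_t100(control, FermentationSummary(STUCK))


# ---------------------------------------------------------------------------
# strain-vs-control tests


def test_identical_group_not_significant():
    groups = {"ctrl": [1.0, 1.1, 0.9], "same": [1.0, 1.1, 0.9]}
    out = compare_to_control(groups, "ctrl")
    assert not out["significant"].iloc[0]


def test_t_statistic_closed_form():
    # n=3 each, means 10 vs 14, both SD=1: t = -4 * sqrt(3/2), df = 4
    groups = {"ctrl": [13.0, 14.0, 15.0], "strain": [9.0, 10.0, 11.0]}
    out = compare_to_control(groups, "ctrl").set_index("strain")
    t_expected = -4.0 * math.sqrt(1.5)
    assert out.loc["strain", "t"] == pytest.approx(t_expected, rel=1e-12)
    p_expected = 2 * stats.t.cdf(t_expected, df=4)  # independent textbook evaluation
    assert out.loc["strain", "p_raw"] == pytest.approx(p_expected, rel=1e-9)


def test_bonferroni_bounds():
    rng = np.random.default_rng(5)
    groups = {"ctrl": rng.normal(0, 1, 5)}
    for i in range(6):
        groups[f"s{i}"] = rng.normal(0.5 * i, 1, 5)
    out = compare_to_control(groups, "ctrl")
    assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()
    assert (out["p_adj"] <= 1.0).all()


def test_bonferroni_family_size():
    groups = {"ctrl": [1.0, 2.0, 3.0], "a": [2.0, 3.0, 4.0], "b": [1.5, 2.5, 3.5]}
    out = compare_to_control(groups, "ctrl").set_index("strain")
    for s in ("a", "b"):
        raw, adj = out.loc[s, "p_raw"], out.loc[s, "p_adj"]
        assert adj == pytest.approx(min(1.0, raw * 2))


def test_zero_variance_equal_means_p1():
    groups = {"ctrl": [1.0, 1.0, 1.0], "same": [1.0, 1.0, 1.0]}
    out = compare_to_control(groups, "ctrl")
    assert out["p_raw"].iloc[0] == 1.0
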