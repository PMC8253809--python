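"""Log-logistic fitting, AICc selection, spline fallback, and AUC."""

import numpy as np
import pytest

import screenfit as sf
from screenfit.doseresponse import AUC_GRID, AUC_HI, AUC_LO, aicc, ec50_from_fit

from conftest import make_dataset


def grid_search_rss(dataset, medians, n_grid=200):
    """Brute-force oracle: best three-parameter RSS over a dense
    (hill, log10 ec50) grid with yFin profiled out by linear least squares
    (clipped to its box)."""
    hills = np.linspace(-10.0, -1e-3, n_grid)
    log_ecs = np.linspace(-11.0, -4.0, n_grid)
    x, y = dataset.concentrations, dataset.activities
    lnx = np.log(x)
    best = np.inf
    yfin_hi = max(0.0, medians.max_median)
    for h in hills:
        # shape matrix for all ec50 candidates at once: s = 1/(1+exp(h(lnx-lnec)))
        s = 1.0 / (1.0 + np.exp(h * (lnx[None, :] - np.log(10.0**log_ecs)[:, None])))
        denom = (s * s).sum(axis=1)
        yfin = np.clip((s * y[None, :]).sum(axis=1) / denom, 0.0, yfin_hi)
        rss = ((yfin[:, None] * s - y[None, :]) ** 2).sum(axis=1)
        best = min(best, float(rss.min()))
    return best


def logistic_auc_closed_form(y0, yfin, hill, ec50, lo=AUC_LO, hi=AUC_HI):
    """Analytic integral of the log-logistic curve over u = log10 x.

    With t = hill*ln(10)*(u - log10 ec50), the integrand is
    y0 + (yfin-y0)/(1+e^t) and the antiderivative of 1/(1+e^t) in u is
    -ln(1+e^t)/(hill*ln10).
    """
    c = hill * np.log(10.0)

    def anti(u):
        t = c * (u - np.log10(ec50))
        return y0 * u + (yfin - y0) * (u - np.logaddexp(0.0, t) / c)

    return anti(np.log10(hi)) - anti(np.log10(lo))


class TestPoolingAndMedians:
    def test_pool_concatenates_and_is_order_independent(self, threefold_series):
        reps = [make_dataset(0, 80, -1, 1e-7, replicates=1) for _ in range(3)]
        pooled = sf.pool_replicates(reps)
        assert pooled.n_points == 30
        shuffled = sf.pool_replicates(reps[::-1])
        assert np.array_equal(pooled.concentrations, shuffled.concentrations)
        assert np.array_equal(pooled.activities, shuffled.activities)

    def test_pool_rejects_mismatched_pairs(self):
        a = make_dataset(0, 80, -1, 1e-7, compound="A")
        b = make_dataset(0, 80, -1, 1e-7, compound="B")
        with pytest.raises(ValueError):
            sf.pool_replicates([a, b])

    def test_median_midpoint_convention(self):
        ds = sf.DoseResponseDataset("D", "L", [1e-7, 1e-7, 1e-6, 1e-6, 1e-6],
                                    [10.0, 20.0, 0.0, 50.0, 100.0])
        med = sf.concentration_medians(ds)
        assert med.medians == pytest.approx([15.0, 50.0])
        assert (med.min_median, med.max_median) == (15.0, 50.0)


class TestAicc:
    def test_stated_formula(self):
        # n=30, k=3, rss=30: 30*ln(1) + 6 + 24/26
        assert aicc(30, 3, 30.0) == pytest.approx(6.0 + 24.0 / 26.0, abs=1e-9)

    def test_penalty_monotone_in_k(self):
        assert aicc(30, 3, 12.0) < aicc(30, 4, 12.0)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc(5, 4, 1.0)


class TestSigmoidFit:
    def test_noiseless_parameter_recovery(self):
        # truth well inside the median-derived yFin box
        ds = make_dataset(0, 100, -1.0, 1e-8)
        fit = sf.fit_sigmoid(ds, model="three_param")
        assert fit.converged
        assert fit.yfin == pytest.approx(100.0, rel=1e-3)
        assert fit.hill == pytest.approx(-1.0, rel=1e-3)
        assert fit.ec50 == pytest.approx(1e-8, rel=1e-3)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ec50 = 10.0 ** rng.uniform(-9, -6)
            hill = rng.uniform(-4, -0.5)
            yfin = rng.uniform(30, 110)
            ds = make_dataset(0, yfin, hill, ec50, replicates=1)
            med = sf.concentration_medians(ds)
            fit = sf.fit_sigmoid(ds, med, "three_param")
            oracle = grid_search_rss(ds, med)
            assert fit.rss <= oracle + 1e-6

    def test_null_response_gives_near_zero_auc(self):
        ds = sf.DoseResponseDataset(
            "D", "L", np.tile(sf.build_dilution_series(35e-6, 10, 3).concentrations, 3),
            np.zeros(30))
        summary = sf.summarize_curve(ds)
        assert summary.auc is not None
        assert abs(summary.auc) <= 0.01 * 700.0


class TestModelSelection:
    def test_lower_aicc_wins_and_nonconverged_loses(self):
        ds = make_dataset(0, 90, -1, 1e-7)
        f3 = sf.fit_sigmoid(ds, model="three_param")
        f4 = sf.fit_sigmoid(ds, model="four_param")
        chosen = sf.select_model(f3, f4)
        assert chosen.aicc == min(f3.aicc, f4.aicc)
        f4.converged = False
        assert sf.select_model(f3, f4) is f3

    def test_baseline_shift_selects_four_param(self):
        # true zero-dose response of 20% with mild noise: the 3-parameter
        # model (y0 pinned at 0) cannot follow the data
        rng = np.random.default_rng(3)
        ds = make_dataset(20, 90, -1.5, 1e-7, noise_sd=2.0, rng=rng)
        med = sf.concentration_medians(ds)
        fit = sf.select_model(sf.fit_sigmoid(ds, med, "three_param"),
                              sf.fit_sigmoid(ds, med, "four_param"))
        assert fit.model == "four_param"
        assert fit.y0 == pytest.approx(20.0, abs=5.0)


class TestSplineFallback:
    def test_linear_data_reproduced_and_auc_matches_trapezoid(self):
        # activity linear in log10 concentration: a smoothing spline is
        # exact (zero roughness) and the AUC decomposes into the segment
        # integral plus flat extrapolation rectangles
        concs = np.logspace(-9, -5, 9)
        u = np.log10(concs)
        act = 10.0 * (u - u[0])  # 0 .. 40
        ds = sf.DoseResponseDataset("D", "L", concs, act)
        summary = sf.fit_spline_fallback(ds)
        assert summary.fit_kind == "spline"
        inner = 0.5 * (act[0] + act[-1]) * (u[-1] - u[0])
        left = act[0] * (u[0] - np.log10(AUC_LO))
        right = act[-1] * (np.log10(AUC_HI) - u[-1])
        assert summary.auc == pytest.approx(inner + left + right, rel=1e-6)

    def test_bell_shaped_data_gets_finite_auc(self):
        concs = np.logspace(-9, -5, 9)
        u = np.log10(concs)
        act = 60.0 * np.exp(-((u + 7.0) ** 2))  # non-monotone bump
        ds = sf.DoseResponseDataset("D", "L", concs, act)
        summary = sf.fit_spline_fallback(ds)
        assert summary.fit_kind == "spline" and np.isfinite(summary.auc)

    def test_too_few_concentrations_marked_unfit(self):
        ds = sf.DoseResponseDataset("D", "L", [1e-8, 1e-7, 1e-6], [0, 50, 90])
        summary = sf.fit_spline_fallback(ds)
        assert summary.fit_kind == "unfit" and summary.auc is None


class TestAUC:
    def test_constant_curves(self):
        assert sf.compute_auc(lambda x: np.zeros_like(x)) == pytest.approx(0.0)
        assert sf.compute_auc(lambda x: np.full_like(x, 100.0)) == pytest.approx(700.0)

    def test_matches_closed_form_logistic_integral(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            y0 = rng.uniform(0, 30)
            yfin = rng.uniform(40, 110)
            hill = rng.uniform(-6, -0.3)
            ec50 = 10.0 ** rng.uniform(-9, -6)
            fit = sf.SigmoidFit("four_param", y0, yfin, hill, ec50, 0.0, 30, 4,
                                0.0, True)
            exact = logistic_auc_closed_form(y0, yfin, hill, ec50)
            assert sf.compute_auc(fit) == pytest.approx(exact, rel=1e-3)

    def test_grid_refinement_stable(self):
        fit = sf.SigmoidFit("three_param", 0.0, 90.0, -2.0, 10.0**-7.5, 0.0,
                            30, 3, 0.0, True)
        a1 = sf.compute_auc(fit, n_grid=AUC_GRID)
        a2 = sf.compute_auc(fit, n_grid=2 * AUC_GRID - 1)
        assert a2 == pytest.approx(a1, rel=1e-4)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            sf.compute_auc(lambda x: x, lo=1e-4, hi=1e-11)


class TestEC50:
    def test_self_consistency_and_absent_when_not_converged(self):
        ds = make_dataset(0, 100, -1.0, 1e-7)
        fit = sf.fit_sigmoid(ds, model="three_param")
        assert ec50_from_fit(fit) == pytest.approx(1e-7, rel=0.01)
        fit.converged = False
        assert ec50_from_fit(fit) is None

    def test_monotone_curve_on_dense_grid(self):
        ds = make_dataset(0, 95, -3.0, 1e-7)
        fit = sf.fit_sigmoid(ds, model="three_param")
        x = np.logspace(-11, -4, 500)
        y = fit(x)
        assert np.all(np.diff(y) >= -1e-9)


class TestEndToEndTable:
    def test_fit_table_shape_and_determinism(self, threefold_series):
        import pandas as pd
        rng = np.random.default_rng(5)
        rows = []
        for cid, ec in [("A", 1e-8), ("B", 1e-7)]:
            for rep in range(3):
                for c in threefold_series.concentrations:
                    a = float(sf.loglogistic(c, 0, 90, -1.5, ec))
                    rows.append(dict(compound_id=cid, cell_line="L1",
                                     concentration_M=c,
                                     activity_pct=a + rng.normal(0, 1),
                                     replicate_id=f"r{rep}"))
        table = pd.DataFrame(rows)
        fits1 = sf.fit_activity_table(table)
        fits2 = sf.fit_activity_table(table.sample(frac=1, random_state=0))
        assert len(fits1) == 2
        assert (fits1["fit_kind"] == "sigmoid").all()
        pd.testing.assert_frame_equal(
            fits1.sort_values("compound_id", ignore_index=True),
            fits2.sort_values("compound_id", ignore_index=True))
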