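"""Interval averaging, spline basis, mixed-model curves and reductions."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from lltproject import (
    combine_reductions,
    fit_trajectory_model,
    interval_averages,
    natural_spline_basis,
    scenario_reduction,
)
from lltproject.trajmodel import RandomInterceptModel


def _avg_frame(points, end):
    df = pd.DataFrame(points, columns=["day", "value"])
    df.insert(0, "patient_id", 0)
    return interval_averages(df, pd.Series({0: end}))


class TestIntervalAverages:
    def test_constant_bin(self):
        res = _avg_frame([(0, 90.0)], 29)
        assert res["value"].tolist() == [90.0]
        assert res["weight"].tolist() == [30.0]

    def test_equal_split(self):
        # 100 on days 0-14, 80 on days 15-29 -> (15*100 + 15*80)/30 = 90
        res = _avg_frame([(0, 100.0), (15, 80.0)], 29)
        assert res["value"].iloc[0] == pytest.approx(90.0)

    def test_unequal_split(self):
        # 100 on days 0-9, 70 on days 10-29 -> (10*100 + 20*70)/30 = 80
        res = _avg_frame([(0, 100.0), (10, 70.0)], 29)
        assert res["value"].iloc[0] == pytest.approx(80.0)

    def test_partial_terminal_bin(self):
        res = _avg_frame([(0, 100.0)], 44)
        assert res["value"].tolist() == [100.0, 100.0]
        assert res["weight"].tolist() == [30.0, 15.0]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            interval_averages(
                pd.DataFrame(columns=["patient_id", "day", "value"]), pd.Series(dtype=float)
            )

    def test_matches_daily_integration_oracle(self):
        """Weighted averaging equals brute-force averaging on a daily grid."""
        rng = np.random.default_rng(21)
        for _ in range(25):
            n_pts = rng.integers(1, 8)
            days = np.unique(np.r_[0, rng.integers(1, 400, n_pts - 1)])
            values = rng.uniform(30, 200, days.size)
            end = int(rng.integers(days.max(), 430))
            res = _avg_frame(list(zip(days, values)), end)
            # oracle: materialize the step function day by day
            daily = np.empty(end + 1)
            for d, v in zip(days, values):
                daily[d:] = v
            for _, row in res.iterrows():
                lo = int(row.interval) * 30
                hi = min(lo + 30, end + 1)
                assert row.value == pytest.approx(daily[lo:hi].mean())
                assert row.weight == hi - lo


class TestNaturalSplineBasis:
    def test_dimension_and_boundary_linearity(self):
        x = np.linspace(0, 1460, 200)
        interior = np.quantile(x, [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6])
        H = natural_spline_basis(x, interior, (0, 1460))
        assert H.shape == (200, 6)
        # natural constraint: second differences vanish near the boundaries
        d2 = np.diff(H[:4], 2, axis=0)
        assert np.abs(d2).max() < 1e-4

    def test_invalid_knots_raise(self):
        with pytest.raises(ValueError):
            natural_spline_basis(np.arange(10.0), [5.0, 2.0], (0.0, 9.0))
        with pytest.raises(ValueError):
            natural_spline_basis(np.arange(10.0), [12.0], (0.0, 9.0))

    def test_matches_r_splines_ns(self, tmp_path):
        """OLS fits on our basis and on R's splines::ns agree exactly."""
        rng = np.random.default_rng(42)
        x = np.linspace(0, 1460, 40)
        y = 90 - 20 * np.exp(-x / 300) + rng.normal(0, 5, x.size)
        interior = np.quantile(x, np.arange(1, 6) / 6)
        H = np.column_stack([np.ones_like(x), natural_spline_basis(x, interior, (0, 1460))])
        beta, *_ = np.linalg.lstsq(H, y, rcond=None)
        fit_py = H @ beta
        csv = tmp_path / "d.csv"
        np.savetxt(csv, np.column_stack([x, y]), delimiter=",", header="x,y", comments="")
        r = subprocess.run(
            [
                "Rscript",
                "-e",
                f'd <- read.csv("{csv}"); k <- quantile(d$x, (1:5)/6);'
                "f <- lm(y ~ splines::ns(x, knots=k, Boundary.knots=c(0,1460)), data=d);"
                'cat(sprintf("%.12f\\n", fitted(f)))',
            ],
            capture_output=True,
            text=True,
            timeout=120,
        )
        fit_r = np.array([float(v) for v in r.stdout.split()])
        assert np.abs(fit_py - fit_r).max() < 1e-8


class TestRandomInterceptModel:
    def _panel(self, seed=3, n_pat=150, n_bins=12):
        rng = np.random.default_rng(seed)
        codes = np.repeat(np.arange(n_pat), n_bins)
        day = np.tile(np.arange(n_bins) * 30 + 15.0, n_pat)
        interior = np.quantile(day, np.arange(1, 6) / 6)
        X = np.column_stack(
            [np.ones(day.size), natural_spline_basis(day, interior, (0, n_bins * 30))]
        )
        y = (
            85
            - 15 * np.exp(-day / 150)
            + rng.normal(0, 9, n_pat)[codes]
            + rng.normal(0, 7, day.size)
        )
        return y, X, codes

    def test_matches_statsmodels_mixedlm(self):
        """Profiled-ML fitter agrees with statsmodels MixedLM (ML)."""
        import warnings

        import statsmodels.api as sm

        y, X, codes = self._panel()
        m = RandomInterceptModel(y, X, codes)
        beta = m.fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(y, X, groups=codes).fit(reml=False)
        assert np.abs(beta - np.asarray(ref.fe_params)).max() < 1e-6
        lam_ref = float(np.asarray(ref.cov_re)[0, 0] / ref.scale)
        assert m.lambda_ == pytest.approx(lam_ref, rel=1e-2)

    def test_weights_equal_duplication(self):
        """Cluster weight 2 is exactly a duplicated cluster."""
        y, X, codes = self._panel(n_pat=40)
        m = RandomInterceptModel(y, X, codes)
        w = np.ones(40)
        w[3] = 2
        beta_w = m.fit(w)
        # duplicate cluster 3 explicitly as a new cluster
        sel = codes == 3
        y2 = np.r_[y, y[sel]]
        X2 = np.vstack([X, X[sel]])
        codes2 = np.r_[codes, np.full(sel.sum(), 40)]
        beta_dup = RandomInterceptModel(y2, X2, codes2).fit()
        assert np.abs(beta_w - beta_dup).max() < 1e-8

    def test_unsorted_clusters_rejected(self):
        y, X, codes = self._panel(n_pat=5)
        with pytest.raises(ValueError):
            RandomInterceptModel(y, X, codes[::-1])


def _balanced_averages(values_by_scenario, n_pat, n_bins, sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for sc, mu in values_by_scenario.items():
        mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_bins,))
        for p in range(n_pat):
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": p,
                        "scenario": sc,
                        "interval": np.arange(n_bins),
                        "value": mu + rng.normal(0, sd, n_bins),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


class TestFitTrajectoryModel:
    def test_degenerate_constant_cohort(self):
        """All-constant LDL-C: flat mean curve with zero-width CI."""
        avgs = _balanced_averages({"observed": 95.0}, n_pat=30, n_bins=12)
        curves = fit_trajectory_model(
            avgs, n_bootstrap=20, seed=1, boundary=(0.0, 360.0)
        )
        c = curves["observed"]
        assert np.allclose(c.mean, 95.0, atol=1e-8)
        assert np.all(c.hi - c.lo < 1e-8)

    def test_bootstrap_prefix_stability(self):
        avgs = _balanced_averages({"observed": 90.0}, n_pat=25, n_bins=10, sd=6.0, seed=2)
        few = fit_trajectory_model(avgs, n_bootstrap=2, seed=7, boundary=(0.0, 300.0))
        more = fit_trajectory_model(avgs, n_bootstrap=6, seed=7, boundary=(0.0, 300.0))
        np.testing.assert_allclose(
            few["observed"].boot_curves, more["observed"].boot_curves[:2]
        )

    def test_recovers_piecewise_mean_away_from_jump(self):
        """True mean 100 before day 90, 70 after: fit matches bin means at 180+."""
        n_bins = 24
        mu = np.where(np.arange(n_bins) * 30 + 15 < 90, 100.0, 70.0)
        avgs = _balanced_averages({"observed": mu}, n_pat=120, n_bins=n_bins, sd=8.0, seed=4)
        curves = fit_trajectory_model(
            avgs, n_bootstrap=30, seed=4, boundary=(0.0, 720.0)
        )
        c = curves["observed"]
        late = c.grid >= 180
        emp = 70.0  # empirical mean of late bins by construction
        assert np.abs(c.mean[late] - emp).max() < 2.0

    def test_ci_ordering(self):
        avgs = _balanced_averages({"observed": 90.0}, n_pat=40, n_bins=12, sd=10.0, seed=5)
        c = fit_trajectory_model(avgs, n_bootstrap=40, seed=5, boundary=(0.0, 360.0))[
            "observed"
        ]
        assert np.all(c.lo <= c.mean + 1e-9)
        assert np.all(c.mean <= c.hi + 1e-9)

    def test_validation(self):
        avgs = _balanced_averages({"observed": 90.0}, n_pat=5, n_bins=4)
        with pytest.raises(ValueError):
            fit_trajectory_model(avgs, n_bootstrap=0)
        with pytest.raises(ValueError):
            fit_trajectory_model(avgs, spline_df=2)


class TestScenarioReduction:
    def _curves(self, obs_mu, statin_mu, ez_mu):
        avgs = _balanced_averages(
            {"observed": obs_mu, "opt_statin": statin_mu, "opt_statin_ez": ez_mu},
            n_pat=25,
            n_bins=12,
        )
        return fit_trajectory_model(avgs, n_bootstrap=10, seed=3, boundary=(0.0, 360.0))

    def test_identical_scenarios_zero_reduction(self):
        red = scenario_reduction(self._curves(90.0, 90.0, 90.0))
        for q in ("statin", "incremental_ez", "total"):
            sub = red[red.quantity == q]
            assert np.allclose(sub["est"], 0.0, atol=1e-8)

    def test_component_arithmetic(self):
        red = scenario_reduction(self._curves(100.0, 80.0, 72.0))
        at = lambda q: red[red.quantity == q]["est"].iloc[5]
        assert at("statin") == pytest.approx(20.0, abs=1e-6)
        assert at("incremental_ez") == pytest.approx(8.0, abs=1e-6)
        assert at("total") == pytest.approx(at("statin") + at("incremental_ez"))
        assert at("ez_ratio") == pytest.approx(8.0 / 20.0, abs=1e-6)

    def test_missing_scenario_raises(self):
        avgs = _balanced_averages({"observed": 90.0}, n_pat=10, n_bins=6)
        curves = fit_trajectory_model(avgs, n_bootstrap=5, seed=1, boundary=(0.0, 180.0))
        with pytest.raises(ValueError):
            scenario_reduction(curves)


class TestCombineReductions:
    def test_totals_and_ratio(self):
        total, ratio = combine_reductions(21.9, 8.7)
        assert total == pytest.approx(30.6)
        assert ratio == pytest.approx(39.7, abs=0.05)

    def test_zero_component_raises(self):
        with pytest.raises(ZeroDivisionError):
            combine_reductions(0.0, 5.0)
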