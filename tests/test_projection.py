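"""Cumulative incidence, rate-ratio projection, NNT."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lltproject import (
    CttAssociation,
    cumulative_incidence,
    lognormal_params,
    nnt,
    nnt_with_ci,
    outcome_survival_data,
    project_incidence,
    run_projection,
)


def brute_force_cif(durations, status, grid):
    """Independent discrete-time Aalen-Johansen implementation."""
    durations = np.asarray(durations, dtype=float)
    status = np.asarray(status)
    out = []
    for g in np.asarray(grid, dtype=float):
        surv = 1.0
        cif = 0.0
        for t in sorted(set(durations)):
            if t > g:
                break
            at_risk = np.sum(durations >= t)
            d_any = np.sum((durations == t) & (status > 0))
            d_int = np.sum((durations == t) & (status == 1))
            cif += surv * d_int / at_risk
            surv *= 1.0 - d_any / at_risk
        out.append(cif)
    return np.array(out)


class TestCumulativeIncidence:
    def test_no_events(self):
        cif = cumulative_incidence([5, 6, 7], [0, 0, 0], [10])
        assert cif.tolist() == [0.0]

    def test_four_patient_worked_example(self):
        """Death at t1, MI at t2, censored t3, event-free t4 -> CIF_MI(t2)=0.25."""
        cif = cumulative_incidence([1, 2, 3, 4], [2, 1, 0, 0], [2])
        assert cif[0] == pytest.approx((1 - 1 / 4) * (1 / 3))
        assert cif[0] == pytest.approx(0.25)

    def test_death_without_censoring_is_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 200)
        cif = cumulative_incidence(t, np.ones_like(t), [5.0, 10.0, 20.0])
        for g, c in zip([5.0, 10.0, 20.0], cif):
            assert c == pytest.approx((t <= g).mean())

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(3, 40))
            t = rng.integers(1, 15, n).astype(float)  # heavy ties
            s = rng.integers(0, 3, n)
            grid = np.array([2.0, 5.0, 9.0, 14.0, 20.0])
            np.testing.assert_allclose(
                cumulative_incidence(t, s, grid),
                brute_force_cif(t, s, grid),
                atol=1e-12,
            )

    def test_matches_lifelines(self):
        from lifelines import AalenJohansenFitter, KaplanMeierFitter

        rng = np.random.default_rng(23)
        t = rng.uniform(0.5, 20, 300)  # tie-free for lifelines comparability
        s = rng.integers(0, 3, 300)
        grid = np.array([4.0, 8.0, 16.0])
        ours = cumulative_incidence(t, s, grid)
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(t, s, event_of_interest=1)
        ref = ajf.cumulative_density_.iloc[:, 0]
        for g, v in zip(grid, ours):
            assert v == pytest.approx(float(ref[ref.index <= g].iloc[-1]), abs=1e-10)
        km_ours = cumulative_incidence(t, (s > 0).astype(int), grid)
        km = KaplanMeierFitter().fit(t, s > 0)
        for g, v in zip(grid, km_ours):
            assert v == pytest.approx(
                1 - float(km.survival_function_at_times(g).iloc[0]), abs=1e-10
            )

    def test_cif_sum_plus_survivor_at_most_one(self):
        rng = np.random.default_rng(5)
        t = rng.integers(1, 30, 500).astype(float)
        s = rng.integers(0, 3, 500)
        grid = np.arange(1.0, 31.0)
        cif1 = cumulative_incidence(t, s, grid)
        s_swapped = np.where(s == 1, 2, np.where(s == 2, 1, 0))
        cif2 = cumulative_incidence(t, s_swapped, grid)
        surv = 1 - cumulative_incidence(t, (s > 0).astype(int), grid)
        assert np.all(cif1 + cif2 + surv <= 1 + 1e-9)
        assert np.allclose(cif1 + cif2 + surv, 1.0, atol=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cumulative_incidence([], [], [1.0])


class TestOutcomeSurvivalData:
    def _events(self):
        return pd.DataFrame(
            {
                "patient_id": [0, 0, 1, 2, 3],
                "event": ["mi", "death", "revascularization", "revascularization", "death"],
                "day": [100, 200, 20, 400, 50],
            }
        )

    def test_death(self):
        fu = pd.Series({0: 200.0, 1: 1460.0, 2: 1460.0, 3: 50.0})
        dur, st_ = outcome_survival_data(self._events(), fu, "death")
        assert dur.tolist() == [200.0, 1460.0, 1460.0, 50.0]
        assert st_.tolist() == [1, 0, 0, 1]

    def test_nonfatal_with_competing_death(self):
        fu = pd.Series({0: 200.0, 1: 1460.0, 2: 1460.0, 3: 50.0})
        dur, st_ = outcome_survival_data(self._events(), fu, "mi")
        assert (dur[0], st_[0]) == (100.0, 1)  # MI before death
        assert (dur[3], st_[3]) == (50.0, 2)  # death competes
        assert st_[1] == 0 and st_[2] == 0

    def test_early_revascularization_ignored(self):
        """Events in the first 30 days do not count for revascularization."""
        fu = pd.Series({0: 200.0, 1: 1460.0, 2: 1460.0, 3: 50.0})
        dur, st_ = outcome_survival_data(self._events(), fu, "revascularization")
        assert st_[1] == 0  # day-20 event ignored, patient censored at end
        assert dur[1] == 1460.0
        assert (dur[2], st_[2]) == (400.0, 1)


class TestLognormalParams:
    def test_degenerate(self):
        assert lognormal_params(CttAssociation("x", 1.0, 1.0, 1.0)) == (0.0, 0.0)

    def test_published_association(self):
        meanlog, sdlog = lognormal_params(CttAssociation("mve", 0.78, 0.65, 0.94))
        assert meanlog == pytest.approx(math.log(0.78))
        assert meanlog == pytest.approx(-0.2485, abs=5e-5)
        assert sdlog == pytest.approx(
            (math.log(0.94) - math.log(0.65)) / (2 * 1.959964), rel=1e-6
        )
        assert sdlog == pytest.approx(0.0941, abs=5e-5)

    def test_geometric_mean_property(self):
        lo, hi = 0.6, 0.9
        rr = math.sqrt(lo * hi)
        meanlog, sdlog = lognormal_params(CttAssociation("x", rr, lo, hi))
        assert meanlog == pytest.approx((math.log(lo) + math.log(hi)) / 2)

    def test_invalid_association(self):
        with pytest.raises(ValueError):
            CttAssociation("x", 0.8, 0.9, 1.0)
        with pytest.raises(ValueError):
            CttAssociation("x", -0.5, -0.9, 1.0)


class TestProjectIncidence:
    @pytest.mark.parametrize(
        "inc, delta, rr, expected",
        [
            (0.10, 0.0, 0.5, 0.10),
            (0.10, 38.67, 0.78, 0.078),
            (0.10, 30.6, 0.78, 0.10 * 0.78 ** (30.6 / 38.67)),
        ],
    )
    def test_examples(self, inc, delta, rr, expected):
        assert project_incidence(inc, delta, rr) == pytest.approx(expected, rel=1e-12)

    def test_third_example_value(self):
        # 0.10 * 0.78 ** (30.6 / 38.67) evaluated with math.exp/math.log
        expected = 0.10 * math.exp(math.log(0.78) * 30.6 / 38.67)
        assert expected == pytest.approx(0.0821511, abs=5e-7)
        assert project_incidence(0.10, 30.6, 0.78) == pytest.approx(expected, rel=1e-12)

    def test_clamped(self):
        assert project_incidence(0.9, -60.0, 0.5) == 1.0  # rr^negative exponent > 1

    def test_negative_rr_raises(self):
        with pytest.raises(ValueError):
            project_incidence(0.1, 10.0, -0.5)

    def test_strictly_decreasing_in_delta(self):
        deltas = np.linspace(0, 80, 50)
        vals = project_incidence(0.2, deltas, 0.78)
        assert np.all(np.diff(vals) < 0)


class TestNnt:
    @pytest.mark.parametrize(
        "arr, expected",
        [(0.5, 2), (0.0133, 76), (0.0180, 56), (0.25, 4), (1.0, 1)],
    )
    def test_examples(self, arr, expected):
        assert nnt(arr) == expected

    def test_not_applicable(self):
        assert nnt(0.0) is None
        assert nnt(-0.01) is None
        assert nnt(float("nan")) is None

    def test_ci_orientation(self):
        point, lo, hi = nnt_with_ci(0.0133, 0.0091, 0.0175)
        assert (point, lo, hi) == (76, 58, 110)

    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_ceiling_consistency(self, x):
        n = nnt(x)
        assert n * x >= 1.0 > (n - 1) * x


class TestRunProjection:
    def _inputs(self, n=300, seed=8):
        rng = np.random.default_rng(seed)
        grid = np.array([180.0, 365.0, 730.0])
        obs = np.tile(rng.uniform(60, 120, n)[:, None], (1, grid.size))
        values = {"observed": obs, "opt_statin": obs - 20.0, "opt_statin_ez": obs - 28.0}
        t = rng.uniform(30, 800, n)
        censored = t > 730
        t[censored] = 730
        status = np.where(censored, 0, 1)
        survival = {"death": (t, status)}
        return values, survival, grid

    def test_rr_one_projects_identity(self):
        values, survival, grid = self._inputs()
        assoc = {"death": CttAssociation("death", 1.0, 1.0, 1.0)}
        res = run_projection(values, survival, grid, assoc, n_bootstrap=20, seed=1)
        assert np.allclose(res["arr"], 0.0, atol=1e-12)
        assert np.allclose(res["projected_inc"], res["observed_inc"], atol=0.05)

    def test_deterministic(self):
        values, survival, grid = self._inputs()
        a = run_projection(values, survival, grid, n_bootstrap=15, seed=4)
        b = run_projection(values, survival, grid, n_bootstrap=15, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_ezetimibe_reduction_dominates(self):
        """Larger LDL-C reduction -> larger projected risk reduction."""
        values, survival, grid = self._inputs()
        res = run_projection(values, survival, grid, n_bootstrap=30, seed=2)
        piv = res.pivot_table(index=["outcome", "day"], columns="scenario", values="arr")
        assert (piv["opt_statin_ez"] >= piv["opt_statin"] - 1e-12).all()

    def test_strata_split(self):
        values, survival, grid = self._inputs()
        mask = np.zeros(300, dtype=bool)
        mask[:150] = True
        res = run_projection(
            values,
            survival,
            grid,
            n_bootstrap=10,
            seed=3,
            strata={"acs": mask, "non_acs": ~mask},
        )
        assert set(res["stratum"]) == {"acs", "non_acs"}

    def test_unknown_rr_mode(self):
        values, survival, grid = self._inputs()
        with pytest.raises(ValueError):
            run_projection(values, survival, grid, n_bootstrap=2, rr_mode="sometimes")

    def test_per_timepoint_mode_runs(self):
        values, survival, grid = self._inputs()
        res = run_projection(
            values, survival, grid, n_bootstrap=10, seed=5, rr_mode="per_timepoint"
        )
        assert len(res) == grid.size * 2
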