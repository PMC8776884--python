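"""Schaefer inversion, viable-pair sampling and fleet trait estimation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fleetres import (
    EffortSeries,
    FleetResilienceModel,
    FleetTraits,
    PriorConfig,
    estimate_traits,
    implied_catch,
    sample_viable_pairs,
    simulate_schaefer,
    stress_series,
    viability_mask,
)
from fleetres.synthetic import ADRIATIC_FLEETS, simulate_effort_series


def months_from(year, month, n):
    return [( (year + (month - 1 + i) // 12), (month - 1 + i) % 12 + 1) for i in range(n)]


class TestImpliedCatch:
    def test_hand_value(self):
        # 1000 + 0.6*1000*(1 - 1000/2000) - 900 = 400
        assert implied_catch([1000.0, 900.0], r=0.6, kq=2000.0)[0] == pytest.approx(400.0)

    def test_equilibrium_gives_zero(self):
        assert np.allclose(implied_catch([2000.0] * 5, r=0.8, kq=2000.0), 0.0)

    def test_small_r_limit_is_pure_difference(self):
        assert implied_catch([500.0, 450.0], r=1e-12, kq=1000.0)[0] == pytest.approx(50.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            implied_catch([100.0, -5.0], r=0.5, kq=200.0)
        with pytest.raises(ValueError):
            implied_catch([100.0, 90.0], r=-0.5, kq=200.0)

    @given(
        r=st.floats(0.05, 2.0),
        kq=st.floats(200.0, 5000.0),
        a0_frac=st.floats(0.1, 0.9),
    )
    def test_inversion_roundtrip(self, r, kq, a0_frac):
        """Forward simulation with the implied catch reconstructs the series."""
        rng = np.random.default_rng(0)
        a = [a0_frac * kq]
        for _ in range(10):
            a.append(max(a[-1] * rng.uniform(0.7, 1.2), 1.0))
        a = np.asarray(a)
        cq = implied_catch(a, r, kq)
        back = simulate_schaefer(a[0], r, kq, cq)
        assert np.allclose(back, a, rtol=1e-9)


class TestViablePairs:
    def test_constant_series_viability_rule(self):
        """For constant A=100, a pair is viable iff kq >= 100."""
        a = np.array([100.0, 100.0, 100.0])
        r = np.linspace(0.05, 2.0, 25)
        for kq in (50.0, 99.0, 100.0, 250.0):
            mask = viability_mask(a, r, np.full_like(r, kq))
            assert mask.all() == (kq >= 100.0)
            assert mask.any() == (kq >= 100.0)

    def test_sampler_matches_exhaustive_enumeration(self):
        """On a 4-month series, vectorized viability equals a brute-force loop
        over a 20x20 (r, kq) grid, exactly."""
        a = np.array([800.0, 650.0, 700.0, 780.0])
        r_grid = np.exp(np.linspace(np.log(0.05), np.log(2.0), 20))
        kq_grid = np.exp(np.linspace(np.log(800.0), np.log(3200.0), 20))
        rr, kk = map(np.ravel, np.meshgrid(r_grid, kq_grid))
        mask = viability_mask(a, rr, kk)
        for r, kq, got in zip(rr, kk, mask):
            ok = max(a) <= kq
            for t in range(3):
                cq = a[t] + r * a[t] * (1 - a[t] / kq) - a[t + 1]
                ok = ok and cq >= 0
            assert got == ok
        assert mask.any() and not mask.all()

    def test_impossible_growth_yields_no_viable_pairs(self):
        series = EffortSeries("OTB", months_from(2019, 1, 4), [1.0, 3.0, 9.0, 27.0])
        with pytest.raises(ValueError, match="widen"):
            sample_viable_pairs(series, PriorConfig(n_samples=2000, seed=0))

    def test_deterministic_under_seed(self):
        series = EffortSeries("PS", months_from(2019, 1, 6), [500, 430, 460, 510, 480, 490.0])
        a = sample_viable_pairs(series, PriorConfig(n_samples=5000, seed=3))
        b = sample_viable_pairs(series, PriorConfig(n_samples=5000, seed=3))
        pd.testing.assert_frame_equal(a, b)


class TestTraits:
    def test_single_pair_degenerates_gracefully(self):
        t = estimate_traits(pd.DataFrame({"r": [1.0], "kq": [400.0]}))
        assert t.r_hat == 1.0 and t.kq_hat == 400.0
        assert t.r_ci == (1.0, 1.0) and t.kq_ci == (400.0, 400.0)
        assert t.msr == pytest.approx(100.0)

    def test_msr_from_adriatic_purse_seine_point_estimates(self):
        t = FleetTraits(1.04, (0.75, 1.52), 20818.0, (18842.0, 23175.0), n_viable=5000)
        assert t.msr == pytest.approx(5412.68)

    def test_median_of_symmetric_cloud_is_centre(self):
        rng = np.random.default_rng(1)
        eps = rng.uniform(-0.2, 0.2, 4001)
        cloud = pd.DataFrame({"r": 1.0 + eps, "kq": 900.0 + 100 * eps})
        t = estimate_traits(cloud)
        assert t.r_hat == pytest.approx(1.0, abs=0.01)
        assert t.kq_hat == pytest.approx(900.0, abs=1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            estimate_traits(pd.DataFrame({"r": [], "kq": []}))


class TestStressSeries:
    def _series(self, hours):
        return EffortSeries("PS", months_from(2020, 1, len(hours)), hours)

    def test_states_from_cmsr(self):
        # r=0.4, kq=1000 -> msr=100; constructed so Cq = [50, 150]
        a = np.array([500.0, 550.0, 500.0])
        r, kq = 0.4, 1000.0
        cq = implied_catch(a, r, kq)
        t = FleetTraits(r, (r, r), kq, (kq, kq), n_viable=1)
        s = stress_series(self._series(a), t)
        assert np.allclose(s["Cmsr"], cq / 100.0)
        assert list(s["state"]) == ["UNDER" if c < 100 else "OVER" for c in cq]

    def test_sustainable_at_exact_msr(self):
        r, kq = 0.4, 1000.0
        msr = r * kq / 4
        a = simulate_schaefer(500.0, r, kq, [msr] * 5)
        t = FleetTraits(r, (r, r), kq, (kq, kq), n_viable=1)
        s = stress_series(self._series(a), t)
        assert (s["state"] == "SUSTAINABLE").all()
        assert np.allclose(s["Cmsr"], 1.0)

    def test_stress_peaks_in_shock_month(self, fleet_fits):
        for gear, res in fleet_fits.items():
            s = res.stress
            peak = s.loc[s["Cmsr"].idxmax()]
            assert (int(peak["year"]), int(peak["month"])) in {(2020, 3), (2020, 4), (2020, 5)}


class TestModelApi:
    def test_fit_report_and_summary(self, fleet_fits):
        res = fleet_fits["PS"]
        rep = res.to_report()
        assert rep["fleet"] == "PS" and rep["n_months"] == 71
        assert len(res.stress) == 70
        assert rep["traits"]["n_viable"] > 0
        text = res.summary()
        assert "MSR" in text and "viable" in text

    def test_fit_deterministic_under_seed(self):
        p = dataclasses.replace(ADRIATIC_FLEETS["PTM"], noise_cv=0.0)
        series = simulate_effort_series(p)
        a = FleetResilienceModel(series, prior=PriorConfig(n_samples=10_000, seed=4)).fit()
        b = FleetResilienceModel(series, prior=PriorConfig(n_samples=10_000, seed=4)).fit()
        assert a.traits == b.traits

    def test_single_lucky_sample_collapses_cis(self):
        series = EffortSeries("PS", months_from(2020, 1, 3), [100.0, 100.0, 100.0])
        res = FleetResilienceModel(series, prior=PriorConfig(n_samples=1, seed=0)).fit()
        assert res.traits.n_viable == 1
        assert res.traits.r_ci == (res.traits.r_hat, res.traits.r_hat)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorConfig(r_range=(2.0, 0.05))
        with pytest.raises(ValueError):
            PriorConfig(n_samples=0)

    def test_roundtrip_for_fitted_viable_pairs(self, fleet_fits):
        """Any viable pair inverts and re-simulates each monthly step to 1e-9.

        The step-wise check is the sharp one: over a full 71-month
        trajectory, float rounding is amplified by the product of the
        logistic map's derivatives, which for fast-growth pairs exceeds the
        10^9 headroom of double precision even though the inversion itself
        is exact.
        """
        for res in fleet_fits.values():
            a = res.model.series.hours
            sub = res.viable.head(50)
            for r, kq in zip(sub["r"], sub["kq"]):
                cq = implied_catch(a, r, kq)
                assert (cq >= 0).all()
                step = np.array(
                    [simulate_schaefer(a[t], r, kq, [cq[t]])[-1] for t in range(len(cq))]
                )
                assert np.allclose(step, a[1:], rtol=1e-9)
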