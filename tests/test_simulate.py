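"""Trajectory simulation, elimination times, pathway fractions, and the
mass-balance ledger, including the simulator-vs-closed-form cross-check."""

import math

import numpy as np
import pytest

import pyrfate as pf
from pyrfate.errors import ContractError, NotEliminatedError, NothingAbsorbedError

from .conftest import constant_params

FOUR = ("sorption", "desorption", "biodegradation", "volatilization")


def zero_params(space):
    return constant_params(space, dict.fromkeys(FOUR, 0.0), [0, 0, 100.0, 0])


class TestSimulate:
    def test_single_step_water_decline(self, normal, space):
        """One hour in: water loses (volatilization + sorption) x 102.05,
        with no desorption inflow because sediment starts empty."""
        traj = pf.simulate(normal, horizon=1.0)
        expected = 102.05 * (1 - 0.0186 - 0.0284)
        assert traj.state("water")[1] == pytest.approx(expected, rel=1e-12)
        assert traj.state("volatilization")[1] == pytest.approx(102.05 * 0.0186, rel=1e-12)
        assert traj.state("sediment")[1] == pytest.approx(102.05 * 0.0284, rel=1e-12)

    def test_zero_rate_regime_constant(self, space):
        traj = pf.simulate(zero_params(space), horizon=50.0)
        np.testing.assert_array_equal(traj.values, np.tile([0, 0, 100.0, 0], (51, 1)))

    def test_wet_transients_exhausted_by_2000h(self, wet):
        traj = pf.simulate(wet, horizon=2000.0)
        assert traj.transient_mass()[-1] < 1e-6 * traj.initial_total

    def test_total_mass_conserved_along_trajectory(self, all_regimes):
        for params in all_regimes.values():
            traj = pf.simulate(params, horizon=500.0)
            totals = traj.values.sum(axis=1)
            np.testing.assert_allclose(totals, traj.initial_total, rtol=1e-9)

    def test_absorbing_states_non_decreasing(self, all_regimes):
        for params in all_regimes.values():
            traj = pf.simulate(params, horizon=500.0)
            for label in ("volatilization", "biodegradation"):
                assert np.all(np.diff(traj.state(label)) >= -1e-12)

    def test_qualitative_shape_water_falls_sediment_peaks(self, all_regimes):
        """Water declines from t=0 (no interior maximum); sediment fills
        then drains, so its maximum is interior."""
        for params in all_regimes.values():
            traj = pf.simulate_to_exhaustion(params)
            water, sed = traj.state("water"), traj.state("sediment")
            assert np.argmax(water) == 0
            assert np.all(np.diff(water) < 0)
            peak = int(np.argmax(sed))
            assert 0 < peak < len(sed) - 1

    def test_horizon_below_step_rejected(self, normal):
        with pytest.raises(ContractError):
            pf.simulate(normal, horizon=0.5, t0=1.0)

    def test_zero_order_interpretation_conserves_mass(self, normal):
        traj = pf.simulate(normal, horizon=300.0, interpretation="zero_order")
        np.testing.assert_allclose(
            traj.values.sum(axis=1), traj.initial_total, rtol=1e-9
        )
        assert np.all(traj.values >= 0)


class TestEliminationTime:
    def test_zero_rate_regime_never_eliminates(self, space):
        traj = pf.simulate(zero_params(space), horizon=100.0)
        with pytest.raises(NotEliminatedError):
            pf.elimination_time(traj, "water", 0.001)

    def test_normal_water_near_printed_value(self, normal):
        traj = pf.simulate_to_exhaustion(normal)
        t = pf.elimination_time(traj, "water")
        assert 110 < t < 190  # on the order of the reported 150 h

    def test_halflife_of_pure_decay_chain(self, space):
        """With only volatilization active at rate r the water content is
        102.05 (1-r)^t; the 50% crossing must land on the analytic step."""
        r = 0.0542
        params = constant_params(
            space,
            {"sorption": 0.0, "desorption": 0.0, "biodegradation": 0.0, "volatilization": r},
            [0, 0, 102.05, 0],
        )
        traj = pf.simulate(params, horizon=300.0)
        expected = math.floor(math.log(0.5) / math.log(1 - r)) + 1
        assert pf.elimination_time(traj, "water", 0.5) == expected

    def test_guards_against_early_dip(self, space):
        """Sediment starts below threshold but rises above it later; the
        elimination time must be after the refill, not hour 0."""
        traj = pf.simulate_to_exhaustion(pf.regime_parameters("normal"))
        t_sed = pf.elimination_time(traj, "sediment")
        sed = traj.state("sediment")
        assert sed[0] == 0.0  # below threshold at the start
        assert t_sed > traj.times[int(np.argmax(sed))]

    def test_threshold_domain(self, normal):
        traj = pf.simulate(normal, horizon=10.0)
        with pytest.raises(ContractError):
            pf.elimination_time(traj, "water", 0.0)

    def test_monotone_in_elimination_rates(self, all_regimes):
        """Doubling both terminal pathway rates never slows elimination."""
        for name, params in all_regimes.items():
            fast_scheds = dict(params.schedules)
            for pathway in ("volatilization", "biodegradation"):
                s = params.schedules[pathway]
                fast_scheds[pathway] = pf.PiecewiseRateSchedule(
                    segments=tuple(
                        pf.Segment(seg.start, seg.end, seg.rate * 2) for seg in s.segments
                    ),
                    source=s.source,
                    destination=s.destination,
                    units=s.units,
                )
            fast = pf.RegimeParameterSet(
                regime=name, space=params.space, schedules=fast_scheds, u0=params.u0
            )
            slow_traj = pf.simulate_to_exhaustion(params)
            fast_traj = pf.simulate_to_exhaustion(fast)
            for medium in ("water", "sediment"):
                assert pf.elimination_time(fast_traj, medium) <= pf.elimination_time(
                    slow_traj, medium
                )

    def test_seasonal_ordering_wet_fastest_dry_slowest(self, all_regimes):
        times = {}
        for name, params in all_regimes.items():
            traj = pf.simulate_to_exhaustion(params)
            times[name] = (
                pf.elimination_time(traj, "water"),
                pf.elimination_time(traj, "sediment"),
            )
        for medium in (0, 1):
            assert times["wet"][medium] < times["normal"][medium] < times["dry"][medium]


class TestPathwayFractions:
    def test_single_pathway_takes_all(self, space):
        params = constant_params(
            space,
            {"sorption": 0.0, "desorption": 0.0, "biodegradation": 0.0, "volatilization": 0.02},
            [0, 0, 100.0, 0],
        )
        fracs = pf.pathway_fractions(pf.simulate_to_exhaustion(params))
        assert fracs["volatilization"] == pytest.approx(100.0)
        assert fracs["biodegradation"] == pytest.approx(0.0)

    def test_nothing_absorbed_is_undefined(self, space):
        traj = pf.simulate(zero_params(space), horizon=10.0)
        with pytest.raises(NothingAbsorbedError):
            pf.pathway_fractions(traj)

    @pytest.mark.parametrize("seed", [11, 23, 47])
    def test_homogeneous_chain_matches_fundamental_matrix(self, seed, space):
        """For constant rates the iterated chain's ultimate split must agree
        with B = N R weighted by the initial vector, to 1e-6."""
        rng = np.random.default_rng(seed)
        rates = dict(zip(FOUR, rng.uniform(0.005, 0.1, size=4)))
        params = constant_params(space, rates, [0, 0, float(rng.uniform(50, 150)), 0])
        traj = pf.simulate_to_exhaustion(params, tol=1e-10)
        sim_fracs = pf.pathway_fractions(traj)

        P = pf.build_transition_matrix(params.schedules, space, t=0.0)
        Q, R = pf.canonical_decomposition(P)
        B = pf.absorption_probabilities(pf.fundamental_matrix(Q), R)
        u0_t = params.u0.values[list(space.transient_indices)]
        analytic = 100.0 * (u0_t @ B) / u0_t.sum()
        assert sim_fracs["volatilization"] == pytest.approx(analytic[0], abs=1e-6)
        assert sim_fracs["biodegradation"] == pytest.approx(analytic[1], abs=1e-6)

    def test_fractions_sum_to_100(self, all_regimes):
        for params in all_regimes.values():
            fracs = pf.pathway_fractions(pf.simulate_to_exhaustion(params))
            assert sum(fracs.values()) == pytest.approx(100.0, abs=1e-6)


class TestMassBalance:
    def test_residuals_negligible_on_valid_runs(self, all_regimes):
        for params in all_regimes.values():
            traj = pf.simulate(params, horizon=400.0)
            ledger = pf.mass_balance(traj)
            assert ledger["residual"].max() <= 1e-9
            assert not ledger["flagged"].any()

    def test_perturbed_trajectory_flagged_at_the_right_step(self, normal):
        traj = pf.simulate(normal, horizon=50.0)
        traj.values[20, 2] += 0.5  # inject a bookkeeping error at step 20
        ledger = pf.mass_balance(traj)
        flagged = ledger.loc[ledger["flagged"], "step"].tolist()
        assert 19 in flagged and 20 in flagged  # entering and leaving the bad point

    def test_first_step_sediment_inflow_is_sorption_outflow(self, normal):
        traj = pf.simulate(normal, horizon=5.0)
        ledger = pf.mass_balance(traj)
        expected = 102.05 * 0.0284
        assert ledger.loc[0, "inflow_sediment"] == pytest.approx(expected, rel=1e-12)
        assert ledger.loc[0, "outflow_sediment"] == 0.0


class TestEliminationReport:
    def test_report_fields_and_fraction_sum(self, wet):
        report, traj = pf.elimination_report(wet)
        assert report.regime == "wet"
        assert report.threshold == pf.DEFAULT_THRESHOLD
        assert report.volatilization_fraction + report.biodegradation_fraction == pytest.approx(
            100.0, abs=1e-6
        )
        assert 0 < report.water_time < report.sediment_time < traj.horizon
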