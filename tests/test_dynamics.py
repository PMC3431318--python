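"""Deterministic recursion, stochastic sampling and ensembles."""

import numpy as np
import pytest

import saacage as sc
from saacage.dynamics import PopulationCollapseError
from saacage.genetics import ALL_GENOTYPES


def neutral_params(**kwargs):
    return sc.ModelParams(
        mating=sc.MatingParams(w_photo=1.0),
        female_fecundity=(1.0, 1.0, 1.0),
        **kwargs,
    )


class TestDeterministicStep:
    def test_neutral_conservation_over_1000_generations(self):
        # with equal fecundities and no mating advantage the allele
        # frequency is exactly invariant
        traj = sc.run_deterministic(neutral_params(), sc.state_at_hw(0.3), 1000)
        assert np.abs(traj.freqs - traj.freqs[0]).max() <= 1e-14

    def test_female_costs_alone_drive_decline(self):
        # no male advantage, default female fecundity costs: frequency
        # strictly decreases every generation
        params = sc.ModelParams(mating=sc.MatingParams(w_photo=1.0))
        traj = sc.run_deterministic(params, sc.state_at_hw(0.03), 50)
        assert (np.diff(traj.freqs) < 0).all()

    def test_fixation_is_absorbing(self):
        params = sc.ModelParams(mating=sc.MatingParams(w_photo=2.0))
        state = sc.state_at_hw(1.0)
        nxt = sc.deterministic_step(state, params)
        assert sc.x_allele_frequency(nxt) == pytest.approx(1.0, abs=0)
        assert nxt.generation == state.generation + 1

    def test_zero_fecundity_collapses(self):
        params = sc.ModelParams(
            mating=sc.MatingParams(w_photo=2.0),
            female_fecundity=(0.0, 0.0, 0.0),
        )
        with pytest.raises(PopulationCollapseError):
            sc.deterministic_step(sc.state_at_hw(0.5), params)


class TestTrajectoriesAndEquilibria:
    def test_neutral_trajectory_is_flat_and_converged(self):
        traj = sc.run_deterministic(neutral_params(), sc.state_at_hw(0.2), 100)
        assert traj.converged
        assert traj.freqs.min() == pytest.approx(traj.freqs.max(), abs=1e-14)

    def test_calibrated_invasion_rises_to_plateau(self, calibrated_params, p1_founding):
        # the males-only founding state oscillates for a few generations
        # while genotypes equilibrate; thereafter the rise is monotone
        traj = sc.run_deterministic(calibrated_params, p1_founding, 1000)
        assert (np.diff(traj.freqs[8:]) > -1e-15).all()
        assert traj.freqs[-1] > traj.freqs[0]
        assert traj.freqs[-1] == pytest.approx(0.126, abs=1e-3)

    def test_equilibrium_reached_from_both_sides(self, calibrated_params):
        lo = sc.find_equilibrium(calibrated_params, sc.state_at_hw(0.03))
        hi = sc.find_equilibrium(calibrated_params, sc.state_at_hw(0.85))
        assert abs(lo.equilibrium - hi.equilibrium) < 1e-3
        assert lo.freq_at_700 == pytest.approx(lo.equilibrium, abs=1e-3)

    def test_no_male_advantage_means_extinction(self):
        params = sc.ModelParams(mating=sc.MatingParams(w_photo=1.0))
        res = sc.find_equilibrium(params, sc.state_at_hw(0.03))
        assert res.equilibrium < 1e-10

    def test_neutral_equilibrium_is_the_founding_frequency(self):
        res = sc.find_equilibrium(neutral_params(max_generations=200), sc.state_at_hw(0.37))
        assert res.equilibrium == pytest.approx(0.37, abs=1e-12)

    def test_protected_polymorphism_with_recessive_cost(self):
        # fully recessive female cost: a modest male advantage makes the
        # allele increase when rare AND decrease when common
        # w_eff = 1.5 via w_photo: w_eff = 0.402 w + 0.598 at 12:12
        params = sc.ModelParams(
            mating=sc.MatingParams(w_photo=(1.5 - 0.598) / 0.402),
            female_fecundity=(0.388, 1.0, 1.0),
        )
        for q0, sign in ((0.01, 1), (0.9, -1)):
            state = sc.state_at_hw(q0)
            nxt = sc.deterministic_step(state, params)
            delta = sc.x_allele_frequency(nxt) - sc.x_allele_frequency(state)
            assert np.sign(delta) == sign

    def test_equilibrium_monotone_in_w_photo(self):
        eqs = []
        for w in (1.6, 2.0, 2.5, 3.0, 4.0):
            params = sc.ModelParams(mating=sc.MatingParams(w_photo=w))
            eqs.append(sc.find_equilibrium(params, sc.state_at_hw(0.1)).equilibrium)
        assert all(a <= b + 1e-12 for a, b in zip(eqs, eqs[1:]))

    def test_permanent_dark_drives_loss_from_any_start(self, calibrated_w_photo):
        params = sc.ModelParams(
            mating=sc.MatingParams(w_photo=calibrated_w_photo, light_hours=0.0),
            max_generations=500,
        )
        for q0 in (0.05, 0.5, 0.9):
            res = sc.find_equilibrium(params, sc.state_at_hw(q0))
            assert res.equilibrium < 1e-4


class TestCalibration:
    def test_calibration_hits_target_equilibrium(self, calibrated_params, calibrated_w_photo):
        res = sc.find_equilibrium(calibrated_params, sc.state_at_hw(0.03))
        assert res.equilibrium == pytest.approx(0.126, abs=1e-6)
        assert 1.2 < calibrated_w_photo < 4.0

    def test_unbracketed_target_rejected(self):
        params = sc.ModelParams(mating=sc.MatingParams(w_photo=2.0))
        with pytest.raises(ValueError):
            sc.calibrate_w_photo(0.9, params, sc.state_at_hw(0.03), bracket=(1.1, 1.2))


class TestStochastic:
    def test_sampled_proportions_match_pool_expectation(self, calibrated_params, p1_founding, rng):
        # Monte Carlo mean of the drawn class counts vs the analytic
        # multinomial mean, within 3 standard errors per class
        n_draws, n = 10_000, calibrated_params.sample_size
        from saacage.dynamics import _offspring_pool

        pool = _offspring_pool(p1_founding, calibrated_params)
        probs = pool / pool.sum()
        draws = np.array(
            [
                [s.counts[g] for g in ALL_GENOTYPES]
                for s, ok in (
                    sc.stochastic_step(p1_founding, calibrated_params, rng)
                    for _ in range(n_draws)
                )
                if ok
            ]
        )
        mean = draws.mean(axis=0)
        se = np.sqrt(n * probs * (1 - probs) / len(draws))
        assert (np.abs(mean - n * probs) <= 3 * se + 1e-9).all()

    def test_huge_sample_approaches_deterministic(self, calibrated_params, p1_founding, rng):
        det = sc.run_deterministic(calibrated_params, p1_founding, 23)
        big = sc.ModelParams(
            mating=calibrated_params.mating, sample_size=10**6
        )
        stoch = sc.run_stochastic(big, p1_founding, 23, rng)
        assert np.abs(stoch.freqs - det.freqs).max() < 1e-2

    def test_fixed_seed_reproduces_trajectory(self, calibrated_params, p1_founding):
        a = sc.run_stochastic(calibrated_params, p1_founding, 15, np.random.default_rng(7))
        b = sc.run_stochastic(calibrated_params, p1_founding, 15, np.random.default_rng(7))
        assert (a.freqs == b.freqs).all()

    def test_exact_pool_mode_runs_and_agrees_in_mean(self, calibrated_params, p1_founding, rng):
        params = sc.ModelParams(
            mating=calibrated_params.mating, exact_pool=True
        )
        ens = sc.run_ensemble(params, p1_founding, 10, seed=3)
        det = sc.run_deterministic(calibrated_params, p1_founding, 10)
        gap = np.abs(ens.mean - det.freqs)
        assert (gap <= 3 * ens.sd / np.sqrt(ens.n_runs) + 1e-12).all()


class TestEnsemble:
    def test_summary_ordering(self, calibrated_params, p1_founding):
        ens = sc.run_ensemble(calibrated_params, p1_founding, 12, seed=11)
        assert (ens.lo95 <= ens.mean + 1e-12).all()
        assert (ens.mean <= ens.hi95 + 1e-12).all()
        assert ens.freqs.shape == (100, 13)

    def test_master_seed_reproducibility(self, calibrated_params, p1_founding):
        a = sc.run_ensemble(calibrated_params, p1_founding, 8, seed=5)
        b = sc.run_ensemble(calibrated_params, p1_founding, 8, seed=5)
        c = sc.run_ensemble(calibrated_params, p1_founding, 8, seed=6)
        assert (a.freqs == b.freqs).all()
        assert (a.freqs != c.freqs).any()

    def test_huge_sample_collapses_band_width(self, calibrated_params, p1_founding):
        params = sc.ModelParams(
            mating=calibrated_params.mating, sample_size=10**6, n_runs=10
        )
        ens = sc.run_ensemble(params, p1_founding, 5, seed=2)
        assert (ens.hi95 - ens.lo95 < 1e-2).all()


class TestPoolSize:
    def test_all_control_pool_is_census_times_brood(self):
        state = sc.state_at_hw(0.0)
        params = sc.ModelParams(mating=sc.MatingParams(w_photo=2.0))
        assert sc.expected_pool_size(state, params) == pytest.approx(3000.0)

    def test_default_pool_in_protocol_range(self, calibrated_params):
        pool = sc.expected_pool_size(sc.state_at_hw(0.03), calibrated_params)
        assert 2500 <= pool <= 5400

    def test_no_females_no_pool(self):
        state = sc.PopulationState(
            male_freqs=np.array([0.5, 0.5]),
            female_freqs=np.array([0.0, 0.0, 1.0]),
            n_females=0,
        )
        params = sc.ModelParams(mating=sc.MatingParams(w_photo=2.0))
        assert sc.expected_pool_size(state, params) == 0.0
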