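"""Tests for model fitting: closed-form oracles, recovery, pooling."""

import numpy as np
import pandas as pd
import pytest

from catchain.core_model import (
    LearningModel,
    StationaryModel,
    chance_vector,
    expected_progress,
)
from catchain.inference import (
    GROUP_LABEL,
    _paule_mandel,
    dataset_loglik,
    fit_hierarchical,
    fit_learning,
    fit_stationary,
    summarize_progress,
)
from catchain.task_sim import (
    LearningCohortSpec,
    simulate_cohort,
    simulate_human,
    simulate_stationary_phase,
)


def conditional_frequency(trials, item):
    """Closed-form ML oracle: correct-at-position / reached-position."""
    reached = trials["progress"] >= item - 1
    if reached.sum() == 0:
        return np.nan
    return (trials.loc[reached, "progress"] >= item).mean()


class TestFitStationary:
    def test_mle_equals_conditional_frequency(self, plateau_trials):
        fit = fit_stationary(plateau_trials, mode="mle")
        est = fit.estimates
        for item in range(1, 5):
            p_hat = est[(est["item"] == item)
                        & (est["parameter"] == "p")]["estimate"].iloc[0]
            assert p_hat == pytest.approx(
                conditional_frequency(plateau_trials, item), abs=1e-8)

    def test_recovers_generating_probabilities(self, plateau_trials,
                                               stationary_model):
        fit = fit_stationary(plateau_trials, mode="mle")
        est = fit.estimates
        truth = stationary_model.choice_probs().as_array()
        for item in range(1, 5):
            reached = (plateau_trials["progress"] >= item - 1).sum()
            p = truth[item - 1]
            se = np.sqrt(p * (1 - p) / reached)
            p_hat = est[(est["item"] == item)
                        & (est["parameter"] == "p")]["estimate"].iloc[0]
            assert abs(p_hat - p) < 3 * se

    def test_all_rewarded_flags_boundary(self):
        model = StationaryModel((30.0,) * 4)
        tr = simulate_stationary_phase(model, 200, seed=1)
        assert (tr["progress"] == 4).all()
        fit = fit_stationary(tr)
        est = fit.estimates[fit.estimates["parameter"] == "p"]
        assert (est["flag"] == "boundary").all()
        assert (est["estimate"] > 0.999).all()

    def test_bayes_agrees_with_mle_at_large_n(self, stationary_model):
        tr = simulate_stationary_phase(stationary_model, 10_000, seed=13)
        mle = fit_stationary(tr, mode="mle")
        bay = fit_stationary(tr, mode="bayes", seed=13)
        p_mle = mle.estimates[mle.estimates["parameter"] == "p"]
        p_bay = bay.estimates[bay.estimates["parameter"] == "p"]
        diff = np.abs(p_mle["estimate"].to_numpy()
                      - p_bay["estimate"].to_numpy())
        assert diff.max() < 0.02

    def test_bayes_seed_reproducible(self, plateau_trials):
        a = fit_stationary(plateau_trials, mode="bayes", seed=5)
        b = fit_stationary(plateau_trials, mode="bayes", seed=5)
        np.testing.assert_array_equal(a.draws[("m0", 1)]["m"],
                                      b.draws[("m0", 1)]["m"])
        c = fit_stationary(plateau_trials, mode="bayes", seed=6)
        # different seeds: summaries agree within Monte-Carlo error
        pa = a.estimates[a.estimates["parameter"] == "p"]["estimate"]
        pc = c.estimates[c.estimates["parameter"] == "p"]["estimate"]
        assert np.abs(pa.to_numpy() - pc.to_numpy()).max() < 0.02

    def test_fitted_beats_chance_loglik(self, plateau_trials):
        fit = fit_stationary(plateau_trials)
        model = fit.models["m0"]
        ll_fit = dataset_loglik(
            plateau_trials,
            lambda t: np.tile(model.choice_probs().as_array(), (len(t), 1)))
        ll_chance = dataset_loglik(
            plateau_trials,
            lambda t: np.tile(chance_vector().as_array(), (len(t), 1)))
        assert ll_fit >= ll_chance

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fit_stationary(pd.DataFrame(columns=["subject_id", "progress",
                                                 "t"]))


class TestFitLearning:
    def test_nonlearner_fits_to_floor(self):
        model = LearningModel(s=(1e-6,) * 3, m=(-30.0,) * 3)
        frames = [simulate_human(model, "photographic", seed=s,
                                 subject_id=f"h{s:02d}") for s in range(10)]
        tr = pd.concat(frames, ignore_index=True)
        fit = fit_learning(tr, mode="mle")
        t_grid = np.arange(120)
        ep0 = []
        for sid in fit.subject_ids():
            p = fit.choice_prob_matrix(sid, t_grid)
            # fitted curves stay close to the floors throughout
            ep0.append(expected_progress(np.clip(p[0], 1e-9, 1)))
        chance_ep = expected_progress(chance_vector())
        assert abs(np.mean(ep0) - chance_ep) < 0.1

    def test_steep_learner_reaches_near_perfect_reward(self):
        model = LearningModel(s=(0.4,) * 3, m=(6.0, 5.0, 4.0),
                              p4_const=0.999)
        tr = simulate_human(model, "photographic", seed=3)
        fit = fit_learning(tr, mode="mle")
        p_end = fit.choice_prob_matrix("h0", [119.0])[0]
        assert np.prod(p_end) > 0.95

    def test_too_few_trials_raises(self):
        tr = simulate_human(LearningModel(s=(0.1,) * 3, m=(4, 2.5, 0.5)),
                            seed=1).head(2)
        with pytest.raises(ValueError, match="parameters"):
            fit_learning(tr)

    def test_free_floors_mode_runs(self, small_human_cohort):
        trials, _ = small_human_cohort
        one = trials[trials["subject_id"] == "s000"]
        fit = fit_learning(one, mode="mle", floors="free")
        est = fit.estimates
        f_rows = est[est["parameter"] == "f"]
        assert len(f_rows) == 3
        assert ((f_rows["estimate"] >= 0) & (f_rows["estimate"] < 1)).all()

    def test_curve_recovery_small_cohort(self, small_human_cohort):
        trials, truth = small_human_cohort
        fit = fit_learning(trials, mode="mle")
        t_grid = np.arange(120.0)
        maes = []
        for sid in fit.subject_ids():
            g = truth[truth["subject_id"] == sid]
            look = {(int(r.item), r.parameter): r.value
                    for r in g.itertuples()}
            true_model = LearningModel(
                s=tuple(look[(i, "s")] for i in (1, 2, 3)),
                m=tuple(look[(i, "m")] for i in (1, 2, 3)),
                v=tuple(look[(i, "v")] for i in (1, 2, 3)))
            mae = np.abs(true_model.prob_matrix(t_grid)[:, :3]
                         - fit.choice_prob_matrix(sid, t_grid)[:, :3]).mean()
            maes.append(mae)
        assert np.mean(maes) < 0.07

    def test_bayes_mode_runs_and_is_seeded(self, small_human_cohort):
        trials, _ = small_human_cohort
        one = trials[trials["subject_id"] == "s000"]
        a = fit_learning(one, mode="bayes", seed=3, n_steps=400, n_walkers=8)
        b = fit_learning(one, mode="bayes", seed=3, n_steps=400, n_walkers=8)
        np.testing.assert_array_equal(a.draws[("s000", 1)]["s"],
                                      b.draws[("s000", 1)]["s"])
        est = a.estimates
        assert (est["lo95"] <= est["estimate"]).all()
        assert (est["estimate"] <= est["hi95"]).all()


class TestHierarchical:
    def test_identical_subjects_concentrate_group_sd(self):
        model = StationaryModel.from_probs([0.8, 0.85, 0.9, 0.99])
        frames = [simulate_stationary_phase(model, 800, seed=s,
                                            subject_id=f"m{s}")
                  for s in range(6)]
        tr = pd.concat(frames, ignore_index=True)
        fit = fit_hierarchical(tr, "stationary")
        g = fit.estimates[(fit.estimates["subject_id"] == GROUP_LABEL)
                          & (fit.estimates["parameter"] == "m")]
        raw = fit_stationary(tr)
        m_rows = raw.estimates[raw.estimates["parameter"] == "m"]
        for item in range(1, 5):
            tau = g[g["item"] == item]["tau"].fillna(0).iloc[0]
            noise = m_rows[m_rows["item"] == item]["se"].mean()
            # heterogeneity not detectably above within-subject noise
            assert tau < noise

    def test_group_mean_between_bimodal_modes(self):
        spec = LearningCohortSpec(p_learner=0.5)
        trials, _ = simulate_cohort(14, spec, seed=21)
        fit = fit_hierarchical(trials, "learning")
        t_end = np.array([119.0])
        finals = np.array([fit.choice_prob_matrix(s, t_end)[0, 0]
                           for s in fit.subject_ids()])
        low, high = finals[finals < 0.5], finals[finals > 0.8]
        assert len(low) >= 3 and len(high) >= 3
        group_p1 = finals.mean()
        assert low.max() < group_p1 < high.min()

    def test_single_subject_falls_back_with_warning(self, plateau_trials):
        with pytest.warns(UserWarning, match="single subject"):
            fit = fit_hierarchical(plateau_trials, "stationary")
        assert GROUP_LABEL not in set(fit.estimates["subject_id"])

    def test_shrinkage_moves_toward_group_mean(self, small_monkey_cohort):
        trials, _ = small_monkey_cohort
        pooled = fit_hierarchical(trials, "stationary")
        raw = fit_stationary(trials)
        for item in (1, 2):
            g = pooled.estimates
            mu = g[(g["subject_id"] == GROUP_LABEL) & (g["item"] == item)
                   & (g["parameter"] == "m")]["estimate"].iloc[0]
            for sid in raw.estimates["subject_id"].unique():
                sel = lambda df: df[(df["subject_id"] == sid)
                                    & (df["item"] == item)
                                    & (df["parameter"] == "m")][
                    "estimate"].iloc[0]
                raw_m, pool_m = sel(raw.estimates), sel(pooled.estimates)
                # shrunken estimate lies between the raw one and the mean
                assert (min(raw_m, mu) - 1e-9 <= pool_m
                        <= max(raw_m, mu) + 1e-9)

    def test_interval_coverage_of_group_mean(self):
        """Group 95% intervals cover the generating group mean in most
        replicate cohorts (stationary model, logit scale)."""
        m_true = StationaryModel.from_probs([0.8, 0.85, 0.9, 0.97]).m
        hits, total = 0, 0
        for rep in range(12):
            rng = np.random.default_rng(300 + rep)
            frames = []
            for j in range(6):
                m_j = np.array(m_true) + rng.normal(0, 0.3, 4)
                frames.append(simulate_stationary_phase(
                    StationaryModel(tuple(m_j)), 400,
                    seed=1000 * rep + j, subject_id=f"m{j}"))
            fit = fit_hierarchical(pd.concat(frames, ignore_index=True),
                                   "stationary")
            g = fit.estimates[
                (fit.estimates["subject_id"] == GROUP_LABEL)
                & (fit.estimates["parameter"] == "m")]
            for item in range(1, 5):
                row = g[g["item"] == item].iloc[0]
                hits += row["lo95"] <= m_true[item - 1] <= row["hi95"]
                total += 1
        assert hits / total >= 0.85


class TestPauleMandel:
    def test_homogeneous_reduces_to_fixed_effect(self):
        theta = np.array([1.0, 1.02, 0.98, 1.01])
        se = np.full(4, 0.2)
        mu, se_mu, tau2 = _paule_mandel(theta, se)
        assert mu == pytest.approx(theta.mean(), abs=1e-9)
        assert tau2 == pytest.approx(0.0, abs=1e-6)
        assert se_mu == pytest.approx(0.1, abs=1e-3)

    def test_heterogeneous_tau_positive(self):
        rng = np.random.default_rng(4)
        theta = rng.normal(0, 1.0, 30)
        se = np.full(30, 0.1)
        mu, se_mu, tau2 = _paule_mandel(theta, se)
        assert tau2 > 0.5
        assert abs(mu - theta.mean()) < 0.05


class TestSummarizeProgress:
    def test_chance_fit_at_t0(self):
        model = LearningModel(s=(1e-6,) * 3, m=(-30.0,) * 3)
        frames = [simulate_human(model, "photographic", seed=s,
                                 subject_id=f"h{s:02d}") for s in range(8)]
        tr = pd.concat(frames, ignore_index=True)
        fit = fit_learning(tr, mode="mle")
        summ = summarize_progress(fit, [0.0], seed=1)
        # cohort-average expected progress at onset sits at the chance value
        assert summ["expected_progress"].mean() == pytest.approx(
            0.4167, abs=0.06)

    def test_identity_with_core_model(self, small_human_cohort):
        trials, _ = small_human_cohort
        fit = fit_learning(trials[trials["subject_id"] == "s001"])
        t_grid = np.array([0.0, 60.0, 119.0])
        summ = summarize_progress(fit, t_grid, seed=2)
        p = fit.choice_prob_matrix("s001", t_grid)
        expect = np.cumprod(np.clip(p, 1e-12, 1), axis=1).sum(axis=1)
        np.testing.assert_allclose(summ["expected_progress"].to_numpy(),
                                   expect, atol=1e-9)

    def test_perfect_fit_is_four(self):
        model = StationaryModel((30.0,) * 4)
        tr = simulate_stationary_phase(model, 300, seed=2)
        fit = fit_stationary(tr)
        summ = summarize_progress(fit, [0.0, 10.0], seed=3)
        assert (summ["expected_progress"] > 3.95).all()

    def test_monotone_for_learners(self, small_human_cohort):
        trials, _ = small_human_cohort
        fit = fit_learning(trials[trials["subject_id"] == "s000"])
        t_grid = np.linspace(0, 119, 25)
        summ = summarize_progress(fit, t_grid, seed=4)
        ep = summ["expected_progress"].to_numpy()
        assert np.all(np.diff(ep) >= -1e-9)


def test_dataset_loglik_matches_trial_loglik_sum(plateau_trials,
                                                 stationary_model):
    from catchain.core_model import trial_loglik

    p = stationary_model.choice_probs().as_array()
    direct = sum(trial_loglik(int(k), p)
                 for k in plateau_trials["progress"])
    vect = dataset_loglik(plateau_trials,
                          lambda t: np.tile(p, (len(t), 1)))
    assert vect == pytest.approx(direct, rel=1e-10)
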