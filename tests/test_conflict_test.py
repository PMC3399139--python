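import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from islandclock.calibration import CalibrationPrior
from islandclock.conflict_test import (
    CONCOMITANT,
    POST_ISLAND,
    PRE_ISLAND,
    HardBoundReferenceError,
    classify_node,
    compare_schemes,
    hpd_interval,
    kl_divergence,
)
from islandclock.dating_engine import PosteriorTrace


def normal_normal_kl(m1, s1, m2, s2):
    return math.log(s2 / s1) + (s1**2 + (m1 - m2) ** 2) / (2 * s2**2) - 0.5


class TestHPD:
    def test_standard_normal_interval(self):
        rng = np.random.default_rng(0)
        lo, hi = hpd_interval(rng.standard_normal(10_000))
        assert abs(lo + 1.96) < 0.08
        assert abs(hi - 1.96) < 0.08

    def test_uniform_width(self):
        rng = np.random.default_rng(1)
        lo, hi = hpd_interval(rng.random(10_000))
        assert 0.93 <= hi - lo <= 0.97

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.full(500, 2.0))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(50, dtype=float))

    def test_skewed_distribution_shorter_than_quantile_interval(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0.0, 1.0, size=20_000)
        lo, hi = hpd_interval(x)
        q = np.quantile(x, [0.025, 0.975])
        assert hi - lo < q[1] - q[0]


class TestKLDivergence:
    PRIOR = CalibrationPrior("normal", mean=2.6, sd=1.1)

    def test_samples_from_prior_give_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2.6, 1.1, size=10_000)
        assert kl_divergence(x, self.PRIOR) <= 0.05

    def test_matches_normal_normal_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1.1, 0.3, size=10_000)
        expected = normal_normal_kl(1.1, 0.3, 2.6, 1.1)
        assert abs(kl_divergence(x, self.PRIOR) - expected) < 0.1

    def test_narrowing_posterior_increases_divergence(self):
        rng = np.random.default_rng(5)
        estimates = []
        for sd in (0.9, 0.45, 0.15):
            x = rng.normal(1.1, sd, size=10_000)
            estimates.append(kl_divergence(x, self.PRIOR))
        assert estimates[0] < estimates[1] < estimates[2]

    def test_estimator_consistency_with_sample_size(self):
        expected = normal_normal_kl(1.1, 0.3, 2.6, 1.1)
        errs = []
        for n in (1_000, 10_000):
            errors = []
            for seed in range(5):
                x = np.random.default_rng(seed).normal(1.1, 0.3, size=n)
                errors.append(abs(kl_divergence(x, self.PRIOR) - expected))
            errs.append(np.mean(errors))
        assert errs[1] < errs[0]

    def test_hard_uniform_reference_with_outliers_rejected(self):
        prior = CalibrationPrior("hard_uniform", lower=2.59, upper=2.61)
        x = np.random.default_rng(6).normal(2.6, 0.05, size=2_000)
        with pytest.raises(HardBoundReferenceError, match="normal"):
            kl_divergence(x, prior)

    def test_flipped_direction_also_near_zero_on_prior_samples(self):
        x = np.random.default_rng(7).normal(2.6, 1.1, size=10_000)
        assert kl_divergence(x, self.PRIOR, direction="prior_from_posterior") <= 0.1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.random.default_rng(8).random(500), self.PRIOR)


class TestClassification:
    @pytest.mark.parametrize("hpd,island_age,expected", [
        ((0.6, 1.1), 0.5, PRE_ISLAND),      # divergence older than the island
        ((0.0, 2.7), 4.7, POST_ISLAND),     # divergence younger than the island
        ((2.0, 3.0), 2.6, CONCOMITANT),
        ((2.0, 3.0), 2.0, CONCOMITANT),     # tie on an endpoint: not rejected
        ((2.0, 3.0), 3.0, CONCOMITANT),
    ])
    def test_examples(self, hpd, island_age, expected):
        assert classify_node(hpd, island_age) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        lo=st.floats(0.0, 5.0), width=st.floats(0.01, 5.0),
        ages=st.lists(st.floats(0.0, 12.0), min_size=2, max_size=8),
    )
    def test_monotone_in_island_age(self, lo, width, ages):
        order = {PRE_ISLAND: 0, CONCOMITANT: 1, POST_ISLAND: 2}
        hpd = (lo, lo + width)
        labels = [order[classify_node(hpd, a)] for a in sorted(ages)]
        assert labels == sorted(labels)


def _trace(values: dict[str, np.ndarray]) -> PosteriorTrace:
    return PosteriorTrace(
        pd.DataFrame(values),
        {c: (c,) for c in values if c.startswith("t_")},
    )


class TestCompareSchemes:
    def test_identical_traces_zero_difference(self):
        rng = np.random.default_rng(9)
        tr = _trace({"t_4": rng.random(1000), "t_5": rng.random(1000)})
        diffs, (lo, hi) = compare_schemes(tr, tr)
        assert all(d == 0.0 for d in diffs.values())
        assert (lo, hi) == (0.0, 0.0)

    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(10)
        a = rng.random(1000)
        b = rng.random(1000)
        tr_n = _trace({"t_4": a, "t_5": b})
        tr_p = _trace({"t_4": a + 0.5, "t_5": b})
        diffs, (lo, hi) = compare_schemes(tr_n, tr_p)
        assert diffs["t_4"] == pytest.approx(0.5)
        assert diffs["t_5"] == pytest.approx(0.0)
        assert (lo, hi) == (pytest.approx(0.0), pytest.approx(0.5))

    def test_schema_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        tr_n = _trace({"t_4": rng.random(1000)})
        tr_p = _trace({"t_9": rng.random(1000)})
        with pytest.raises(ValueError):
            compare_schemes(tr_n, tr_p)

    def test_schemes_diverge_toward_truth_on_offset_scenario(self):
        """With the true divergence well above the island age, the soft and
        punctual posteriors separate by more than the Monte-Carlo error, and
        the soft-scheme mean sits on the side of the truth."""
        from islandclock.dating_engine import MCMCSettings, mcmc_run
        from islandclock.mcmc_diagnostics import ess
        from islandclock.pipeline import _scheme_tables
        from islandclock.substitution import SubstitutionModel
        from islandclock.synthetic_data import (
            SimulationScenario,
            scenario_calibrations,
            simulate_scenario,
        )

        scenario = SimulationScenario(
            n_taxa=6, root_age=5.0, island_age=1.0, divergence_offset=1.0,
            clock_mean_rate=0.02, n_sites=1000, seed=17,
        )
        truth, aln = simulate_scenario(scenario)
        schemes = _scheme_tables(scenario_calibrations(truth)[0])
        traces = {}
        for name in ("normal", "punctual"):
            traces[name] = mcmc_run(
                aln, truth.true_tree, schemes[name], "strict",
                MCMCSettings(n_samples=400, thin=3, seed=17,
                             estimate_substitution_model=False),
                model=SubstitutionModel(gamma_shape=1.0),
            )
        col = f"t_{truth.focal_node}"
        diffs, _ = compare_schemes(traces["normal"], traces["punctual"])
        x = traces["normal"].samples[col].to_numpy()
        mc_se = math.sqrt(x.var() / ess(x))
        assert diffs[col] > mc_se
        # punctual pins the node at the island age; the soft scheme moves it
        # toward the true (older) age
        m_norm = traces["normal"].samples[col].mean()
        m_punc = traces["punctual"].samples[col].mean()
        true_age = truth.true_tree.ages[truth.focal_node]
        assert abs(m_norm - true_age) < abs(m_punc - true_age)


class TestAssessAll:
    def test_report_invariant_to_calibration_order(self, quartet_tree):
        from islandclock.calibration import CalibrationEntry, CalibrationTable
        from islandclock.conflict_test import assess_all
        from islandclock.dating_engine import MCMCSettings, mcmc_run

        entries = (
            CalibrationEntry("a", "d", "Oahu", 2.6,
                             CalibrationPrior("normal", mean=2.6, sd=1.1)),
            CalibrationEntry("a", "b", "Hawaii", 0.5,
                             CalibrationPrior("normal", mean=0.5, sd=0.2)),
        )
        scheme = CalibrationTable(entries)
        reversed_scheme = CalibrationTable(entries[::-1])
        tr = mcmc_run(None, quartet_tree, scheme, "strict",
                      MCMCSettings(n_samples=1500, thin=2, seed=13))
        _, rep1, _ = assess_all({"normal": tr}, scheme, quartet_tree, scheme)
        _, rep2, _ = assess_all({"normal": tr}, reversed_scheme, quartet_tree,
                                reversed_scheme)
        assert rep1.equals(rep2)
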