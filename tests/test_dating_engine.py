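import math

import numpy as np
import pytest
from scipy.stats import chisquare

from islandclock.calibration import (
    CalibrationEntry,
    CalibrationPrior,
    CalibrationTable,
)
from islandclock.dating_engine import (
    CalibrationResolutionError,
    GammaRootPrior,
    MCMCSettings,
    PosteriorTrace,
    mcmc_run,
    node_age_prior_logdensity,
    resolve_calibrations,
    run_replicates,
)
from islandclock.likelihood import pruning_loglik
from islandclock.substitution import SubstitutionModel
from islandclock.synthetic_data import (
    simulate_alignment,
    simulate_rates,
    simulate_time_tree,
)

JC4 = SubstitutionModel(gamma_shape=1.0, n_categories=4)


def _quartet_scheme(prior: CalibrationPrior) -> CalibrationTable:
    return CalibrationTable((CalibrationEntry("a", "d", "island", 2.6, prior),))


class TestAgePriorDensity:
    def test_hard_bound_violation_is_minus_inf(self, quartet_tree_with_ages):
        tree = quartet_tree_with_ages
        cal = {tree.root: CalibrationPrior("hard_uniform", lower=2.59, upper=2.61)}
        ages = tree.ages.copy()
        ages[tree.root] = 2.60
        assert np.isfinite(node_age_prior_logdensity(tree, ages, cal))
        ages[tree.root] = 2.62
        assert node_age_prior_logdensity(tree, ages, cal) == -math.inf

    def test_normal_calibration_unimodal_at_mean(self, quartet_tree_with_ages):
        tree = quartet_tree_with_ages
        cal = {tree.root: CalibrationPrior("normal", mean=2.6, sd=0.3)}
        def at(root_age):
            ages = tree.ages.copy()
            ages[tree.root] = root_age
            return node_age_prior_logdensity(tree, ages, cal)
        assert at(2.6) > at(2.6 + 0.6)
        assert at(2.6) > at(2.6 - 0.6)

    def test_ordering_violation_is_minus_inf(self, quartet_tree_with_ages):
        tree = quartet_tree_with_ages
        cal = {tree.root: CalibrationPrior("normal", mean=2.6, sd=1.1)}
        ages = tree.ages.copy()
        ages[tree.root] = 0.5  # below its children
        assert node_age_prior_logdensity(tree, ages, cal) == -math.inf

    def test_uncalibrated_root_needs_prior(self, quartet_tree_with_ages):
        tree = quartet_tree_with_ages
        cherry = next(i for i in tree.internal_nodes if i != tree.root)
        cal = {cherry: CalibrationPrior("normal", mean=1.0, sd=0.4)}
        with pytest.raises(ValueError, match="root"):
            node_age_prior_logdensity(tree, tree.ages, cal, root_prior=None)
        lp = node_age_prior_logdensity(
            tree, tree.ages, cal, root_prior=GammaRootPrior(2.0, 2.0)
        )
        assert np.isfinite(lp)


class TestIdentifiability:
    def test_tree_scale_preserves_likelihood_under_co_scaled_rate(self):
        """Only rate x time is data-constrained: scaling all ages by c and the
        rate by 1/c leaves the exact pruning likelihood unchanged."""
        tree = simulate_time_tree(6, 5.0, seed=0)
        rates = simulate_rates(tree, "strict", 0.01, seed=0)
        aln = simulate_alignment(tree, rates, JC4, 500, seed=0)
        ll = pruning_loglik(aln, tree, 0.01, JC4)
        c = 3.7
        scaled = tree.with_ages(tree.ages * c)
        ll_scaled = pruning_loglik(aln, scaled, 0.01 / c, JC4)
        assert ll_scaled == pytest.approx(ll, abs=1e-8)


class TestMCMCContracts:
    def test_same_seed_bit_identical_trace(self, quartet_tree):
        aln = _tiny_alignment(quartet_tree, seed=1)
        scheme = _quartet_scheme(CalibrationPrior("normal", mean=2.6, sd=1.1))
        settings = MCMCSettings(n_samples=40, thin=2, seed=9)
        tr1 = mcmc_run(aln, quartet_tree, scheme, "strict", settings, model=JC4)
        tr2 = mcmc_run(aln, quartet_tree, scheme, "strict", settings, model=JC4)
        assert tr1.samples.equals(tr2.samples)

    def test_replicates_differ_but_share_schema(self, quartet_tree):
        aln = _tiny_alignment(quartet_tree, seed=2)
        scheme = _quartet_scheme(CalibrationPrior("normal", mean=2.6, sd=1.1))
        settings = MCMCSettings(n_samples=40, thin=2, seed=9, n_replicates=2)
        reps = run_replicates(aln, quartet_tree, scheme, "strict", settings, model=JC4)
        assert list(reps[0].samples.columns) == list(reps[1].samples.columns)
        assert not reps[0].samples.equals(reps[1].samples)

    def test_trace_respects_age_ordering(self, quartet_tree):
        aln = _tiny_alignment(quartet_tree, seed=3)
        scheme = _quartet_scheme(CalibrationPrior("normal", mean=2.6, sd=1.1))
        tr = mcmc_run(aln, quartet_tree, scheme, "strict",
                      MCMCSettings(n_samples=60, thin=2, seed=4), model=JC4)
        root_col = f"t_{quartet_tree.root}"
        for i in quartet_tree.internal_nodes:
            if i == quartet_tree.root:
                continue
            assert (tr.samples[root_col] > tr.samples[f"t_{i}"]).all()

    def test_punctual_scheme_confines_samples(self, quartet_tree):
        scheme = _quartet_scheme(
            CalibrationPrior("hard_uniform", lower=2.59, upper=2.61)
        )
        tr = mcmc_run(None, quartet_tree, scheme, "strict",
                      MCMCSettings(n_samples=500, thin=2, seed=5))
        x = tr.samples[f"t_{quartet_tree.root}"]
        assert ((x >= 2.59) & (x <= 2.61)).all()

    def test_conflicting_hard_bounds_rejected(self, quartet_tree):
        scheme = CalibrationTable((
            CalibrationEntry("a", "d", "old", 1.0,
                             CalibrationPrior("hard_uniform", lower=0.99, upper=1.01)),
            CalibrationEntry("a", "b", "young", 2.0,
                             CalibrationPrior("hard_uniform", lower=1.99, upper=2.01)),
        ))
        with pytest.raises(CalibrationResolutionError):
            mcmc_run(None, quartet_tree, scheme, "strict",
                     MCMCSettings(n_samples=20, thin=1, seed=6))

    def test_duplicate_node_calibrations_rejected(self, quartet_tree):
        scheme = CalibrationTable((
            CalibrationEntry("a", "d", "x", 1.0,
                             CalibrationPrior("normal", mean=1.0, sd=0.4)),
            CalibrationEntry("b", "c", "y", 2.0,
                             CalibrationPrior("normal", mean=2.0, sd=0.9)),
        ))
        with pytest.raises(CalibrationResolutionError):
            resolve_calibrations(quartet_tree, scheme)

    def test_trace_tsv_round_trip(self, tmp_path, quartet_tree):
        scheme = _quartet_scheme(CalibrationPrior("normal", mean=2.6, sd=1.1))
        tr = mcmc_run(None, quartet_tree, scheme, "strict",
                      MCMCSettings(n_samples=50, thin=1, seed=7))
        p = tmp_path / "trace.tsv"
        tr.to_tsv(p)
        back = PosteriorTrace.from_tsv(p)
        assert back.node_clades == tr.node_clades
        assert np.allclose(back.samples.to_numpy(), tr.samples.to_numpy())


class TestPriorOnlySampling:
    def test_root_marginal_matches_rejection_oracle(self, quartet_tree):
        """Prior-only MCMC marginal at the calibrated root equals the
        calibration density restricted to feasible (positive) ages."""
        scheme = _quartet_scheme(CalibrationPrior("normal", mean=2.6, sd=1.1))
        tr = mcmc_run(None, quartet_tree, scheme, "strict",
                      MCMCSettings(n_samples=4000, thin=5, seed=8))
        x = tr.samples[f"t_{quartet_tree.root}"].to_numpy()
        # independent rejection-sampling oracle for the truncated normal
        rng = np.random.default_rng(999)
        y = rng.normal(2.6, 1.1, size=200_000)
        y = y[y > 0]
        from islandclock.mcmc_diagnostics import ess

        se = math.sqrt(x.var() / ess(x) + y.var() / y.size)
        assert abs(x.mean() - y.mean()) < 3 * se


class TestRecovery:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_true_root_age_in_hpd(self, seed):
        from islandclock.conflict_test import hpd_interval

        tree = simulate_time_tree(6, 5.0, seed=seed)
        rates = simulate_rates(tree, "strict", 0.01, seed=seed)
        aln = simulate_alignment(tree, rates, JC4, 1000, seed=seed)
        ra, rb = (tree.taxon_labels[min(tree.tipset(c))]
                  for c in tree.children[tree.root])
        scheme = CalibrationTable((
            CalibrationEntry(ra, rb, "anchor", 5.0,
                             CalibrationPrior("normal", mean=5.0, sd=2.2)),
        ))
        tr = mcmc_run(aln, tree, scheme, "strict",
                      MCMCSettings(n_samples=400, thin=3, seed=seed,
                                   estimate_substitution_model=False),
                      model=JC4)
        lo, hi = hpd_interval(tr.samples[f"t_{tree.root}"].to_numpy())
        assert lo <= 5.0 <= hi


class TestJointPriorCalibration:
    def test_sbc_rank_histogram_uniform(self, quartet_tree):
        """Simulation-based calibration: drawing ages and the clock rate from
        the prior, simulating data, and re-inferring yields uniform posterior
        ranks of the true root age (chi-square on 10 bins, 100 draws)."""
        scheme = _quartet_scheme(CalibrationPrior("normal", mean=2.6, sd=1.1))
        topo = quartet_tree
        root = topo.root
        cherries = [i for i in topo.internal_nodes if i != root]
        rng = np.random.default_rng(2024)
        n_draws, n_kept = 100, 99
        ranks = []
        for _ in range(n_draws):
            while True:
                r = rng.normal(2.6, 1.1)
                if r > 0:
                    break
            ages = np.zeros(topo.n_nodes)
            ages[root] = r
            for c, a in zip(cherries, rng.uniform(0, r, size=2)):
                ages[c] = a
            tree = topo.with_ages(ages)
            mu = rng.lognormal(math.log(0.01), 1.0)
            rates = np.full(topo.n_nodes, mu)
            rates[root] = 0.0
            aln = simulate_alignment(tree, rates, JC4, 150,
                                     seed=int(rng.integers(2**31)))
            tr = mcmc_run(aln, topo, scheme, "strict",
                          MCMCSettings(n_samples=n_kept, thin=4,
                                       seed=int(rng.integers(2**31)),
                                       estimate_substitution_model=False),
                          model=JC4)
            x = tr.samples[f"t_{root}"].to_numpy()
            ranks.append(int((x < r).sum()))
        hist, _ = np.histogram(ranks, bins=10, range=(0, n_kept + 1))
        assert chisquare(hist).pvalue > 0.01


def _tiny_alignment(tree, seed: int):
    aged = tree.with_ages(_quartet_ages(tree))
    rates = simulate_rates(aged, "strict", 0.01, seed=seed)
    return simulate_alignment(aged, rates, JC4, 200, seed=seed)


def _quartet_ages(tree):
    ages = np.zeros(tree.n_nodes)
    for node in tree.internal_nodes:
        clade = tree.clade_labels(node)
        ages[node] = {("a", "b"): 1.0, ("c", "d"): 1.5,
                      ("a", "b", "c", "d"): 2.6}[clade]
    return ages
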