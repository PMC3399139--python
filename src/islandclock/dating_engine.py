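"""Bayesian node dating on a fixed rooted topology.

The model: sequence data evolve under GTR + discrete gamma; branch rates
follow either a strict clock (one global rate, subs/site/Ma) or independent
lognormal branch rates; calibrated node ages carry the calibration densities
(normal, or hard-bounded uniform); uncalibrated internal node ages are
jointly uniform over the region compatible with the topology given the root
age; an uncalibrated root receives a weakly informative gamma prior.

Inference is Metropolis-within-Gibbs: sliding-window moves on node ages
(respecting parent/child bounds), multiplicative scale moves on the clock
mean, gamma shape, exchangeabilities, branch rates and the rate spread, and
a whole-tree scale move that multiplies all ages while dividing the rates —
the move that lets calibrations, not the likelihood, fix absolute time.
Proposal windows auto-tune during burn-in only, preserving detailed balance
afterwards; every chain is fully reproducible from its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import spawn
from .calibration import CalibrationPrior, CalibrationTable
from .likelihood import PruningLikelihood
from .phylo_io import SequenceAlignment, resolve_mrca
from .substitution import SubstitutionModel, discrete_gamma_rates
from .trees import RootedTimeTree

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class MCMCError(RuntimeError):
    """Chain failure that requires operator attention (e.g. frozen block)."""


class CalibrationResolutionError(ValueError):
    """Calibration table entries that cannot be attached to the tree."""


# --------------------------------------------------------------------- priors

def _lognorm_logpdf(x: float, log_mean: float, log_sd: float) -> float:
    if x <= 0:
        return -math.inf
    z = (math.log(x) - log_mean) / log_sd
    return -math.log(x) - math.log(log_sd) - _LOG_SQRT_2PI - 0.5 * z * z


def _gamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return (
        (shape - 1.0) * math.log(x)
        - x / scale
        - math.lgamma(shape)
        - shape * math.log(scale)
    )


@dataclass(frozen=True)
class GammaRootPrior:
    """Weakly informative root-age prior used when the root is uncalibrated:
    gamma with shape 2 and mean twice the oldest calibration mean."""

    shape: float
    mean: float

    def logpdf(self, age: float) -> float:
        return _gamma_logpdf(age, self.shape, self.mean / self.shape)


@dataclass
class Hyperpriors:
    """Hyperpriors on clock and substitution parameters (all overridable)."""

    mu_log_mean: float = math.log(0.01)  # subs/site/Ma
    mu_log_sd: float = 1.0
    sigma_mean: float = 0.3              # exponential mean of the rate spread
    alpha_log_mean: float = 0.0
    alpha_log_sd: float = 0.5
    exch_log_mean: float = 0.0
    exch_log_sd: float = 1.0
    root_shape: float = 2.0


@dataclass
class ClockModel:
    kind: str = "independent_lognormal"  # or "strict"
    mean_rate: float = 0.01
    log_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("strict", "independent_lognormal"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.mean_rate <= 0 or self.log_sd < 0:
            raise ValueError("mean_rate must be > 0 and log_sd >= 0")


@dataclass
class MCMCSettings:
    n_samples: int = 10_000
    thin: int = 100
    burnin_fraction: float = 0.25
    seed: int = 0
    n_replicates: int = 2
    tune_interval: int = 50
    estimate_substitution_model: bool = True

    def __post_init__(self):
        if self.n_samples < 1 or self.thin < 1:
            raise ValueError("n_samples and thin must be >= 1")
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in [0, 1)")

    @property
    def burnin_cycles(self) -> int:
        keep = self.n_samples * self.thin
        return int(math.ceil(self.burnin_fraction / (1 - self.burnin_fraction) * keep))


@dataclass
class PosteriorTrace:
    """Thinned MCMC samples plus the node-column metadata."""

    samples: pd.DataFrame
    node_clades: dict[str, tuple[str, ...]]
    meta: dict = field(default_factory=dict)

    @property
    def age_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("t_")]

    def ages_for_clade(self, clade: tuple[str, ...]) -> np.ndarray:
        clade = tuple(sorted(clade))
        for col, cl in self.node_clades.items():
            if tuple(cl) == clade:
                return self.samples[col].to_numpy()
        raise KeyError(f"no trace column for clade {clade}")

    def to_tsv(self, path: str | Path) -> None:
        header = {
            "node_clades": {k: list(v) for k, v in self.node_clades.items()},
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            fh.write("# islandclock trace " + json.dumps(header) + "\n")
            self.samples.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PosteriorTrace":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# islandclock trace "):
                raise ValueError(f"{path} is not an islandclock trace file")
            header = json.loads(first[len("# islandclock trace "):])
            samples = pd.read_csv(fh, sep="\t")
        clades = {k: tuple(v) for k, v in header["node_clades"].items()}
        return cls(samples, clades, header.get("meta", {}))


# -------------------------------------------------------- calibration resolve

def resolve_calibrations(
    tree: RootedTimeTree, scheme: CalibrationTable
) -> dict[int, CalibrationPrior]:
    """Map scheme entries to internal node indices; nodes must be distinct."""
    out: dict[int, CalibrationPrior] = {}
    for entry in scheme:
        if entry.prior is None:
            raise CalibrationResolutionError(
                f"entry {entry.island_name!r} has no prior; build a scheme first"
            )
        node = resolve_mrca(tree, (entry.taxon_a, entry.taxon_b))
        if node in out:
            raise CalibrationResolutionError(
                f"two calibrations resolve to the same node {tree.node_label(node)!r}"
            )
        out[node] = entry.prior
    return out


def node_age_prior_logdensity(
    tree: RootedTimeTree,
    ages: np.ndarray,
    calibrations: dict[int, CalibrationPrior],
    root_prior: Optional[GammaRootPrior] = None,
) -> float:
    """Joint log-density of internal node ages under the dating prior.

    Calibrated nodes contribute their calibration density; uncalibrated
    non-root nodes are uniform given the topology and root age (each
    contributes ``-log root_age``); an uncalibrated root needs ``root_prior``.
    Returns ``-inf`` whenever an ordering or hard bound is violated.
    """
    root = tree.root
    root_age = ages[root]
    if root_age <= 0:
        return -math.inf
    for i in tree.internal_nodes:
        for c in tree.children[i]:
            if not ages[i] > ages[c]:
                return -math.inf
    total = 0.0
    n_uncal = 0
    for i in tree.internal_nodes:
        prior = calibrations.get(i)
        if prior is not None:
            lp = prior.log_density(float(ages[i]))
            if lp == -math.inf:
                return -math.inf
            total += lp
        elif i != root:
            n_uncal += 1
    if root not in calibrations:
        if root_prior is None:
            raise ValueError("uncalibrated root requires a root prior")
        lp = root_prior.logpdf(float(root_age))
        if lp == -math.inf:
            return -math.inf
        total += lp
    total -= n_uncal * math.log(root_age)
    return total


def default_root_prior(scheme: CalibrationTable, hyper: Hyperpriors) -> GammaRootPrior:
    oldest = max(e.prior.reference_age if e.prior else e.island_age for e in scheme)
    return GammaRootPrior(hyper.root_shape, 2.0 * oldest)


# ------------------------------------------------------------- initialization

def _initial_ages(
    tree: RootedTimeTree, calibrations: dict[int, CalibrationPrior]
) -> np.ndarray:
    """Feasible starting ages: calibrated nodes at their reference ages,
    uncalibrated nodes spread proportionally to subtree height."""
    n = tree.n_nodes
    height = np.zeros(n, dtype=int)
    for node in tree.postorder:
        if not tree.is_tip(node):
            height[node] = 1 + max(height[c] for c in tree.children[node])
    ages = np.zeros(n)
    root = tree.root
    refs = [p.reference_age for p in calibrations.values()]
    if root in calibrations:
        ages[root] = calibrations[root].reference_age
    else:
        ages[root] = 2.0 * max(refs)
    order = [nd for nd in reversed(tree.postorder) if not tree.is_tip(nd) and nd != root]
    for node in order:
        parent_age = ages[int(tree.parent[node])]
        prior = calibrations.get(node)
        frac = height[node] / (height[node] + 1.0)
        fallback = parent_age * frac
        if prior is None:
            ages[node] = fallback
        elif prior.kind == "normal":
            ref = prior.reference_age
            ages[node] = ref if 0 < ref < parent_age else fallback
        else:
            lo, hi = prior.lower, prior.upper
            if lo >= parent_age:
                raise CalibrationResolutionError(
                    f"hard-bounded calibration [{lo:g}, {hi:g}] on node "
                    f"{tree.node_label(node)!r} lies above its parent's starting age"
                )
            ages[node] = 0.5 * (lo + min(hi, parent_age))
    # sanity: ordering must hold by construction
    tmp = tree.with_ages(ages)
    tmp.validate_ages()
    return ages


# ----------------------------------------------------------------- the sampler

class _DatingMCMC:
    def __init__(
        self,
        aln: Optional[SequenceAlignment],
        tree: RootedTimeTree,
        scheme: CalibrationTable,
        clock: ClockModel,
        settings: MCMCSettings,
        hyper: Hyperpriors,
        model: Optional[SubstitutionModel],
        seed_labels: Sequence[str | int],
    ):
        self.tree = tree
        self.settings = settings
        self.hyper = hyper
        self.clock = clock
        self.prior_only = aln is None
        self.rng = spawn(settings.seed, "mcmc", *seed_labels)
        self.calibrations = resolve_calibrations(tree, scheme)
        self.root = tree.root
        self.root_prior = (
            None if self.root in self.calibrations else default_root_prior(scheme, hyper)
        )
        self.internal = tree.internal_nodes
        self.nonroot = np.array([n for n in range(tree.n_nodes) if tree.parent[n] >= 0])
        self.parent_of_nonroot = tree.parent[self.nonroot]

        if model is None:
            freqs = _empirical_freqs(aln) if aln is not None else np.full(4, 0.25)
            model = SubstitutionModel(base_freqs=freqs)
        self.base_freqs = model.base_freqs
        self.n_categories = model.n_categories
        self.engine = None if self.prior_only else PruningLikelihood(aln, tree)

        # ---- state
        self.ages = _initial_ages(tree, self.calibrations)
        self.mu = math.exp(hyper.mu_log_mean)
        self.alpha = float(model.gamma_shape)
        self.exch = np.asarray(model.exchangeabilities, dtype=float).copy()
        self.estimate_subst = settings.estimate_substitution_model and not self.prior_only
        self.relaxed = clock.kind == "independent_lognormal"
        self.sigma = clock.log_sd if clock.log_sd > 0 else 0.1
        self.branch_rates = np.full(tree.n_nodes, self.mu)
        self.branch_rates[self.root] = 0.0

        # ---- caches
        self._refresh_subst_cache()
        self.cur_ll = self._loglik()
        self.cur_age_prior = self._age_prior()
        self.cur_hyper = self._hyper_prior()
        self.cur_rate_prior = self._rate_prior()
        if not np.isfinite(self.cur_age_prior):
            raise MCMCError("infeasible starting state (check calibrations)")

        # ---- proposal windows
        self.windows: dict[str, float] = {
            "mu": 0.6, "alpha": 0.6, "exch": 0.6, "sigma": 0.6,
            "rate": 0.6, "tree_scale": 0.2,
        }
        self.age_windows = np.zeros(tree.n_nodes)
        for i in self.internal:
            prior = self.calibrations.get(i)
            if prior is None:
                self.age_windows[i] = max(0.2 * self.ages[self.root], 0.05)
            elif prior.kind == "normal":
                self.age_windows[i] = prior.sd
            else:
                self.age_windows[i] = prior.upper - prior.lower
        self._acc: dict[str, list[int]] = {}

    # ------------------------------------------------------------- densities
    def _refresh_subst_cache(self) -> None:
        model = SubstitutionModel(
            exchangeabilities=self.exch,
            base_freqs=self.base_freqs,
            gamma_shape=self.alpha,
            n_categories=self.n_categories,
        )
        self._eig = model.eigensystem()
        self._cat_rates = discrete_gamma_rates(self.alpha, self.n_categories)

    def _loglik(self) -> float:
        if self.prior_only:
            return 0.0
        durations = self.ages[self.parent_of_nonroot] - self.ages[self.nonroot]
        rates = self.branch_rates[self.nonroot] if self.relaxed else self.mu
        lens = np.zeros(self.tree.n_nodes)
        lens[self.nonroot] = durations * rates
        w, left, right = self._eig
        return self.engine.loglik_core(
            lens, self._cat_rates, w, left, right, self.base_freqs
        )

    def _age_prior(self) -> float:
        return node_age_prior_logdensity(
            self.tree, self.ages, self.calibrations, self.root_prior
        )

    def _hyper_prior(self) -> float:
        h = self.hyper
        total = _lognorm_logpdf(self.mu, h.mu_log_mean, h.mu_log_sd)
        if self.estimate_subst:
            total += _lognorm_logpdf(self.alpha, h.alpha_log_mean, h.alpha_log_sd)
            for r in self.exch[:5]:
                total += _lognorm_logpdf(r, h.exch_log_mean, h.exch_log_sd)
        if self.relaxed:
            total += -self.sigma / h.sigma_mean - math.log(h.sigma_mean)
        return total

    def _rate_prior(self) -> float:
        if not self.relaxed:
            return 0.0
        loc = math.log(self.mu) - 0.5 * self.sigma**2
        total = 0.0
        for n in self.nonroot:
            total += _lognorm_logpdf(self.branch_rates[n], loc, self.sigma)
        return total

    @property
    def log_posterior(self) -> float:
        return self.cur_ll + self.cur_age_prior + self.cur_hyper + self.cur_rate_prior

    # -------------------------------------------------------------- proposals
    def _record(self, block: str, accepted: bool) -> None:
        acc = self._acc.setdefault(block, [0, 0])
        acc[0] += int(accepted)
        acc[1] += 1

    def _move_age(self, node: int) -> None:
        lower = max(self.ages[c] for c in self.tree.children[node])
        p = int(self.tree.parent[node])
        upper = math.inf if p < 0 else self.ages[p]
        w = self.age_windows[node]
        prop = self.ages[node] + w * (self.rng.random() - 0.5)
        # reflect into the feasible interval (symmetric proposal)
        for _ in range(100):
            if prop < lower:
                prop = 2 * lower - prop
            elif prop > upper:
                prop = 2 * upper - prop
            else:
                break
        else:
            self._record(f"age_{node}", False)
            return
        old_age = self.ages[node]
        self.ages[node] = prop
        new_ap = self._age_prior()
        if new_ap == -math.inf:
            self.ages[node] = old_age
            self._record(f"age_{node}", False)
            return
        new_ll = self._loglik()
        log_r = (new_ll - self.cur_ll) + (new_ap - self.cur_age_prior)
        if math.log(self.rng.random()) < log_r:
            self.cur_ll, self.cur_age_prior = new_ll, new_ap
            self._record(f"age_{node}", True)
        else:
            self.ages[node] = old_age
            self._record(f"age_{node}", False)

    def _scale_move(self, name: str, get, set_, affects_ll: bool, extra_prior=None) -> None:
        w = self.windows[name]
        c = math.exp(w * (self.rng.random() - 0.5))
        old = get()
        set_(old * c)
        new_hyper = self._hyper_prior()
        new_rp = self._rate_prior() if (self.relaxed and extra_prior) else self.cur_rate_prior
        new_ll = self._loglik() if affects_ll else self.cur_ll
        log_r = (
            (new_ll - self.cur_ll)
            + (new_hyper - self.cur_hyper)
            + (new_rp - self.cur_rate_prior)
            + math.log(c)  # Jacobian of the multiplicative proposal
        )
        if np.isfinite(log_r) and math.log(self.rng.random()) < log_r:
            self.cur_ll, self.cur_hyper, self.cur_rate_prior = new_ll, new_hyper, new_rp
            self._record(name, True)
        else:
            set_(old)
            self._record(name, False)

    def _move_mu(self) -> None:
        affects_ll = not self.relaxed and not self.prior_only
        self._scale_move(
            "mu", lambda: self.mu, self._set_mu, affects_ll, extra_prior=True
        )

    def _set_mu(self, v: float) -> None:
        self.mu = v

    def _move_alpha(self) -> None:
        if self.prior_only or not self.estimate_subst:
            return
        w = self.windows["alpha"]
        c = math.exp(w * (self.rng.random() - 0.5))
        old = self.alpha
        self.alpha = old * c
        self._refresh_subst_cache()
        new_hyper = self._hyper_prior()
        new_ll = self._loglik()
        log_r = (new_ll - self.cur_ll) + (new_hyper - self.cur_hyper) + math.log(c)
        if np.isfinite(log_r) and math.log(self.rng.random()) < log_r:
            self.cur_ll, self.cur_hyper = new_ll, new_hyper
            self._record("alpha", True)
        else:
            self.alpha = old
            self._refresh_subst_cache()
            self._record("alpha", False)

    def _move_exch(self) -> None:
        if self.prior_only or not self.estimate_subst:
            return
        idx = int(self.rng.integers(5))  # GT stays fixed at 1
        w = self.windows["exch"]
        c = math.exp(w * (self.rng.random() - 0.5))
        old = self.exch[idx]
        self.exch[idx] = old * c
        self._refresh_subst_cache()
        new_hyper = self._hyper_prior()
        new_ll = self._loglik()
        log_r = (new_ll - self.cur_ll) + (new_hyper - self.cur_hyper) + math.log(c)
        if np.isfinite(log_r) and math.log(self.rng.random()) < log_r:
            self.cur_ll, self.cur_hyper = new_ll, new_hyper
            self._record("exch", True)
        else:
            self.exch[idx] = old
            self._refresh_subst_cache()
            self._record("exch", False)

    def _move_sigma(self) -> None:
        if not self.relaxed:
            return
        w = self.windows["sigma"]
        c = math.exp(w * (self.rng.random() - 0.5))
        old = self.sigma
        self.sigma = old * c
        new_hyper = self._hyper_prior()
        new_rp = self._rate_prior()
        log_r = (new_hyper - self.cur_hyper) + (new_rp - self.cur_rate_prior) + math.log(c)
        if np.isfinite(log_r) and math.log(self.rng.random()) < log_r:
            self.cur_hyper, self.cur_rate_prior = new_hyper, new_rp
            self._record("sigma", True)
        else:
            self.sigma = old
            self._record("sigma", False)

    def _move_branch_rate(self, node: int) -> None:
        w = self.windows["rate"]
        c = math.exp(w * (self.rng.random() - 0.5))
        old = self.branch_rates[node]
        self.branch_rates[node] = old * c
        new_rp = self._rate_prior()
        new_ll = self._loglik()
        log_r = (new_ll - self.cur_ll) + (new_rp - self.cur_rate_prior) + math.log(c)
        if np.isfinite(log_r) and math.log(self.rng.random()) < log_r:
            self.cur_ll, self.cur_rate_prior = new_ll, new_rp
            self._record("rate", True)
        else:
            self.branch_rates[node] = old
            self._record("rate", False)

    def _move_tree_scale(self) -> None:
        """Multiply all internal ages by c, divide the rates by c.

        Under a strict clock this leaves every branch length (rate x time)
        unchanged, so only the priors discriminate: absolute time is set by
        the calibrations.  Jacobian: n_internal ages scaled up, mu (and the
        branch rates when relaxed) scaled down.
        """
        w = self.windows["tree_scale"]
        c = math.exp(w * (self.rng.random() - 0.5))
        old_ages = self.ages.copy()
        old_mu = self.mu
        old_rates = self.branch_rates.copy()
        self.ages[self.internal] = old_ages[self.internal] * c
        self.mu = old_mu / c
        n_scaled_down = 1
        if self.relaxed:
            self.branch_rates = old_rates / c
            self.branch_rates[self.root] = 0.0
            n_scaled_down += len(self.nonroot)
        new_ap = self._age_prior()
        if new_ap == -math.inf:
            self.ages = old_ages
            self.mu = old_mu
            self.branch_rates = old_rates
            self._record("tree_scale", False)
            return
        new_hyper = self._hyper_prior()
        new_rp = self._rate_prior()
        new_ll = self._loglik()
        log_jac = (len(self.internal) - n_scaled_down) * math.log(c)
        log_r = (
            (new_ll - self.cur_ll)
            + (new_ap - self.cur_age_prior)
            + (new_hyper - self.cur_hyper)
            + (new_rp - self.cur_rate_prior)
            + log_jac
        )
        if np.isfinite(log_r) and math.log(self.rng.random()) < log_r:
            self.cur_ll, self.cur_age_prior = new_ll, new_ap
            self.cur_hyper, self.cur_rate_prior = new_hyper, new_rp
            self._record("tree_scale", True)
        else:
            self.ages = old_ages
            self.mu = old_mu
            self.branch_rates = old_rates
            self._record("tree_scale", False)

    def _sweep(self) -> None:
        for node in self.internal:
            self._move_age(node)
        self._move_mu()
        self._move_alpha()
        self._move_exch()
        if self.relaxed:
            self._move_sigma()
            for node in self.nonroot:
                self._move_branch_rate(int(node))
        self._move_tree_scale()

    def _tune(self) -> None:
        for block, (acc, att) in self._acc.items():
            if att == 0:
                continue
            rate = acc / att
            factor = math.exp(1.2 * (rate - 0.35))
            if block.startswith("age_"):
                node = int(block[4:])
                self.age_windows[node] = float(
                    np.clip(self.age_windows[node] * factor, 1e-4, 1e3)
                )
            else:
                self.windows[block] = float(
                    np.clip(self.windows[block] * factor, 1e-3, 10.0)
                )
        self._acc = {}

    # ------------------------------------------------------------------- run
    def run(self) -> PosteriorTrace:
        s = self.settings
        burnin = s.burnin_cycles
        for cycle in range(burnin):
            self._sweep()
            if (cycle + 1) % s.tune_interval == 0:
                self._tune()
        self._acc = {}

        cols = self._columns()
        out = np.empty((s.n_samples, len(cols)))
        kept = 0
        cycle = 0
        while kept < s.n_samples:
            for _ in range(s.thin):
                self._sweep()
                cycle += 1
            out[kept] = self._row(cycle)
            kept += 1
        self._check_frozen()
        df = pd.DataFrame(out, columns=cols)
        df["state"] = (np.arange(1, s.n_samples + 1) * s.thin + burnin).astype(int)
        df = df[["state"] + cols]
        clades = {
            f"t_{i}": self.tree.clade_labels(i) for i in self.internal
        }
        meta = {
            "clock_kind": self.clock.kind,
            "prior_only": self.prior_only,
            "seed": s.seed,
            "thin": s.thin,
            "n_samples": s.n_samples,
            "burnin_cycles": burnin,
        }
        return PosteriorTrace(df, clades, meta)

    def _columns(self) -> list[str]:
        cols = [f"t_{i}" for i in self.internal] + ["mu"]
        if self.relaxed:
            cols.append("sigma")
        if self.estimate_subst:
            cols += ["alpha", "ex_AC", "ex_AG", "ex_AT", "ex_CG", "ex_CT"]
        if self.relaxed:
            cols += [f"r_{int(n)}" for n in self.nonroot]
        cols += ["lnL", "lnPr"]
        return cols

    def _row(self, cycle: int) -> list[float]:
        row = [float(self.ages[i]) for i in self.internal] + [self.mu]
        if self.relaxed:
            row.append(self.sigma)
        if self.estimate_subst:
            row += [self.alpha] + [float(x) for x in self.exch[:5]]
        if self.relaxed:
            row += [float(self.branch_rates[int(n)]) for n in self.nonroot]
        row += [self.cur_ll, self.cur_age_prior + self.cur_hyper + self.cur_rate_prior]
        return row

    def _check_frozen(self) -> None:
        for block, (acc, att) in self._acc.items():
            if att >= 100 and acc == 0:
                raise MCMCError(
                    f"proposal block {block!r} accepted nothing after tuning "
                    f"({att} attempts); adjust its proposal window or check "
                    "for conflicting hard-bounded calibrations"
                )


def _empirical_freqs(aln: SequenceAlignment) -> np.ndarray:
    counts = np.array([
        (aln.sites == b).sum() for b in "ACGT"
    ], dtype=float)
    counts[3] += (aln.sites == "U").sum()
    if counts.sum() == 0:
        return np.full(4, 0.25)
    freqs = (counts + 1.0) / (counts.sum() + 4.0)  # +1 smoothing keeps freqs > 0
    return freqs / freqs.sum()


def mcmc_run(
    aln: Optional[SequenceAlignment],
    tree: RootedTimeTree,
    scheme: CalibrationTable,
    clock: ClockModel | str = "independent_lognormal",
    settings: Optional[MCMCSettings] = None,
    hyper: Optional[Hyperpriors] = None,
    model: Optional[SubstitutionModel] = None,
    seed_labels: Sequence[str | int] = (),
) -> PosteriorTrace:
    """Run one dating chain and return its thinned posterior trace.

    ``aln=None`` runs the chain prior-only (likelihood identically 1), the
    standard device for checking that the sampler reproduces its own
    calibration densities.
    """
    if isinstance(clock, str):
        clock = ClockModel(kind=clock)
    mcmc = _DatingMCMC(
        aln, tree, scheme,
        clock, settings or MCMCSettings(), hyper or Hyperpriors(), model,
        seed_labels,
    )
    return mcmc.run()


def run_replicates(
    aln: Optional[SequenceAlignment],
    tree: RootedTimeTree,
    scheme: CalibrationTable,
    clock: ClockModel | str = "independent_lognormal",
    settings: Optional[MCMCSettings] = None,
    **kwargs,
) -> list[PosteriorTrace]:
    """Independent replicate chains (different streams off the same seed)."""
    settings = settings or MCMCSettings()
    return [
        mcmc_run(aln, tree, scheme, clock, settings, seed_labels=("rep", r), **kwargs)
        for r in range(settings.n_replicates)
    ]
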