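"""Synthetic multilocus datasets with known truth.

Emulates the kind of data island-calibration studies use — multilocus DNA
alignments (tens of taxa, a few kb) evolved on ultrametric time-trees under
GTR + discrete gamma with strict or independent-lognormal branch rates —
while keeping the true node ages on record.  A scenario pins one focal node
to ``island_age + divergence_offset``: offset 0 emulates cladogenesis
concomitant with island formation, a positive offset a split predating the
island, a negative offset a later split.

The generated calibration table anchors the timescale with a narrow
hard-bounded calibration at the true root age and places the island
calibration (the one under test) on the focal node; absolute time is not
identifiable from sequence data alone, so without the anchor an island
calibration could never be contradicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from ._rng import spawn
from .calibration import (
    CalibrationEntry,
    CalibrationPrior,
    CalibrationTable,
    punctual_interval,
)
from .phylo_io import SequenceAlignment
from .substitution import STATE_ORDER, SubstitutionModel, transition_matrices
from .trees import AgeConstraintError, RootedTimeTree


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic island dataset."""

    n_taxa: int = 8
    root_age: float = 5.0
    island_age: float = 1.0
    divergence_offset: float = 0.0
    clock_kind: Literal["strict", "independent_lognormal"] = "strict"
    clock_mean_rate: float = 0.02
    clock_log_sd: float = 0.3
    subst_model: SubstitutionModel = field(default_factory=SubstitutionModel)
    n_sites: int = 2000
    seed: int = 0

    def __post_init__(self):
        true_age = self.island_age + self.divergence_offset
        if not 0 < true_age < self.root_age:
            raise ValueError(
                f"island_age + divergence_offset must lie in (0, root_age); "
                f"got {true_age} with root_age {self.root_age}"
            )
        if self.clock_mean_rate <= 0:
            raise ValueError("clock_mean_rate must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")


@dataclass
class SimulationTruth:
    """Everything the generator knows that inference must recover."""

    true_tree: RootedTimeTree
    true_rates: np.ndarray  # rate on the branch above each non-root node
    focal_node: int
    scenario: SimulationScenario

    def __post_init__(self):
        nonroot = self.true_tree.parent >= 0
        if np.any(self.true_rates[nonroot] <= 0):
            raise ValueError("branch rates must be strictly positive")


# ------------------------------------------------------------------ time trees

def simulate_time_tree(
    n_taxa: int,
    root_age: float,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> RootedTimeTree:
    """Pure-birth (Yule) tree conditioned on tip count, rescaled to root_age.

    Forward simulation: with k lineages the next split waits Exp(k*lambda)
    and hits a uniformly chosen lineage; after the (n-1)-th split an
    Exp(n*lambda) stem runs to the present.  All node ages are then rescaled
    so the root sits exactly at ``root_age``, with tips at 0.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = spawn(seed, "yule")
    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children: list[tuple[int, ...]] = [()] * n_nodes

    # grow from the root downward; provisional ids are allocated from the top
    # and the lineages still open at the present become the tips
    t = 0.0
    root = n_nodes - 1
    next_id = n_nodes - 2
    active = [root]
    times = {root: 0.0}  # elapsed time from the root to each split
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        times[node] = t
        c1, c2 = next_id, next_id - 1
        next_id -= 2
        parent[c1] = node
        parent[c2] = node
        children[node] = (c1, c2)
        active.extend([c1, c2])
    t_present = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    # remap provisional ids: open lineages -> tips 0..n-1, split nodes -> n..2n-2
    internals = [k for k in range(n_nodes) if children[k]]
    mapping = {old: i for i, old in enumerate(sorted(active))}
    mapping.update({old: n_taxa + i for i, old in enumerate(sorted(internals))})
    new_parent = np.full(n_nodes, -1, dtype=np.int64)
    new_children: list[tuple[int, ...]] = [()] * n_nodes
    ages = np.zeros(n_nodes)
    for old in internals:
        new = mapping[old]
        new_children[new] = tuple(mapping[c] for c in children[old])
        ages[new] = t_present - times[old]
        for c in children[old]:
            new_parent[mapping[c]] = new
    root_new = mapping[root]
    scale = root_age / ages[root_new]
    ages[n_taxa:] *= scale
    labels = [f"t{i+1}" for i in range(n_taxa)]
    return RootedTimeTree(labels, new_parent, new_children, ages)


def pin_node_age(tree: RootedTimeTree, node: int, target_age: float) -> RootedTimeTree:
    """Return a copy with one node's age set exactly to ``target_age``.

    The target must stay strictly between the oldest child and the parent
    (or above the oldest child, for the root).
    """
    if tree.ages is None:
        raise AgeConstraintError("tree has no ages to pin")
    if tree.is_tip(node):
        raise ValueError("cannot pin a tip age")
    lower = max(tree.ages[c] for c in tree.children[node])
    p = int(tree.parent[node])
    upper = np.inf if p < 0 else tree.ages[p]
    if not lower < target_age < upper:
        raise AgeConstraintError(
            f"target age {target_age:g} infeasible for node {tree.node_label(node)!r}: "
            f"must lie in ({lower:g}, {upper:g})"
        )
    ages = tree.ages.copy()
    ages[node] = target_age
    return tree.with_ages(ages)


def rescale_clade(tree: RootedTimeTree, node: int, target_age: float) -> RootedTimeTree:
    """Scale every age inside ``node``'s clade so the node lands on target_age.

    Unlike :func:`pin_node_age` this always succeeds when the target is below
    the parent's age, because descendants shrink or stretch proportionally.
    """
    if tree.ages is None:
        raise AgeConstraintError("tree has no ages")
    p = int(tree.parent[node])
    upper = np.inf if p < 0 else tree.ages[p]
    if not 0 < target_age < upper:
        raise AgeConstraintError(
            f"target age {target_age:g} must lie in (0, {upper:g})"
        )
    factor = target_age / tree.ages[node]
    ages = tree.ages.copy()
    stack = [node]
    while stack:
        nd = stack.pop()
        if not tree.is_tip(nd):
            ages[nd] = tree.ages[nd] * factor
            stack.extend(tree.children[nd])
    return tree.with_ages(ages)


# ---------------------------------------------------------------- branch rates

def simulate_rates(
    tree: RootedTimeTree,
    clock_kind: str,
    mean_rate: float,
    log_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-branch substitution rates (indexed by the node below each branch).

    ``strict`` assigns every branch ``mean_rate``; ``independent_lognormal``
    draws i.i.d. lognormal rates with expectation ``mean_rate`` (location
    ``log mean_rate - log_sd^2 / 2``).  The root entry is 0 (no branch).
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be positive")
    if log_sd < 0:
        raise ValueError("log_sd must be nonnegative")
    rng = spawn(seed, "rates")
    rates = np.zeros(tree.n_nodes)
    nonroot = tree.parent >= 0
    if clock_kind == "strict":
        rates[nonroot] = mean_rate
    elif clock_kind == "independent_lognormal":
        mu = np.log(mean_rate) - 0.5 * log_sd**2
        rates[nonroot] = rng.lognormal(mu, log_sd, size=int(nonroot.sum()))
    else:
        raise ValueError(f"unknown clock_kind {clock_kind!r}")
    return rates


# ------------------------------------------------------------------ sequences

def simulate_alignment(
    tree: RootedTimeTree,
    rates: np.ndarray,
    subst_model: SubstitutionModel,
    n_sites: int,
    seed: int | np.random.Generator = 0,
) -> SequenceAlignment:
    """Evolve sequences site-independently down the dated tree.

    Each site draws a gamma-category rate multiplier; the root sequence is
    drawn from the stationary frequencies (reversibility), and each branch
    applies P(rate x duration x multiplier) from the GTR eigensystem.
    """
    if tree.ages is None:
        raise AgeConstraintError("tree must carry node ages")
    rng = spawn(seed, "seqsim")
    k = subst_model.n_categories
    cat_rates = subst_model.category_rates()
    site_cat = rng.integers(k, size=n_sites)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    root = tree.root
    states[root] = rng.choice(4, size=n_sites, p=subst_model.base_freqs)
    for node in reversed(tree.postorder):  # preorder: parents before children
        if node == root:
            continue
        p = int(tree.parent[node])
        duration = tree.ages[p] - tree.ages[node]
        base_len = rates[node] * duration
        pmats = transition_matrices(subst_model, base_len * cat_rates)  # (k,4,4)
        cdf = pmats.cumsum(axis=2)
        u = rng.random(n_sites)
        rowcdf = cdf[site_cat, states[p]]  # (n_sites, 4)
        states[node] = (u[:, None] > rowcdf).sum(axis=1)
    chars = np.array(list(STATE_ORDER), dtype="U1")
    mat = chars[states[: tree.n_taxa]]
    return SequenceAlignment(list(tree.taxon_labels), mat)


# ------------------------------------------------------------------- scenarios

def _focal_node(tree: RootedTimeTree) -> int:
    """Deterministic focal choice: the root child with the larger clade
    (ties broken toward the smaller node index)."""
    kids = sorted(tree.children[tree.root])
    best = max(kids, key=lambda c: (len(tree.tipset(c)), -c))
    if tree.is_tip(best):
        raise ValueError("root child is a tip; increase n_taxa")
    return best


def simulate_scenario(scenario: SimulationScenario) -> tuple[SimulationTruth, SequenceAlignment]:
    """Generate one full dataset: dated tree, branch rates, and alignment.

    The focal node (a child of the root) is rescaled to
    ``island_age + divergence_offset``; rates and sequences are then drawn
    under the scenario's clock and substitution model.
    """
    true_age = scenario.island_age + scenario.divergence_offset
    # retry until the focal node is internal (tiny trees can attach a tip there)
    for attempt in range(100):
        tree = simulate_time_tree(
            scenario.n_taxa, scenario.root_age, 1.0, spawn(scenario.seed, "scenario", "tree", attempt)
        )
        kids = tree.children[tree.root]
        if any(not tree.is_tip(c) for c in kids):
            break
    focal = _focal_node(tree)
    tree = rescale_clade(tree, focal, true_age)
    rates = simulate_rates(
        tree, scenario.clock_kind, scenario.clock_mean_rate,
        scenario.clock_log_sd, spawn(scenario.seed, "scenario", "rates"),
    )
    aln = simulate_alignment(
        tree, rates, scenario.subst_model, scenario.n_sites,
        spawn(scenario.seed, "scenario", "aln"),
    )
    return SimulationTruth(tree, rates, focal, scenario), aln


def scenario_calibrations(truth: SimulationTruth) -> tuple[CalibrationTable, tuple[str, str]]:
    """Calibration inputs for a scenario: root anchor + island focal node.

    Returns the raw table (island ages, no priors yet — schemes come from
    :func:`islandclock.calibration.build_schemes`) for the focal node, plus a
    ready hard-bounded anchor entry at the true root age, and the taxon pair
    naming the focal node.
    """
    tree = truth.true_tree
    focal = truth.focal_node
    pair = _clade_defining_pair(tree, focal)
    root_pair = _clade_defining_pair(tree, tree.root)
    lo, hi = punctual_interval(truth.scenario.root_age)
    anchor = CalibrationEntry(
        root_pair[0], root_pair[1], "root_anchor", truth.scenario.root_age,
        CalibrationPrior("hard_uniform", lower=lo, upper=hi),
    )
    island = CalibrationEntry(
        pair[0], pair[1], "island", truth.scenario.island_age, None
    )
    return CalibrationTable((anchor, island)), pair


def _clade_defining_pair(tree: RootedTimeTree, node: int) -> tuple[str, str]:
    a, b = tree.children[node]
    ta = tree.taxon_labels[min(tree.tipset(a))]
    tb = tree.taxon_labels[min(tree.tipset(b))]
    return ta, tb


def write_truth_table(truth: SimulationTruth, path: str | Path) -> None:
    """Machine-readable truth: node, true age, island age, offset (TSV)."""
    tree = truth.true_tree
    rows = ["node\ttrue_age_Ma\tisland_age_Ma\toffset_Ma"]
    for n in tree.internal_nodes:
        island = (
            f"{truth.scenario.island_age:g}" if n == truth.focal_node else ""
        )
        offset = (
            f"{truth.scenario.divergence_offset:g}" if n == truth.focal_node else ""
        )
        rows.append(f"{tree.node_label(n)}\t{tree.ages[n]:.6g}\t{island}\t{offset}")
    Path(path).write_text("\n".join(rows) + "\n")
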