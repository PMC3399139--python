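"""Felsenstein pruning likelihood under GTR + discrete gamma.

Sites are compressed to unique patterns once; gaps and ambiguity codes enter
as partial missing data (a tip's conditional likelihood is 1 for every
compatible state).  The per-site likelihood averages over the gamma rate
categories; per-node rescaling keeps small values inside double range.
"""

from __future__ import annotations

import numpy as np

from .phylo_io import IUPAC_STATES, SequenceAlignment
from .substitution import SubstitutionModel
from .trees import RootedTimeTree


class TaxonMismatchError(ValueError):
    """Alignment taxa are not a subset of the tree's tips."""


def _tip_partial_row(symbol: str) -> np.ndarray:
    out = np.zeros(4)
    states = IUPAC_STATES.get(symbol)
    if states is None:
        raise ValueError(f"unknown DNA symbol {symbol!r}")
    out[list(states)] = 1.0
    return out


class PruningLikelihood:
    """Reusable pruning engine bound to one alignment and one topology.

    The topology, pattern compression, and tip partials are fixed at
    construction; :meth:`loglik` evaluates the likelihood for any assignment
    of per-branch lengths (expected substitutions/site, before the gamma
    category multiplier) and substitution model.
    """

    def __init__(self, aln: SequenceAlignment, tree: RootedTimeTree):
        missing = set(aln.taxon_ids) - set(tree.taxon_labels)
        if missing:
            raise TaxonMismatchError(f"alignment taxa absent from tree: {sorted(missing)}")
        missing = set(tree.taxon_labels) - set(aln.taxon_ids)
        if missing:
            raise TaxonMismatchError(f"tree tips absent from alignment: {sorted(missing)}")
        self.tree = tree
        # rows ordered by tree tip index
        rows = np.stack([aln.row(label) for label in tree.taxon_labels])
        patterns, counts = np.unique(rows, axis=1, return_counts=True)
        self.pattern_counts = counts.astype(float)
        self.n_sites = aln.n_sites
        self.n_patterns = patterns.shape[1]
        lut_syms = sorted(IUPAC_STATES)
        lut = np.stack([_tip_partial_row(s) for s in lut_syms])
        sym_index = {s: i for i, s in enumerate(lut_syms)}
        # (n_tips, n_patterns, 4)
        self.tip_partials = np.stack([
            lut[[sym_index[s] for s in patterns[i]]] for i in range(tree.n_taxa)
        ])
        self._post_internal = [n for n in tree.postorder if not tree.is_tip(n)]
        self._nonroot = np.array(
            [n for n in range(tree.n_nodes) if tree.parent[n] >= 0], dtype=np.int64
        )
        self._nonroot_pos = {int(n): i for i, n in enumerate(self._nonroot)}

    def loglik(self, node_lengths: np.ndarray, model: SubstitutionModel) -> float:
        """Log-likelihood given per-node subtending-branch lengths.

        ``node_lengths[i]`` is the length (expected subs/site at the mean
        rate) of the branch above node ``i``; the root entry is ignored.
        """
        w, left, right = model.eigensystem()
        return self.loglik_core(
            np.asarray(node_lengths, dtype=float),
            model.category_rates(), w, left, right, model.base_freqs,
        )

    def loglik_core(
        self,
        node_lengths: np.ndarray,
        cat_rates: np.ndarray,
        w: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        base_freqs: np.ndarray,
    ) -> float:
        """Hot-path evaluation with a precomputed eigensystem and category rates.

        The MCMC sweep caches ``(w, left, right)`` and ``cat_rates`` across
        the many proposals that leave the substitution model untouched.
        """
        tree = self.tree
        k = len(cat_rates)
        lens = node_lengths[self._nonroot, None] * cat_rates[None, :]
        ew = np.exp(lens.reshape(-1, 1) * w[None, :])
        # transition matrices, stored transposed so the pruning step is a
        # batched (k, p, 4) @ (k, 4, 4) matmul
        pmats = np.matmul(left[None, :, :] * ew[:, None, :], right)
        np.clip(pmats, 0.0, None, out=pmats)
        pmats_t = np.ascontiguousarray(
            pmats.reshape(len(self._nonroot), k, 4, 4).transpose(0, 1, 3, 2)
        )

        partials: dict[int, np.ndarray] = {}  # (k, n_patterns, 4) per node
        log_scale = np.zeros(self.n_patterns)
        for node in self._post_internal:
            prod = None
            for child in tree.children[node]:
                pt = pmats_t[self._nonroot_pos[child]]
                if tree.is_tip(child):
                    contrib = np.matmul(self.tip_partials[child][None, :, :], pt)
                else:
                    contrib = np.matmul(partials.pop(child), pt)
                prod = contrib if prod is None else prod * contrib
            scale = prod.max(axis=(0, 2))
            if not np.all(scale > 0.0):
                return -np.inf
            prod /= scale[None, :, None]
            log_scale += np.log(scale)
            partials[node] = prod
        root_partial = partials[tree.root]
        site_lik = (root_partial @ base_freqs).mean(axis=0)
        if not np.all(site_lik > 0.0):
            return -np.inf
        return float(self.pattern_counts @ (np.log(site_lik) + log_scale))


def pruning_loglik(
    aln: SequenceAlignment,
    tree: RootedTimeTree,
    rates: np.ndarray | float,
    model: SubstitutionModel,
) -> float:
    """Log-likelihood of an alignment on a dated tree with per-branch rates.

    ``rates`` is either a scalar (strict clock) or an array indexed by node
    giving the rate (subs/site/Ma) on the branch above each non-root node;
    branch length = rate x time duration.
    """
    if tree.ages is None:
        raise ValueError("tree must carry node ages")
    durations = np.zeros(tree.n_nodes)
    for n in range(tree.n_nodes):
        p = tree.parent[n]
        if p >= 0:
            durations[n] = tree.ages[p] - tree.ages[n]
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (tree.n_nodes,))
    engine = PruningLikelihood(aln, tree)
    return engine.loglik(rates * durations, model)
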