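"""Prior-posterior conflict tests for island calibrations.

For each calibrated node this module computes the 95% HPD interval of the
posterior age, the Kullback-Leibler divergence between the node's normal
calibration prior and its posterior, a three-way classification of the
divergence relative to the island age, and (when both calibration schemes
were run) the absolute difference between the scheme posterior means.

The classification follows the conservative reading of the HPD test: a
divergence is called older (``pre_island``) or younger (``post_island``)
than island formation only when the island age falls strictly outside the
95% HPD; otherwise concomitant cladogenesis is not rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._rng import spawn
from .calibration import CalibrationPrior, CalibrationTable
from .dating_engine import PosteriorTrace, resolve_calibrations
from .phylo_io import resolve_mrca
from .trees import RootedTimeTree

PRE_ISLAND = "pre_island"
CONCOMITANT = "concomitant_not_rejected"
POST_ISLAND = "post_island"

_DENSITY_FLOOR = 1e-300


class HardBoundReferenceError(ValueError):
    """KL against a hard-bounded reference is ill-defined once any posterior
    sample falls outside the bounds; use the normal calibration as reference."""


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` of the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 samples for an HPD, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    if x[0] == x[-1]:
        raise ValueError("HPD of a constant sample is degenerate")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def kl_divergence(
    posterior_samples: np.ndarray,
    prior: CalibrationPrior,
    direction: str = "posterior_from_prior",
    seed: int = 0,
) -> float:
    """KL divergence (nats) between a node's posterior sample and its prior.

    The posterior density is a Gaussian KDE (Silverman bandwidth) over the
    samples.  The default direction KL(posterior || prior) is estimated as
    the sample average of ``log q(x) - log p(x)``; the flipped direction
    draws the same number of points from the (normal) prior.  Negative
    estimates, which can only arise from estimator noise, are clamped to 0.
    """
    x = np.asarray(posterior_samples, dtype=float)
    if x.size < 1000:
        raise ValueError(f"need at least 1000 samples, got {x.size}")
    if prior.kind == "hard_uniform":
        if np.any((x < prior.lower) | (x > prior.upper)):
            raise HardBoundReferenceError(
                "posterior samples fall outside the hard bounds, so the KL "
                "against the punctual prior is infinite; use the normal "
                "calibration prior as the reference density"
            )
    kde = gaussian_kde(x, bw_method="silverman")
    if direction == "posterior_from_prior":
        q = np.clip(kde(x), _DENSITY_FLOOR, None)
        p = np.clip(prior.density(x), _DENSITY_FLOOR, None)
        est = float(np.mean(np.log(q) - np.log(p)))
    elif direction == "prior_from_posterior":
        if prior.kind != "normal":
            raise HardBoundReferenceError(
                "sampling the flipped direction requires the normal prior"
            )
        rng = spawn(seed, "klflip")
        y = rng.normal(prior.mean, prior.sd, size=x.size)
        p = np.clip(prior.density(y), _DENSITY_FLOOR, None)
        q = np.clip(kde(y), _DENSITY_FLOOR, None)
        est = float(np.mean(np.log(p) - np.log(q)))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return max(0.0, est)


def classify_node(hpd: tuple[float, float], island_age: float) -> str:
    """Three-way verdict of a calibrated divergence against its island age.

    Strict inequalities: an island age exactly on an HPD endpoint is not
    rejected (conservative tie-break).
    """
    low, high = hpd
    if not low < high:
        raise ValueError("invalid HPD interval")
    if island_age < low:
        return PRE_ISLAND
    if island_age > high:
        return POST_ISLAND
    return CONCOMITANT


def compare_schemes(
    trace_normal: PosteriorTrace, trace_punctual: PosteriorTrace
) -> tuple[dict[str, float], tuple[float, float]]:
    """Per-node |posterior-mean difference| between the two calibration schemes.

    Returns the per-age-column differences and their (min, max) summary.
    """
    cols_n = set(trace_normal.age_columns)
    cols_p = set(trace_punctual.age_columns)
    if cols_n != cols_p or any(
        trace_normal.node_clades[c] != trace_punctual.node_clades[c] for c in cols_n
    ):
        raise ValueError("scheme traces do not share the node schema")
    diffs = {
        c: float(abs(trace_normal.samples[c].mean() - trace_punctual.samples[c].mean()))
        for c in sorted(cols_n)
    }
    vals = list(diffs.values())
    return diffs, (min(vals), max(vals))


@dataclass
class NodeAssessment:
    """Everything the method reports about one calibrated node."""

    node: str                      # clade label of the calibrated node
    island_name: str
    island_age: float
    posterior_mean: float
    hpd_low: float
    hpd_high: float
    kl_div: float
    classification: str
    scheme_mean_difference: Optional[float]  # None when only one scheme was run


def assess_all(
    traces: dict[str, PosteriorTrace],
    calibration_table: CalibrationTable,
    tree: RootedTimeTree,
    normal_scheme: CalibrationTable,
    hpd_mass: float = 0.95,
    kl_direction: str = "posterior_from_prior",
    density_grid_points: int = 256,
) -> tuple[list[NodeAssessment], pd.DataFrame, dict[str, pd.DataFrame]]:
    """Assess every calibrated node from the normal-scheme posterior.

    ``traces`` maps scheme name ('normal', optionally 'punctual') to its
    trace.  Returns the list of per-node assessments, a tidy report frame,
    and per-node prior/posterior density curves on a common age grid.
    """
    if "normal" not in traces:
        raise ValueError("the normal-scheme trace is required for assessment")
    trace_n = traces["normal"]
    trace_p = traces.get("punctual")
    diffs: Optional[dict[str, float]] = None
    if trace_p is not None:
        diffs, _ = compare_schemes(trace_n, trace_p)

    calmap = resolve_calibrations(tree, normal_scheme)
    entries_by_node = {
        resolve_mrca(tree, (e.taxon_a, e.taxon_b)): e for e in calibration_table
    }
    assessments: list[NodeAssessment] = []
    curves: dict[str, pd.DataFrame] = {}
    for node in sorted(calmap):
        prior = calmap[node]
        entry = entries_by_node[node]
        col = f"t_{node}"
        if col not in trace_n.samples.columns:
            raise ValueError(f"trace lacks a column for calibrated node {col}")
        samples = trace_n.samples[col].to_numpy()
        hpd = hpd_interval(samples, hpd_mass)
        kl = kl_divergence(samples, prior, direction=kl_direction)
        label = "|".join(tree.clade_labels(node))
        assessments.append(NodeAssessment(
            node=label,
            island_name=entry.island_name,
            island_age=entry.island_age,
            posterior_mean=float(samples.mean()),
            hpd_low=hpd[0],
            hpd_high=hpd[1],
            kl_div=kl,
            classification=classify_node(hpd, entry.island_age),
            scheme_mean_difference=None if diffs is None else diffs[col],
        ))
        lo = min(samples.min(), prior.reference_age - 4 * (prior.sd or 1.0)) if prior.kind == "normal" else samples.min()
        hi = max(samples.max(), prior.reference_age + 4 * (prior.sd or 1.0)) if prior.kind == "normal" else samples.max()
        grid = np.linspace(lo, hi, density_grid_points)
        kde = gaussian_kde(samples, bw_method="silverman")
        curves[label] = pd.DataFrame({
            "age_Ma": grid,
            "prior_density": prior.density(grid),
            "posterior_density": kde(grid),
        })
    report = pd.DataFrame([
        {
            "node": a.node, "island": a.island_name, "island_age": a.island_age,
            "post_mean": a.posterior_mean, "hpd_low": a.hpd_low,
            "hpd_high": a.hpd_high, "kl_div": a.kl_div,
            "classification": a.classification,
            "scheme_diff": float("nan") if a.scheme_mean_difference is None
            else a.scheme_mean_difference,
        }
        for a in assessments
    ])
    return assessments, report, curves


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_density_curves(curves: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, df in curves.items():
        safe = label.replace("|", "_")
        p = outdir / f"density_{safe}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths
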