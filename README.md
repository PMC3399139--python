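# islandclock

Bayesian divergence-time inference with **probabilistic island-age
calibrations**, and a formal test of whether each calibrated lineage split
was *concomitant with*, *older than*, or *younger than* the formation of
the island it is tied to.

## The problem

Phylogeographic studies of hot-spot archipelagos (Hawaii being the classic
case) routinely date species trees by fixing the age of a divergence to the
geological age of an island — a *punctual* calibration. That practice
assumes the split happened exactly when the island emerged, so it can never
reveal that a lineage is older than its island (e.g. colonised from an older
island) or younger (delayed colonisation). Treating the island age instead
as a *probability distribution* lets the sequence data pull the node age
away from the island age, and turns the island-age assumption itself into a
testable hypothesis.

`islandclock` implements that re-analysis procedure as a reusable pipeline:

1. **Calibration construction** — for an island age *m* (Ma), the soft
   scheme uses a normal prior N(*m*, *s*) with *s* chosen so that the
   one-sided 99% lower limit reaches the present: *s* = *m*/*z*₀.₉₉ =
   *m*/2.3263, rounded to 0.1 Ma. The punctual scheme uses a hard-bounded
   uniform on [*m* − 0.01, *m* + 0.01]; ages outside have zero probability.
2. **Dating engine** — MCMC over node ages on a fixed rooted topology under
   GTR+Γ (exact Felsenstein pruning likelihood), with a strict or
   independent-lognormal relaxed clock, the calibration densities as node
   priors, and uniform-given-root priors on uncalibrated node ages. Two
   replicate chains per scheme, thinned samples, reproducible from a seed.
3. **Diagnostics** — per-parameter effective sample size
   ESS = *n*/(1 + 2Σρ̂ₖ) with the ESS ≥ 200 rerun rule and a
   two-replicate agreement gate.
4. **Conflict test** — per calibrated node: the 95% highest-posterior-
   density (HPD) interval, the Kullback–Leibler divergence
   KL(posterior ‖ prior) in nats (near 0 when the data add nothing beyond
   the calibration), the three-way verdict (`pre_island` if the island age
   falls below the HPD, `post_island` if above, otherwise
   `concomitant_not_rejected`), and the |Δmean| between the soft- and
   punctual-scheme posteriors.
5. **Synthetic data** — Yule time-trees, strict/lognormal branch rates and
   GTR+Γ alignments with a focal node pinned at `island_age + offset`, so
   the whole pipeline is testable against known truth.

## Worked example

Simulate a 6-taxon island scenario (true divergence = island age = 1.0 Ma,
root 5.0 Ma, 500 sites), run both calibration schemes with two replicate
chains each, and assess:

```python
from islandclock.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_mapping({
    "outdir": "example_out",
    "seed": 1,
    "scheme": "both",
    "clock": "strict",
    "mcmc": {"n_samples": 2000, "thin": 2,
             "estimate_substitution_model": False},
    "scenario": {"n_taxa": 6, "n_sites": 500, "seed": 0},
})
run_pipeline(cfg)
```

`example_out/assessment.tsv` then contains (one row per calibrated node):

```
node               island       island_age  post_mean  hpd_low  hpd_high  kl_div  classification            scheme_diff
t1|t2|t5|t6        island       1.0         0.860      0.518    1.215     0.468   concomitant_not_rejected  0.140
t1|t2|t3|t4|t5|t6  root_anchor  5.0         5.000      4.991    5.009     0.0     concomitant_not_rejected  0.0003
```

Reading the focal row: the posterior mean age of the island-calibrated node
is 0.86 Ma with 95% HPD (0.52, 1.21); the island age 1.0 Ma lies inside the
HPD, so concomitant cladogenesis is not rejected — correct, since the data
were simulated with the split exactly at island formation. The KL divergence
of 0.47 nats says the sequence data sharpened the posterior relative to the
soft prior N(1.0, 0.4) without moving it away. The scheme difference of
0.14 Ma is how far the punctual calibration would have pinned the same node
from the soft-scheme estimate. Simulating with `divergence_offset: 1.0`
instead (true split at 2.0 Ma, twice the island age) flips the verdict to
`pre_island`.

The same stages are available from the shell:

```bash
islandclock simulate --seed 1 --n-taxa 6 --outdir sim
islandclock calibrate sim/calibrations.tsv --outdir sim
islandclock date --alignment sim/alignment.fasta --tree sim/true_tree.nwk \
    --scheme sim/scheme_normal.tsv --clock strict --outdir sim
islandclock diagnose sim/trace_scheme_normal_rep1.tsv sim/trace_scheme_normal_rep2.tsv
islandclock pipeline --config config.yaml
```

## Layout

| module | contents |
| --- | --- |
| `islandclock.phylo_io` | FASTA/relaxed-PHYLIP alignments, newick trees, calibration tables, the p-distance < 0.003 de-duplication filter |
| `islandclock.synthetic_data` | Yule trees, branch rates, GTR+Γ sequence simulation, island scenarios with known truth |
| `islandclock.calibration` | soft/punctual prior construction and densities |
| `islandclock.substitution`, `islandclock.likelihood` | GTR+Γ model and exact pruning likelihood |
| `islandclock.dating_engine` | the dating MCMC and posterior traces |
| `islandclock.mcmc_diagnostics` | ESS and two-replicate convergence gate |
| `islandclock.conflict_test` | HPD, KL divergence, classification, scheme comparison |
| `islandclock.pipeline`, `islandclock.cli` | orchestration and the `islandclock` command |

See `docs/methods.md` for the model, priors, proposal design, and known
limitations.
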