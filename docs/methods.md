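# Methods

## Model

Sequence data are a concatenated DNA supermatrix evolving site-independently
under GTR+Γ on a fixed rooted binary topology with node ages in Ma (tips at
0). The GTR rate matrix is parameterized by exchangeabilities
(AC, AG, AT, CG, CT; GT ≡ 1 as reference) and stationary base frequencies,
normalized to mean rate 1 so branch lengths are expected substitutions per
site. Among-site rate variation uses Yang's discrete-gamma approximation
with equal-probability categories represented by their conditional means
(6 categories by default, matching the GTR+G6 configuration common in the
island-dating literature). Gaps and ambiguity codes are retained and enter
the likelihood as partially missing data (conditional likelihood 1 on every
compatible state). The likelihood is the exact Felsenstein pruning sum with
per-node rescaling; no approximate-likelihood shortcut is used, because at
the tens-of-taxa scale this package targets the exact computation is cheap.

Branch rates follow either a strict clock (one rate μ, subs/site/Ma) or
independent lognormal branch rates with expectation μ and log-scale spread
σ (location log μ − σ²/2). The uncorrelated-lognormal form was chosen
because it is the standard relaxed clock of the programs this procedure is
normally run in; the clock is configurable and defaults to the relaxed form.

## Priors

* **Calibrated nodes.** Soft scheme: N(m, s) with
  s = round₀.₁(m / z₀.₉₉), z₀.₉₉ = 2.3263 — the smallest-SD normal whose
  one-sided 99% lower limit reaches the present. The one-sided reading was
  adopted because it reproduces every conventionally printed (mean, SD)
  calibration pair exactly; the two-sided quantile does not. Punctual
  scheme: hard-bounded uniform on m ± 0.01 Ma, zero density outside.
  Normal calibrations are **not truncated at zero** as densities; the
  sampler's support (node ages above child ages ≥ 0) imposes nonnegativity
  and implicitly renormalizes, which matches soft-bound practice and keeps
  the KL reference density a plain normal.
* **Uncalibrated internal nodes.** Jointly uniform over the age vectors
  compatible with the topology given the root age. Because that feasible
  region scales as (root age)^k for k free nodes, the density contributes
  −k·log(root age) plus an ordering indicator — a proper, simple prior in
  the uniform-given-root family.
* **Root, when uncalibrated.** Gamma with shape 2 and mean twice the oldest
  calibration mean: proper and weakly informative.
* **Hyperpriors.** μ ~ LogNormal(log 0.01, 1²) per Ma; σ ~ Exponential(mean
  0.3); α ~ LogNormal(0, 0.5²); free exchangeabilities i.i.d.
  LogNormal(0, 1²). All overridable. Base frequencies are fixed at their
  (smoothed) empirical values rather than sampled — they are tightly
  identified by composition and fixing them removes a slow-mixing block.

## Sampler

Metropolis-within-Gibbs, one "cycle" = one sweep over:

* each internal node age — uniform sliding window reflected into the
  (oldest child, parent) interval, so proposals are symmetric and always
  feasible;
* μ, α, one randomly chosen exchangeability, σ, and each branch rate
  (relaxed clock) — multiplicative scale moves with the log c Jacobian;
* a whole-tree scale move multiplying all internal ages by c and dividing
  μ (and the branch rates, when relaxed) by c, with Jacobian
  c^(n_internal − 1 − n_rates). Under a strict clock this move leaves every
  branch length, and hence the likelihood, exactly unchanged — absolute
  time is identified only by the calibrations, and this move lets the
  chain traverse that ridge.

Burn-in defaults to 25% of total cycles; proposal windows auto-tune toward
~35% acceptance during burn-in only, preserving detailed balance afterwards.
Sampling then records every `thin`-th cycle until `n_samples` states are
collected (defaults 10,000 samples at thin 100, two replicate chains —
the conventional regime; the test suite scales these down). Chains are
bit-reproducible from a master seed fanned out per purpose and replicate.
A proposal block that accepts nothing after tuning raises a diagnostic
error rather than silently freezing. Prior-only runs (likelihood ≡ 1) are
supported and are the main sampler-validation device.

## Diagnostics

ESS uses the trace-viewer convention: autocorrelations summed to the first
nonpositive term, ESS = n/(1 + 2Σρ̂ₖ), capped at n, undefined for constant
series. A run passes when every non-constant parameter reaches ESS ≥ 200 in
both replicates and every node-age mean agrees between replicates within
2·√(var₁/ESS₁ + var₂/ESS₂); failures report the extension factor
⌈200 / min ESS⌉. The 2-SE agreement rule is this package's concrete
criterion for the usual "two replicates to check convergence" practice; it
is ~95% per parameter under perfect convergence, so occasional retries on
honest chains are expected.

## Conflict test

The 95% HPD is the shortest contiguous interval containing ⌈0.95·n⌉ sorted
samples (Chen–Shao). KL divergence is estimated as the sample average of
log q̂(xᵢ) − log p(xᵢ) with q̂ a Gaussian KDE (Silverman bandwidth) over the
posterior samples and p the normal calibration density; negative estimates
are clamped to 0 and a hard-bounded reference is rejected (it gives
infinite KL as soon as one sample leaves the bounds). The direction
KL(posterior ‖ prior) — information gained from the data — is the default;
the flipped direction is available by configuration. Classification uses
strict inequalities against the HPD endpoints; an island age exactly on an
endpoint is conservatively not rejected. Scheme comparison reports the
per-node absolute difference of posterior means between the soft and
punctual runs.

## Synthetic data

The generator emulates the multilocus island datasets the procedure is
designed for: pure-birth (Yule) time-trees conditioned on taxon count and
rescaled to a chosen root age (the simplest ultrametric generator; the
dating model does not condition on it), strict or i.i.d.-lognormal branch
rates, root sequence from the stationary frequencies, and GTR+Γ site
simulation. A scenario pins a focal node (a child of the root) to
island_age + offset by rescaling its clade, and emits FASTA, newick, a
machine-readable truth table, and a calibration table containing the island
calibration under test plus a narrow hard-bounded anchor at the true root
age. The anchor is essential to the scenario design: sequence data constrain
only rate × time, so without an independent anchor a single island
calibration could never be contradicted by data.

Default scenario conditions: 8 taxa (6 in the scaled-down test runs),
root 5 Ma, island 1 Ma, strict clock at 0.02 subs/site/Ma, 2,000 sites,
6 gamma categories — values a desk-scale island dataset would plausibly
show. What the simulations do **not** emulate: indels (gaps appear only if
present in real input), codon structure, rate autocorrelation along
lineages, alignment error, and topology error — so passing tests certify
the inferential machinery, not robustness to misalignment or a wrong tree.

## Numerical choices

* Transition matrices via the reversible eigendecomposition
  (D^{1/2} Q D^{−1/2} symmetric), clipped at 0 for roundoff; cached across
  proposals that do not touch the substitution model.
* Site patterns compressed once; per-node likelihood rescaling keeps
  partials in double range.
* p-distance for the de-duplication rule: uncorrected, on jointly
  unambiguous columns only; a pair with no comparable columns is treated as
  distant (both kept); greedy first-kept order makes the filter
  deterministic and idempotent. At distances < 0.003 all common model
  corrections coincide to four decimals, so the uncorrected distance is the
  natural reading.
* Rounding of calibration parameters: SDs to 0.1 Ma (floor(x·10 + 0.5)
  to avoid banker's rounding), punctual bounds to 10⁻⁶ to kill float dust
  in serialized tables.
* Initial ages: calibrated nodes at their reference ages, uncalibrated
  nodes spread proportionally to subtree height below their parent —
  always feasible when the calibrations themselves are mutually feasible;
  conflicting hard bounds raise immediately.

## Problem sizes used by the test suite

Sampler validation uses prior-only chains (10,000 samples, thin 10) checked
against rejection-sampling oracles; simulation-based calibration uses 100
prior draws on a quartet at 150 sites; parameter-recovery and operating-
characteristic checks use 20 seeded replicates each of 6-taxon, 2,000-site
strict-clock datasets with 400–500 posterior samples at thin 3. These sizes
were chosen so the full suite stays a desk-scale run while keeping the
Monte-Carlo margins (3 SE, binomial counts) meaningful.

## Known limitations

* Fixed topology: no accounting for topological uncertainty.
* The uniform-given-root prior on uncalibrated ages is simple but not a
  birth–death prior; with very few calibrations deep uncalibrated nodes
  follow it closely.
* KL is estimated by KDE and is noisy below ~0.05 nats; values there should
  be read as "no detectable conflict".
* The relaxed clock is uncorrelated lognormal only; autocorrelated-rate
  models are out of scope.
* Base frequencies and the punctual half-width (0.01 Ma) are fixed by
  design, not estimated.
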