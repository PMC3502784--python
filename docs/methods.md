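# Methods

## The model

`mirmod` infers an undirected miRNA–miRNA network in which an edge means
"these two miRNAs are statistically coupled *through* a shared target
transcript". The mechanism is the sponge/ceRNA picture: an mRNA that
harbours response elements (MREs) for several miRNAs buffers them; when the
transcript is abundant the miRNAs targeting it are jointly sequestered, so
their expression becomes conditionally dependent on the transcript's level.

For a miRNA pair with expression vectors *d*, *r* over the same samples and
a candidate modulator transcript *m*, the modulation statistic is

```
ΔMI(d, r | m) = | MI(d, r) − MI(d, r | m) |
```

with MI the plug-in mutual information (in nats) on a B×B contingency
table over equal-frequency bins, and

```
MI(d, r | m) = Σ_s (n_s / n) · MI(d_s, r_s)
```

where the samples are stratified into S equal-frequency strata of *m* and
MI is re-estimated within each stratum (re-binned per stratum, same B).

Significance is empirical: *m* is permuted across samples `n_perm` times
(the pair stays fixed, so the null preserves the pair's marginal dependence
and the estimator's bias while destroying any modulator-linked structure),
and

```
p = (1 + #{ΔMI_perm ≥ ΔMI_obs}) / (n_perm + 1).
```

The add-one rule keeps p strictly positive. That matters because triplet
p-values for one miRNA pair — pooled over both orientations and all its
candidate mediating targets — are combined by Fisher's method,
`X² = −2 Σ ln p_k` against a chi-square with 2N degrees of freedom, which
is undefined at p = 0. A finite permutation set cannot produce p = 0, so no
clamping is ever needed. Pairs with combined p below α become edges.

Candidate triplets are enumerated from prior knowledge rather than all
pairs × all transcripts: for every known target edge (a, m) the anchored
miRNA *a* is paired with every other profiled miRNA. A `strict` mode
restricts candidates to pairs for which *m* is a *shared* target of both.

## Estimator policy

The statistic needs four knobs; all are explicit parameters with these
defaults, chosen for cohorts of roughly 100–200 samples:

| parameter | default | meaning |
|---|---|---|
| `bins` (B, marginal) | 3 | equal-frequency bins for MI(d, r) |
| `cond_bins` (B, conditional) | 3 | bins within each modulator stratum |
| `strata` (S) | 2 | equal-frequency strata of the modulator |
| `n_perm` | 1000 | permutations per triplet |
| `alpha` | exp(−5) ≈ 6.74e−3 | combined-p edge threshold |

Two of these deserve justification:

* **Matched bin counts.** The marginal and conditional terms must use the
  same B. Plug-in MI has upward bias ≈ (B−1)²/2n, and the conditional term
  carries S times that bias; if the marginal term uses a finer grid (say
  B=6 against B=3), its extra bias exceeds the conditional term's, and
  genuine modulation — which raises the conditional term *toward* the
  inflated marginal value — *shrinks* |ΔMI| below its own permutation
  null. In experiments with strongly modulated planted triplets that
  mismatch drives the permutation p toward 1 (the observed statistic sits
  in the null's lower tail). With matched B the residual bias gap is small
  and genuine modulation moves the statistic into the upper tail.
* **Two strata.** The sponge mechanism is a high/low dichotomy — the
  coupling differs between abundant and scarce modulator. A middle stratum
  mostly mixes the two regimes, diluting the contrast while also halving
  the per-stratum sample size. At n ≈ 139, S=2 roughly doubles detection
  power over S=3 on planted data.

Equal-frequency (rank-based) binning makes every estimate invariant under
strictly monotone transforms of any input, hence insensitive to monotone
normalization differences. Ties are broken by original index order (stable
sort), making results deterministic. No small-sample bias correction is
applied by default — the permutation null absorbs estimator bias exactly
where it matters — but Miller–Madow correction is available for
standalone MI estimates.

Permutations shuffle the modulator's *stratum labels* rather than the raw
vector. For a tie-free modulator the two are identical (equal-frequency
stratification commutes with sample permutation); the label form avoids
re-sorting and, together with a per-triplet RNG stream derived by hashing
the triplet identifiers with the master seed, makes results independent of
candidate iteration order and byte-reproducible under a fixed seed.

The α default takes the published cutoff "P < e⁻⁵" at face value as the
natural exponent. If the intended reading was 10⁻⁵, note that a pair with
a single mediating triplet can then never pass at n_perm = 1000 (its
minimum combined p is 1/1001 ≈ 10⁻³); reaching 10⁻⁵ requires several
mediating targets or more permutations. Both readings are one `--alpha`
flag away.

No multiplicity correction is applied to combined pair p-values by
default, mirroring the original fixed-threshold procedure; a
Benjamini–Hochberg option (`bh=True`) is provided.

## Comparator networks

Hub status in the modulation network could in principle reflect two
confounders, each isolated by a comparator built from the same inputs:

* **Shared-target network** — takes *only* the target table (its signature
  has no expression argument, so independence from expression is
  structural). Two miRNAs are linked when their shared-target count is
  hypergeometrically surprising: with M target mRNAs in the table and
  target-set sizes n₁, n₂ and overlap k, the edge p-value is the exact
  upper tail P(X ≥ k). The raw count is exported alongside so users can
  threshold it directly.
* **Correlation network** — Spearman correlation (rank-based, consistent
  with the MI estimator; Pearson by flag) with two-sided t p-values and
  Benjamini–Hochberg correction; |r| is thresholded, so anti-correlated
  pairs qualify.

`compare_networks` reports edge Jaccard, Spearman correlation of node
degrees over the node union, and hubs unique to either network. Reruns on
sample subsets (e.g. primary-only cohorts) are plain input filtering
(`--sample-class primary`), not a separate code path.

## Synthetic cohorts

`simulate_dataset` generates the full input bundle — paired miRNA/mRNA
matrices, a target table, class labels, survival — with planted ground
truth. Defaults emulate a matched prostate-cohort shape: 139 samples, 370
miRNAs, class proportions 29 normal / 98 primary / 19 metastatic scaled by
largest remainder.

* **True triplets.** The modulator is standard normal; samples above its
  median form the high stratum; within stratum s the pair is bivariate
  normal with correlation `coupling_s` (defaults 0.9 high / 0.0 low). A
  stratum-dependent correlation is the minimal mechanism separating
  MI(a,b|m) from MI(a,b).
* **Hub.** One miRNA participates in `hub_triplets` true triplets through
  a *single shared* modulator (one sponge transcript carrying MREs for hub
  and partners), built as a one-factor model: partner_i = ρ(s)·hub +
  √(1−ρ(s)²)·ε. Sharing one modulator is deliberate: with one modulator
  per partner, each hub pair's single informative p-value is Fisher-pooled
  with the hub's other, inert, mediating candidates and the combined
  evidence dilutes below any sensible α — a real property of the pooling
  rule worth knowing about, but not the structure the hub experiment is
  meant to probe. Remaining true triplets use disjoint fresh pairs.
* **Null triplets.** Independent miRNA pairs attached to modulators they
  do not respond to, several modulators per pair (real miRNA pairs share
  several candidate MREs). Planted on dedicated miRNAs so they are exactly
  null. Decoy target edges attach to background miRNAs only, which gives
  the shared-target comparator structure that is independent of expression
  — and keeps hub partners from anchoring candidates, since pairs of
  partners are genuinely (indirectly) modulated through the hub factor and
  would otherwise surface as "unexpected" edges.
* **Class signal.** The planted signature (all true-triplet miRNAs) is
  shifted down by `class_effect` (default 1.5 sd) in tumor samples —
  tumor-suppressor-like behaviour.
* **Survival.** Samples are split at the median of the signature's mean
  expression; the low-expression half is high-risk, gets an additional
  `risk_effect` (default 1.0 sd) downward shift (a silenced-signature
  subtype, which also makes the risk groups a recoverable cluster
  structure), and exponential event times with hazard
  `baseline_hazard × hazard_ratio` (defaults 0.02/month × 4.9, the
  planted effect size) against 0.02 for the low-risk half, under uniform
  administrative censoring over 30 months (≈45% events).
* **Noise.** Gaussian `noise_sd` (default 0.2 sd) added to every feature
  last. Noise on the *modulator* blurs its high/low stratum assignment,
  so realized stratum couplings are attenuated relative to nominal.

A fixed seed fixes the entire output bit for bit. What the generator does
*not* emulate: count-based sequencing noise, probe effects, batch
structure, copy-number or methylation covariates, and target tables with
realistic degree distributions. Passing tests therefore demonstrate that
the machinery recovers the planted mechanism at realistic n — not that
any particular biological network is correct.

## Validation experiments

The test suite runs these experiments end to end (sizes chosen to probe
the stated conditions at desk scale):

* **Estimator exactness** — vectorized MI equals a nested-loop oracle to
  1e−12 over random inputs (n=60, B ∈ 2..5); closed forms: MI(x,x)=ln B
  on tie-free input, and the XOR triplet (balanced cells, b = a XOR m)
  where marginal MI is exactly 0 and conditional MI exactly ln 2.
* **Calibration** — 500 independent null triplets at n=139, n_perm=200:
  rejection at α=0.05 inside the exact binomial 99% band, p-values pass a
  KS uniformity test; planted-null triplets from the generator behave the
  same.
* **Recovery** — cohort with 10 true triplets (couplings 0.9/0.0, planted
  exactly: `noise_sd=0`, `class_effect=0`, `risk_effect=0`, so no
  attenuation or confounding shifts), 50 planted nulls over 10 pairs, a
  6-triplet hub, 40 decoys, 40 miRNAs × 80 mRNAs, n=139, n_perm=1000,
  α=exp(−5), seed 0: all 10 true pairs recovered, no planted-null pair
  edges, hub is the top-degree node; the shared-target comparator shares
  (essentially) no edges with the modulation network.
* **Signature evaluation** — planted class signal on the full 370-miRNA
  panel: the signature's SVM accuracy (linear kernel, C=1, stratified
  5-fold CV) beats all 200 random same-size signatures, so its empirical p
  sits at the add-one floor 1/201; the planted hazard ratio 4.9 falls
  inside the Cox fit's 95% CI in ≥90 of 100 simulated cohorts; log-rank p
  is uniform when both risk groups share one hazard.
* **Determinism** — the CLI pipeline (simulate → infer → compare →
  evaluate) is byte-identical across two runs with the same seed.

`scripts/acceptance.py` re-runs this battery from scratch at a
user-supplied seed and writes the measured numbers as JSON.

## Numerical and degenerate-input policy

* MI cell sums use exactly-rounded summation (`math.fsum`), so MI is
  symmetric in its arguments to the last bit.
* Zero-count cells contribute zero to MI; constant (zero-variance) vectors
  are rejected at discretization.
* Conditional MI requires every modulator stratum to hold at least 2·B
  samples; `SimulationConfig` refuses cohorts under 20 samples for the
  same reason.
* Missing values are rejected at parse time — the estimator has no
  missingness contract; impute upstream if needed.
* Sample alignment canonicalizes to lexicographic order so permutation
  streams reproduce regardless of input column order; identifier matching
  is exact string match (no alias resolution).
* k-means risk splits use 50 restarts under a fixed seed; the high-risk
  label is oriented to the lower-mean-signature group. A group whose
  follow-up times are all zero is rejected as degenerate; a non-convergent
  multivariate Cox fit is flagged in the result, not fatal.
* Fold changes are ratios of class means on positive-scale data, or
  2^(Δmean) under the log-scale flag (log2 convention); nonpositive means
  in ratio mode raise an error that points at the flag.

## Known limitations

* The plug-in estimator at B=3/S=2 has limited power for weak modulation
  (|Δρ| ≲ 0.3) at n ≈ 139; the permutation keeps it honest but cannot
  create information.
* Fisher pooling assumes triplet p-values for a pair are independent;
  triplets sharing a pair reuse the same expression vectors, so the
  combined p is approximate when one pair has many mediating targets.
* Edge significance is marginal per pair (no FDR by default, mirroring
  the original procedure); at genome scale the fixed threshold implies a
  nontrivial number of false edges, which the `bh` option addresses.
* The permutation engine is exact but serial: genome-scale runs
  (thousands of target edges × 10³ permutations) are hours of CPU, not
  minutes.
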