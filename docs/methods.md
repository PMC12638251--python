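# Methods

This note documents the models and procedures implemented in `screendelta`,
their assumptions, the parameters that matter, the numerical choices, and
what the synthetic-data tests do and do not establish about real data.

## Screen scoring model

**Procedure.** Counts → RPM → per-guide log2 fold change against the day-7
baseline → gene scores (mean over guides, then mean over infection
replicates, per condition) → empirical null from low-expression genes →
per-condition z-scores → ΔZ = Z(minus) − Z(plus), ranked ascending.

**Assumptions.** (i) Low-expression genes (TPM < 1 by default) have no true
fitness effect, so their gene-score distribution estimates the noise
distribution of a null gene; (ii) guide effects combine additively in log
space, so averaging LFCs over guides and replicates is the right location
estimator; (iii) library composition is stable enough that RPM
normalization removes depth differences without distortion.

**Parameters.**

| parameter | default | units | rationale |
|---|---|---|---|
| `pseudocount` | 1 | RPM | guards log2(0); added inside both log terms. Configurable because published analyses often leave it unstated. |
| `tpm_threshold` | 1 | TPM | conventional cutoff for "not expressed"; genes below it define the null and are withheld from ranked outputs. |
| baseline pairing | per-replicate | — | an endpoint sample is compared against the day-7 sample of its own infection replicate when one exists, else against the pooled baseline mean. Mirrors the replicate structure of the averaging step. |
| null s.d. | unbiased (n−1) | log2 | correct for small null sets; the alternative is a one-line change. |

**Conventions.** Control (non-targeting) guides stay in RPM totals —
removing them would silently rescale every other guide — but never enter
gene scores. Guides with zero counts everywhere are dropped with a warning
before normalization. Genes absent from the expression table are treated as
expressed (never allowed into the null) with a warning. All rankings break
ties lexicographically by gene id, so output order is platform-independent.
Constant null scores (σ = 0) and null sets smaller than two genes are
errors, not silent degeneracies.

**Calibration caveat.** The null mean and s.d. are estimated from the
low-expression genes; with *n* null genes the expressed-gene mean Z
inherits a shared offset of s.d. ≈ 1/√n (in Z units) from that estimate —
about ±0.06 at n = 300. Interpreting small global shifts of the Z
distribution (|mean Z| ≲ 0.1) as biology is therefore unwarranted; the
per-gene ranking is unaffected because the offset is common to all genes.

## Preranked enrichment engine

**Statistic.** Walking the ranked list from the most positive statistic
downward, hits raise the running sum by |stat|^p normalized to unit total
hit mass, misses lower it by 1/(N − N_hits); ES is the deviation of maximum
magnitude. `weight_p = 1` is the default (weighted statistic, matching the
default of the widely used desktop tool); `weight_p = 0` gives the classic
unweighted Kolmogorov–Smirnov statistic and makes ES invariant under
strictly monotone transformations of the statistic. With this walk order a
set concentrated among the most negative statistics — the conditionally
*required* genes or *depleted* metabolites — receives a negative ES, so
"negatively enriched" reads as "required/depleted".

**Null.** Preranked data admit no phenotype permutation; the null is random
same-size item sets drawn from the ranked universe with a seeded generator,
shared across query sets of the same size. NES divides ES by the mean |ES|
of same-sign null scores; when no same-sign null score exists at the chosen
permutation count, NES is reported missing with a warning, never
fabricated. The nominal p is the fraction of the null at least as extreme
in the observed direction (over the *whole* same-size null, so an
exhaustively enumerated singleton observed at the top of a 4-item list gets
p = 1/4). FDR q uses the NES-histogram ratio estimate — fraction of pooled
null NES at least as extreme divided by the fraction of observed NES at
least as extreme, per sign, clipped to [0, 1]; Benjamini–Hochberg on
nominal p is available via `fdr_method="bh"`.

**Numerical choices.** The vectorized ES evaluates the running sum only at
hits (candidate maxima) and immediately before hits (candidate minima),
which provably contains the extremum; when the positive and negative
extrema tie in magnitude the positive sign wins, deterministically. ES
comparisons in p-values use a 1e-12 slack: exact ties are *structural*
(every set whose hits all precede the same number of misses scores exactly
1 − m/N_miss) and must not be split by floating-point accumulation order.
Exhaustive enumeration is available (`exhaustive=True`) and guarded above
200,000 combinations.

**Set filtering.** Sets are first intersected with the ranked universe,
then kept iff the used size lies in [min, max]. Typical settings: gene
sets 2–50, curated mitochondrial sets min 15, metabolite sets 3–500.

**Metabolite-set database.** `build_metabolite_db` converts a pathway
membership table (pathway, compound id) into sets keyed by pathway name
with items translated to the names under which metabolites were measured;
measured names without a compound id are excluded and reported, one
measured name mapping to two compounds is an error, and manually curated
sets (e.g. separating mature purines/pyrimidines from their de novo
intermediates) are appended last, overriding on collision with a warning.
The membership table is an input, not a bundled snapshot — pathway
databases are versioned resources the user supplies.

## Targeted-omics statistics

**CV filter.** CV = unbiased s.d. / mean of raw QC intensities per feature;
features above `max_cv` (default 0.30) are discarded, features with fewer
than two present QC values are discarded with the distinct reason
"insufficient QC coverage". Computed pre-log because analytical
peak-area variability is conventionally expressed that way; the filter is
scale-invariant and idempotent.

**Differential abundance.** Two-sided two-sample t-test per feature,
equal-variance by default ("Student's"; Welch via `equal_var=False`), on
log2-transformed values by default, with BH correction across tested
features. Features with fewer than two present values in either group are
reported untested; groups that are both constant at different means have no
finite t — p is reported missing with a "degenerate variance" flag rather
than a fabricated 0 or 1 (identical constant groups are the no-evidence
case, p = 1). Missing values are handled pairwise-complete: no imputation
happens inside the test, keeping the metabolomics pipeline (filter → test)
and the proteomics pipeline (filter → impute → test) each faithful to its
own convention.

**Detection filter.** Keep a feature iff at least one group has ≥
`min_present` present values — `min_present=4` for global proteomics,
`min_present=2` for affinity-purification runs.

**Imputation.** Missing log-scale values draw from
Normal(mean_s − shift·sd_s, (width·sd_s)²) with per-sample statistics
(per-matrix via `per_sample=False`), defaults width 0.3 and shift 1.8 —
emulating left-censored label-free intensities. Present values are
untouched bit-exactly; the draw is seeded; a sidecar log records every
imputed cell. A sample with fewer than two present values has no s.d. and
is an error.

**Contaminant filter.** Keep a candidate interactor iff it was detected in
every bait replicate *and* its average spectral score in a contaminant
repository is ≤ 2.5 (strictly above excludes; unknown features count as
score 0).

**Isotopologues.** fraction_k = abundance(m+k) / Σ_j abundance(m+j) per
metabolite and sample; missing isotopologue rows count as zero abundance
and an all-zero vector yields missing fractions. Fractions sum to one and
are invariant to common rescaling.

## Synthetic data

**Screen generator.** Guide abundance follows
n_g(t) = n_g(0)·2^((r + e + δ_g)·t): common growth r (1 doubling/day),
condition-specific per-gene deficit e ≤ 0, and guide-efficiency jitter
δ_g ~ N(0, 0.01²) per day, shared across replicates and conditions (a
guide's efficiency is a property of the guide). Initial cells per guide are
Poisson at the plating coverage, independent per infection replicate.
Baseline counts are taken at day 7, endpoint counts at day 28 (21 days of
selection); reads are multinomial at exact per-sample depth (default mean
500 reads/guide), with an optional gamma-dispersion knob for
overdispersion studies. Defaults mirror the screen design the pipeline
targets: 4 guides/gene, 500 cells/sgRNA at plating, duplicate infections,
two media conditions. Null-class genes receive TPM < 1 and all others
TPM ≥ 1 by construction, so the null-gene contract is exact. Passaging
bottlenecks, infection multiplicity, cutting efficiency and off-target
effects are *not* modeled; time is continuous.

**Metabolome generator.** Per-feature base abundance is lognormal (log2
level ~ N(14, 2)); group effects multiply by 2^effect; per-sample
analytical noise is lognormal with s.d. 0.25 on the log2 scale (so t-tests
on log2 values are exactly calibrated under the null); QC injections
scatter around the per-feature grand mean at a configured analytical CV
(lognormal with σ = √log(1+CV²), which reproduces the target CV exactly in
expectation); values are censored missing with logistic probability in
their log2 abundance to exercise the imputation path.

**What passing tests show — and don't.** The closed-loop tests establish
that the scoring pipeline is correctly calibrated and powerful *under the
generator's assumptions* (exponential selection, multinomial reads,
lognormal abundances, independent features). Real screens add
copy-number artifacts, variable cutting efficiency and bottleneck noise;
real metabolomes add correlated features, batch drift and heavy-tailed
analytical error. Passing here verifies the statistics, not those data
pathologies.

## Problem sizes

The shipped test suite and the acceptance script run the calibration and
recovery checks at 2,300 genes × 4 guides (≈9,200 guides, 6 samples,
≈4.6 M reads/sample), the enrichment power check at 1,000 ranked items ×
1,000 permutations, and the differential checks at 2,000 features (4 vs 4);
unit tests use smaller instances of the same generators. These sizes were
chosen to make every distributional check statistically meaningful while
keeping the full suite interactive (well under a minute per check).

## Known limitations

- The empirical-null mean carries a 1/√n_null shared offset (see above);
  with a few hundred null genes, global Z-shifts below ~0.1 are not
  interpretable.
- The GSEA-style FDR is a ratio estimator; with very few query sets it is
  coarse (it can only take a handful of values) — prefer `fdr_method="bh"`
  when scoring fewer than ~10 sets.
- The permutation null draws item sets uniformly, ignoring inter-gene
  correlation; as in the desktop tool, q-values are anti-conservative when
  set members are strongly co-expressed or co-fit.
- `differential` assumes (log-)normal within-group noise; with n = 4 per
  group the t-test is not robust to heavy tails — the simulator's exact
  calibration does not promise calibration on heavy-tailed real data.
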