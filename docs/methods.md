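# Methods

## Problem and model

`cnvmeta` implements a stratified case/control meta-analysis of rare copy
number variants (CNVs) called from heterogeneous genotyping-array cohorts.
The analysis treats *carrier status* — whether a sample carries at least
one qualifying CNV matching a predicate (type, locus, gene set, size or
constraint class) — as the unit of comparison, and conditions every
comparison on the stratum a sample belongs to: the unique combination of
array group, genetic-ancestry cluster, and sex. Stratification is the
core defense against confounding, because array platform, ancestry
composition and sex ratios all differ between the contributing cohorts
and all influence CNV call rates independently of phenotype.

### Call and sample QC

Array CNV calls are noisy, and the filter cascade encodes the standard
defenses:

* **Sample intensity QC.** Within each dataset, a sample is an outlier if
  any of the PennCNV-style intensity metrics (LRR SD, BAF drift, GCWF)
  lies more than 3 SD from the dataset *median* of that metric (the SD is
  computed across the dataset; centering at the median resists the very
  outliers being hunted).
* **Raw-call caps.** Dense arrays (610K, GSA) tolerate up to 30 raw calls
  per sample; the sparser OmniExpress group is capped at 15; both cap the
  raw footprint at 20 Mb. Samples beyond the caps are removed wholesale.
* **Qualifying calls**: >= 10 probes, 30 kb–20 Mb (inclusive bounds),
  autosomes 1–22 only.
* **Analysis-grade calls**: qualifying calls additionally > 100 kb
  (strict) with >= 15 probes. Burden and association tests use only
  these; probe densities on the contributing arrays make smaller calls
  unreliable. Tie semantics at every boundary are stated in the filter
  docstrings and pinned by tests.
* **Biobank-profile QC** (for external PennCNV-style callsets): LRR SD
  < 0.3, BAF drift < 0.01, |WF| < 0.05; <= 50 calls and no call > 20 Mb
  per sample; adjacent same-type calls merged when the gap is below 20%
  of the span the merge would create (scanned left-to-right to a fixed
  point, so a merge can enable the next one); calls overlapping
  centromere/telomere/blacklist regions by >= 1 bp discarded; calls whose
  locus (same type, >= 50% reciprocal overlap) is carried by >= 1% of
  samples removed.

The 50% reciprocal-overlap rule is this package's definition of "the same
CNV" wherever locus identity is needed (frequency filtering, singleton
marking); it is a design choice, configurable at the call sites.

### Stratification

Ancestry clusters are Louvain communities on an unweighted, symmetrized
k-nearest-neighbour graph (k = 15) built from the first six genotype
principal components, which are consumed as input (PCA on LD-pruned
genotypes is upstream of this package). Cluster labels are deterministic
given the seed and stable under sample reordering up to relabeling. A
stratum enters the analysis only with >= 5 cases *and* >= 5 controls and
a case fraction within [0.10, 0.90] (inclusive); samples in failing
combinations are reported as dropped, never silently discarded.

### Burden tests

Per-sample burden under a metric spec is the count of analysis-grade
calls satisfying every predicate. A call counts toward a pLI bin or gene
set only when it overlaps >= 1 *protein-coding* base of a member gene —
intronic overlap never counts. Two complementary tests are run per
metric:

* logistic regression `status ~ burden + GROUP + LRR_SD + n_cnv_raw`,
  with GROUP the stratum label as categorical indicators, LRR SD and the
  raw call count absorbing residual intensity-quality differences; the
  reported OR is `exp` of the burden coefficient with a Wald CI;
* a Cochran–Mantel–Haenszel (CMH) test of carrier status across strata.

Constant burden or separation raises an explicit non-identifiability
error rather than emitting a runaway estimate; zero-variance nuisance
covariates are dropped (they are collinear with the intercept).

### The CMH kernel

For stratum *i* with 2x2 carrier table (a_i, b_i; c_i, d_i), n_i total:

* score statistic: `(Σ_i (a_i − E[a_i]))² / Σ_i Var(a_i)` with the
  hypergeometric moments, referred to chi-square(1), two-sided; no
  continuity correction by default (a flag is provided);
* common OR: Mantel–Haenszel `Σ(a_i d_i/n_i) / Σ(b_i c_i/n_i)`;
* CI: Robins–Breslow–Greenland variance of the log OR.

Strata with a zero margin contribute nothing to the score or variance
(they carry no information about the OR); a locus with only degenerate
strata is flagged with p = 1, never dropped. With a single stratum the
statistic reduces to the unstratified 1-df score test, a property the
tests assert at machine precision, and the whole kernel is checked to
1e-8 against statsmodels' `StratifiedTable` and an independently coded
textbook implementation.

### Genome-wide significance by min(P) permutation

Loci are either protein-coding genes (carrier = coding-sequence overlap)
or 200 kb windows advancing in 10 kb steps (carrier = >= 1 bp overlap),
the window scan making the test robust to the differing probe layouts of
the source arrays. Deletions and duplications are tested separately, and
each of the four test families (gene/window x DEL/DUP) gets its own
permutation null: case/control labels are reassigned uniformly at random
*within each stratum* (stratum case counts, and hence the conditioning,
are preserved), all locus p-values are recomputed, and the minimum is
recorded per iteration (default 10,000). The genome-wide threshold is
the k-th smallest minimum with k = max(1, floor(alpha * n_perm)) — the
conservative side of the alpha-quantile. FWER-adjusted p-values use the
(r + 1)/(n + 1) convention, which keeps them valid at any n_perm.
Adjusted p-values are finally doubled (capped at 1) to account for the
two testing rounds (deletions and duplications); the doubling is applied
after FWER adjustment.

External cohorts available only as per-stratum summary counts are
concatenated onto the internal tables as additional strata (a test
verifies the merged CMH equals the directly computed one). Their labels
cannot be permuted, so their score and variance contributions are held
fixed across permutation iterations — a conservative treatment, since
frozen strata contribute signal to the observed statistic but no
variability to the null.

Calibration is monitored with the genomic inflation factor: each raw p
is mapped to its implied 1-df chi-square quantile and lambda is the
median of these over the null median (~0.455).

Permutation internals: within a stratum the per-locus carrier totals are
fixed margins, so each locus's expectation and variance are permutation-
invariant; an iteration only needs the case-carrier counts, computed as
one {0,1}-matrix product per stratum per chunk of iterations. This makes
10,000 iterations over hundreds of loci a sub-second operation at the
cohort sizes used here.

## Synthetic cohorts

The generator emulates the structure the analysis conditions on:
strata with their own sizes, baseline Poisson call rates and intensity
models; log-normal call lengths (median 150 kb, sigma 0.5, so both the
qualifying and analysis-grade filters bite); probe counts from an
array-like density of one probe per 6 kb; and planted risk loci whose
carrier status is Bernoulli with control frequency f and case frequency
f·OR/(1 − f + f·OR), so the true *carrier odds ratio* is exactly the
configured OR. Carriers receive one call spanning the locus with
uniformly jittered boundaries (default up to 20 kb per side), mimicking
array breakpoint uncertainty. Background calls are placed uniformly,
independent of genes and phenotype. PC matrices place ancestry clusters
at well-separated centroids with unit noise.

What the generator does *not* emulate: probe-level intensity signal, GC
waves, genomic hotspots of recurrent CNVs (segmental duplications),
relatedness, or length/frequency correlations of real CNVs. Passing
tests therefore demonstrate the statistical machinery under the stated
sampling model, not robustness to raw-intensity artifacts.

### Choosing scenario magnitudes on a compressed genome

Toy genomes here are ~1000x smaller than a human genome while call
lengths and window sizes stay realistic, so per-window carrier
probability — call rate x (call length + window)/genome — is the
quantity that must be matched to the regime being emulated, not the
per-genome call count. Three scenarios follow from this:

* **Planted-locus recovery** (300 windows, 2 strata x 1000+1000,
  control carrier frequency 0.005, OR 10): baseline rate 0.01
  calls/sample puts background per-window carrier probability at ~5e-4,
  the ultra-rare regime; at higher background the background carriers
  (present equally in both arms) dilute the MH OR at the planted window
  toward the null and its CI would not be expected to cover the true OR.
  Power and localization are assessed to within the breakpoint jitter
  (locus +- 20 kb), because windows overlapping only the jittered fringe
  of the carrier calls can tie or marginally beat the exact planted
  window on raw p.
* **FWER calibration** (300 windows, 2 strata x 125+125, rate 2.0):
  moderate carrier density keeps the permutation p-values
  near-continuous; heavy ties at sparse counts make the empirical FWER
  conservative rather than anti-conservative, but also uninformative.
* **Confounding demonstration** (22 chromosomes x 1.5 Mb,
  non-overlapping 200 kb windows; two strata of 2000 with case fractions
  0.2/0.8 and baseline rates 16/24): the inflation-factor diagnostic
  presumes the chi-square approximation, which needs expected carrier
  counts in the tens per stratum arm, and a lambda estimate within +-0.1
  needs on the order of a thousand effectively independent windows —
  more than one toy genome holds (adjacent windows are correlated over a
  call-length scale), so lambda is computed over 48 replicate cohorts.

These magnitudes are properties of the validation scenarios, fixed in
`cnvmeta.benchmarks`, and derived from the count/variance calculations
above.

## Numerical and degenerate-input choices

* p-values are clipped into (0, 1]; a degenerate test reports p = 1 with
  a flag.
* MH OR is 0 when carriers appear only among controls, infinity when
  only among cases (CI undefined in both cases).
* Chromosomes shorter than the window emit one clipped whole-chromosome
  window, so toy genomes remain scannable.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; scenario sub-seeds are spawned via
  `SeedSequence` so replicates are independent but reproducible.
* Fixture files format floats with fixed precision, making writes
  byte-identical across runs and platforms.

## Known limitations

* The frequency filter's O(pairs-within-chromosome) scan and the
  pure-Python call simulator are sized for cohorts of tens of thousands
  of calls, not biobank-scale millions.
* The permutation null treats external summary strata as fixed; if
  external cohorts carried systematic artifacts, the threshold would not
  reflect them.
* No relatedness handling, no BAF-based call validation, and no CNV
  calling: the package starts from called CNV segments.
* The logistic burden model assumes independent samples and a correctly
  specified linear effect of the burden count on the log-odds.
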