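# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations of `inbredscan`, in the spirit of a statistical package's
methods documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Experimental design being modelled

Four inbred lines (`a`–`d`), each founded from one outbred couple and
sib-mated for 8 generations into independent sublines. Pupa productivity
(pupae per female after 14 days, 3 replicate vials per subline, 70 control
vials) quantifies depression; from each line the 3 most- and 3
least-depressed sublines plus 3 outbred controls are expression-profiled:
27 arrays, 24 inbred. Expression values are RMA-style log2 intensities; the
pipeline consumes an already-normalized matrix and never performs
normalization or present-call filtering.

## Sequential Grubbs scan

Per probe and direction the statistic is G = (x̄ − x₍min₎)/s (down) or
(x₍max₎ − x̄)/s (up), with s the n−1 standard deviation, tested against the
exact Student-t construction G_crit = ((n−1)/√n)·√(t²/(n−2+t²)),
t = t₍α/(kn), n−2₎ (k = 1 one-sided, 2 two-sided). Detected outliers are
removed and the mean/SD recomputed before re-testing (sequential, not
masked-in-place), up to `max_outliers` (default 3) calls. Conventions:

- One-sided tests per direction are the default (`sidedness="one"`), because
  up- and down-regulation are scanned and reported separately; a two-sided
  mode is available. Which convention the original analysis used is not
  derivable from its description, so both are exposed.
- Eligible samples default to the 24 inbred sublines; controls can be added
  with a flag but never carry (line, level) codes.
- Ties at the extreme break to the first sample in sheet order
  (`numpy.argmin`/`argmax` semantics), deterministically.
- Constant (zero-variance) probe rows yield no calls in the scan; the scalar
  `grubbs_statistic` raises `DegenerateDataError` instead, since a caller
  asking for the statistic of a degenerate vector should hear about it.
- No multiplicity correction is applied inside a probe's sequential chain
  beyond the α/n Bonferroni built into G_crit; family-wise control over
  probes is delegated to the randomization test.
- G > G_crit (strict) emits a call; with continuous data equality has
  probability zero.

## SL-LD classification

A probe is a *single line–level of depression* (SL-LD) outlier at order n if
its first n sequential calls (by order) all fall in one (line, level) cell.
Default `mode="at_least"`: a probe with 3 calls is still eligible for the
2-outlier analysis through its top-2 calls, matching the reading that the
"two most extreme expressions" define the pair; `mode="exact"` restricts to
probes with exactly n calls. Probes whose top calls include a control are
excluded — controls have no codes and can never form an SL-LD coincidence.

## Randomization test

Significance of the observed SL-LD count uses code relabeling: each of the
(default) 10000 replicates draws a uniform random permutation assigning the
24 (line, level) codes to the 24 inbred sublines, holds every probe's
outlier-sample identities fixed, and recounts coincidences. Because one
permutation is applied to all probes simultaneously, the between-probe
correlation of outlier patterns is conserved. Outlier calls are *never*
recomputed inside a replicate. p_total is the plain proportion of replicates
whose count reaches the observed total (so an observed count of 0 gives
p = 1); the (b+1)/(R+1) correction is available behind `add_one` but off by
default. For the most-depressed-only comparison, `most_comparison="total"`
(default) compares the observed most-level count against the replicate
distribution of *total* counts — conservative by construction, since the
replicate total is stochastically larger than either level's share; the
alternative `"half"` compares against half the replicate total. Both
readings are recorded in the result object because the original figure
legend is ambiguous about this construction.

On a toy design of 2 lines × 2 levels × 2 sublines with a single
coincident-pair probe, exact enumeration gives expected count and p of 1/7
(the second code lands in the first's 2-subline cell with probability 2/14);
the test suite checks convergence to this value.

## Calibration, and why the study conditions are not a null

The relabeling test's null hypothesis is that the codes are exchangeable
across sublines. The study conditions themselves violate this even with no
planted effects: within-line expression variance is higher in most-depressed
sublines (0.086) than least-depressed ones (0.044), so per-probe outliers
concentrate in most-depressed sublines and coincide in their cells more
often than randomized codes predict — in *both* directions of expression
change. Simulations at the study conditions therefore show SL-LD counts
above the relabeling expectation even for "null" probes; this is a real
level-associated signal, correctly detected, not a bug. Consequently:

- Type-I calibration is assessed on data generated under the test's own
  null: `null_calibration_config()` sets both inbred groups to the pooled
  within-line variance (0.044 + 0.086)/2 = 0.065 and plants nothing. Under
  those conditions the rejection rate at 0.05 over 200 simulations falls
  within the exact binomial 99% interval (the test is mildly conservative
  because the count statistic is discrete).
- Under the study-condition generator, the up-direction randomization test
  is anti-conservative (the acceptance suite documents this as an expected
  failure of the "up never significant" property). The original study's
  non-significant up-regulation result suggests its variance excess was
  carried by a subset of dysregulated probes rather than a uniform
  per-probe inflation; the generator deliberately keeps the simpler stated
  per-group model rather than inventing an unpublished mixture.

## Synthetic-data generator

What it emulates, and the defaults (all overridable in `SimulationConfig`):

- **Design**: 4 lines × 2 levels × 3 sublines + 3 controls (27 samples).
- **Null probes**: Gaussian on the log2 scale around `baseline_mean` (8.0,
  a typical mid-range log2 intensity) with per-group standard deviations
  √0.028 / √0.044 / √0.086 (controls / least / most), the study's printed
  within-line variances. RMA-style per-probe values are approximately
  Gaussian, so heavier-tailed options are deliberately omitted.
- **Correlation**: exchangeable blocks of `block_size=50` probes with
  correlation `block_rho=0.3`, via a shared per-block factor. The magnitude
  of between-probe correlation is not published; 0.3 is a free parameter
  chosen once to make the correlation-preserving feature of the
  randomization test consequential, and is flagged as such.
- **Planted effects**: additive shifts δ applied to whole sublines of one
  cell (a fixed genetic alteration, not per-array noise). The default
  plants the headline-like pattern: 14 down-regulated probes, 6/3/2/3 in
  lines b/c/d/a, all in most-depressed cells, δ = −2.0 log2 units, 2
  affected sublines each (exercising the two-outlier case), with each
  line's probes sharing one correlation block (common regulation).
- **Probes**: 9000 by default, near the 9133 retained in the original
  analysis.
- **Productivity**: per-subline means Normal(34.28, sd 12.0) truncated at
  0.5, 25 sublines per line, 3 replicate vials with CV 0.2; 70 control
  vials Normal(101.97, CV 0.2). The subline SD was chosen once so the
  per-subline depression rates span roughly the printed 0.64–1.4 range;
  CV 0.2 reproduces the printed control standard error (±2.39 over 70
  vials ⇒ SD ≈ 20 ≈ 0.2·101.97).
- **Determinism**: all draws derive from `numpy.random.default_rng` seeded
  by `SeedSequence([seed, k])` with distinct stream keys for expression and
  productivity; identical config + seed gives bit-identical outputs.

What it does **not** emulate: pedigrees/genotypes across the 8 generations,
probe-level (CEL) intensities, array batch effects, heavy-tailed or
probe-specific variance heterogeneity, and any linkage between the
expression design's chosen sublines and the productivity table's subline
identities. Passing tests on this generator therefore demonstrate the
pipeline's statistical behaviour under the stated Gaussian model, not
robustness to real-array artefacts.

## Depression metrics

IDR = (W_O − W_I)/(F·W_O), per unit F (read ×100/100 as % per 1% F). W_O is
the pooled control-vial mean; W_I the mean of per-subline means. F defaults
to the study's stated 0.7. The full-sib recurrence
F_t = (1 + 2F₍t−1₎ + F₍t−2₎)/4 is provided as a documented utility — it
gives F₈ = 0.826 for pure sib mating and ≈ 0.762 with a switch to
ΔF = 1/(2N_e), N_e = 4 (two males × two females) after generation 4 —
neither of which reconciles exactly with the stated "about 0.7", so the
constant, not the recurrence, feeds the IDR default. Extreme-subline
selection ranks sublines by mean productivity, with an explicit numeric
`min_viable` threshold standing in for the qualitative "enough individuals"
filter (default: no filter, keeping synthetic tests deterministic), and
ties breaking by subline id.

## Candidate characterization

Pairwise Pearson correlations are computed over all 27 samples (r) and
after removing the named outlier sublines (r′); the removal set may have
any size (three sublines where outliers span three). Each pair is tested
with t = r·√((n−2)/(1−r²)) against Student t with df = n−2 — df = 25 for
the full design, 23 after removing two sublines — two-sided, with
Benjamini–Hochberg step-up control over the unordered pairs at 0.05 (via
`statsmodels.multipletests`); |r| = 1 maps to p = 0. Clustering uses the
distance 1 − |r| with complete linkage (scipy); gene order is sorted
lexicographically before linkage so distance ties resolve
deterministically, and merge heights are non-decreasing by the linkage's
monotonicity. Cluster support is the plain bootstrap proportion: samples
(columns) resampled with replacement, default 1000 times, a node supported
when a replicate tree contains its exact leaf set; single-gene leaves have
support 1 by convention. Multiscale-bootstrap "approximately unbiased"
p-values are intentionally not implemented; BP is reported instead. A gene
that becomes constant in a bootstrap replicate contributes correlation 0
there rather than aborting the replicate. Whether the original dendrogram
used all 27 samples or inbred-only is unstated; all 27 is the default.

## Interchange formats and validation

All tables are plain TSV (decimal points, no thousands separators), probes
in rows and samples in columns for matrices, with `#` comment lines carrying
package version, seed, and a config hash (computed over analysis parameters,
excluding the output directory, so re-runs into different directories remain
byte-identical). Missing values in expression matrices are rejected, not
imputed — the normalized input is complete by construction. Sample roles and
depression levels are a lowercase controlled vocabulary; unknown tokens are
errors. Matrix/sheet cross-validation rejects any sample present in exactly
one of the two files. Result tables round-trip through their readers at
`%.12g` float precision.

## Problem sizes used by the test suite

The suite exercises the full study scale where the statistics demand it
(9000-probe simulations; 10000 randomization replicates for the power
check; 200 × 1000 replicates for calibration; 10000 Monte-Carlo rows for
generator checks) and smaller scales (hundreds of probes, hundreds of
replicates) where only structural behaviour is under test. The whole suite
completes in well under a minute on one CPU.

## Known limitations

- The published real-data candidate counts (14 SL-LD probes at α = 0.05;
  9 up / 24 down three-outlier probes) are not reproduced here: they
  require the deposited GEO series (GSE47176) plus RMA and present-call
  preprocessing. They are kept as flagged reference constants only.
- The randomization test inherits the anti-conservativeness described above
  whenever within-group variances genuinely differ by level; its p-values
  test code exchangeability, not "no mean shift".
- Grubbs-based scanning assumes per-probe Gaussianity; heavy-tailed
  expression would inflate outlier calls (robust median/MAD variants are
  out of scope).
- Bootstrap proportions are known to be biased estimates of cluster
  confidence relative to multiscale-bootstrap corrections; they are used
  for ranking support, not as calibrated probabilities.
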