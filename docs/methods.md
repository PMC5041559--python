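# Methods

## Problem and scope

`promopanel` reimplements, as a tested pipeline, a biomarker-discovery
workflow for discriminating the two major non-small-cell lung cancer
subtypes — squamous cell carcinoma (SCC) and adenocarcinoma (AD) — with a
focus on the histologically ambiguous pair: poorly differentiated SCC
(PDSCC) and AD without a lepidic component (non-lepidic AD). The workflow
has two halves:

1. **Promoter screening.** CAGE-like promoter-activity count matrices
   (regions × samples) are QC'd, CPM-normalized, filtered for inactivity,
   embedded by MDS, and screened for candidate marker promoters between two
   subtype groups with a negative-binomial exact test, Benjamini–Hochberg
   FDR control and fold-change/expression thresholds, plus a
   complete-separation screen for promoters whose expression ranges in the
   two groups are disjoint.
2. **IHC evaluation.** Ordinal immunohistochemistry scores (0/1/2) are
   binarized (positive iff score 2), per-marker diagnostic performance is
   computed with exact Clopper–Pearson 95 % CIs, two-marker
   definitive-diagnosis panels are searched exhaustively, and samples and
   markers are clustered by average linkage on binary profiles.

Because no public accession accompanies the study, a synthetic-data module
generates cohorts with known ground truth; it is first-class, tested code.

## Count model and the synthetic cohort

Counts are negative binomial with common dispersion φ:
`count_rj ~ NB(mean = L_j · a_r · f_rj, var = μ + φμ²)`, where `L_j` is a
log-normal library size (median 5·10⁶ mapped reads, log-SD 0.25, satisfying
the > 2·10⁶ QC threshold for almost all libraries), `a_r` a relative
abundance drawn log-uniformly over four decades (10⁻⁷–10⁻³ before
normalization to sum 1, so a region's expected CPM equals `a_r · 10⁶`), and
`f_rj` a planted fold term. The default cohort mirrors the discovery set:
97 tumors (5 WDSCC, 14 MDSCC, 3 PDSCC, 7 pure-lepidic, 56 mixed-lepidic,
12 non-lepidic AD). φ defaults to 0.15 (biological CV ≈ 0.39), a typical
value for heterogeneous human tumor cohorts; the NB-with-common-dispersion
family makes the differential test's assumptions true by construction.

The default region count is 4 000 — a deliberately scaled-down promoter set
(real robust-peak references run to tens of thousands of retained regions)
chosen so that the exact test, whose cost is linear in each region's total
count, completes a full screen in seconds on one core. Planted regions are
given mid-range baseline abundance (≈ 10–100 CPM) so they pass the
expression threshold and carry information.

Planted effects act on the *whole super-type* containing each contrast
group: an 8-fold (default) DE region is up in all SCC samples (or, for a
small minority of planted regions, all AD samples), and separator regions
are shifted in all samples of one super-type. This reproduces two features
of the real data at once: the stated fold between PDSCC and non-lepidic AD,
and the global SCC/AD structure visible in the MDS embedding. Complete
separation is a property of realized data, not of parameters, so each
planted separator is verified after sampling (disjoint CPM ranges between
the contrast groups with a log2 margin ≥ 2 by default) and redrawn with an
escalating shift for a bounded number of retries.

All randomness flows from one integer seed through `numpy.random.SeedSequence`
spawns (one stream per output), so identical seeds give bit-identical
cohorts.

What the generator does **not** emulate: subtype-specific marker behavior
(a marker's sensitivity is constant across subtypes of its class, whereas
real established markers perform better on well-differentiated tumors),
correlated markers, batch effects, tumor purity variation, and read-level
artifacts. Consequently a passing panel search demonstrates the search and
scoring logic, not clinical marker performance; the simulated best-panel
accuracy on a validation-style cohort (~81 %) is below the published 90.5 %
precisely because established markers are simulated at their
hard-subtype sensitivities cohort-wide.

## Normalization, filtering, MDS

- **QC:** libraries with ≤ 2 000 000 mapped reads are dropped (strictly
  greater required to pass).
- **CPM:** `count · 10⁶ / library_size`, no pseudocount; library size is
  total mapped reads and may exceed in-region counts.
- **Inactivity filter:** a region is removed iff, in *both* super-type
  groups, strictly more than 77 % of samples have CPM ≤ 1. The pooled
  reading (one rule over all samples) is available behind a flag.
- **MDS:** pairwise sample distance is the root-mean-square of the 500
  largest absolute differences of `log2(CPM + 0.5)` between the pair
  (leading log-fold-change distance); the prior count 0.5 is fixed and
  documented because the upstream tool's internals are not part of the
  contract. Coordinates come from classical (Torgerson) MDS; axis signs are
  canonicalized so the largest-magnitude loading on each axis is positive.

## Differential screen

The common dispersion is estimated by method of moments: counts are scaled
to the geometric-mean library size; per region, `(var − mean)/mean²` is
averaged over the two groups; the estimator is the median over regions,
floored at 0. The median is slightly conservative (≈ 10 % low at φ = 0.4
with 10 + 10 samples) but robust to the planted outlier regions.

The exact test conditions on a region's total count after deterministic
scaling + rounding to the geometric-mean library size (in place of quantile
adjustment). The sum of n iid NB(μ, φ) counts is NB(nμ, φ/n), so under the
null the conditional probability of each split of the total is the product
of two group-sum NB pmfs; the two-sided p-value sums all splits no more
probable than the one observed (minimum-likelihood convention, with a
1e-10 log-scale tie tolerance; the doubling convention is the documented
alternative). With φ = 0 and one sample per group this reduces to the
two-sided binomial(total, ½) test, which the tests exploit as a closed-form
oracle; small multi-sample instances are checked against explicit
convolution enumeration.

Candidates satisfy FDR < 0.01, linear |fold| > 4 and mean CPM > 4, all
strict; `log2fc > 0` means higher in the second-named group. Fold changes
use a prior count of 0.5 (on the common-library scale, expressed in CPM) to
stabilize zeros. The complete-separation screen is applied to the candidate
set, mirroring the study's narrative of finding perfectly separating
promoters among its candidates; the separating threshold is the geometric
mean of the two boundary CPMs (arithmetic midpoint when the low boundary is
0), the margin is `log2(min_high / max_low)`, and tied boundaries yield no
separator. The published counts (65 candidates, 7 separators) depend on the
real cohort and are not reproduced.

## IHC scoring and diagnostics

Novel markers: score 0 iff no tumor cells stain, score 2 iff > 50 % of
tumor cells show moderate-or-stronger staining (strict), else 1. Established
markers: score 0 iff no staining, score 2 iff ≥ 10 % of cells stain
(inclusive), else 1. Positive call ⇔ score 2. The two-pathologist consensus
process is modeled as a single resolved score.

Per-marker 2×2 tables set the condition-positive class by marker class
(AD markers: AD; SCC markers: SCC). Sensitivity a/(a+c), specificity
d/(b+d), PPV a/(a+b), NPV d/(c+d) and accuracy (a+d)/total each carry an
exact Clopper–Pearson CI on their own numerator/denominator (the published
tables print CIs for all five); a metric with denominator 0 is undefined
and rendered "N.A.". Table output rounds half-up to 3 decimals; internal
values keep full precision.

## Panels

A panel is one AD marker + one SCC marker: single-positive concordant
patterns classify (AD or SCC); double-positive and double-negative are both
inconclusive — the conservative, symmetric completion of the published
rule, which does not define the double-positive case. Accuracy counts
inconclusive samples in the denominator and never as correct, reproducing
the published arithmetic (67 correct + 7 inconclusive of 74 → 90.5 % /
9.5 %). The exhaustive search evaluates every AD×SCC pair, ranked by
accuracy, then fewer inconclusive calls, then lexicographic names; panels
larger than two markers are out of scope. The sequential strategy applies a
second pair only to samples the first left inconclusive.

## Clustering

Binary profiles (1 iff score 2) are compared by Euclidean distance
(√Hamming). UPGMA uses unweighted average linkage with ties broken by the
smallest original item index, making the tree deterministic; markers are
clustered with the same distance over their sample vectors (the published
figure clusters both axes but specifies the distance only for samples).
Dendrograms serialize to Newick with branch lengths equal to merge-height
differences; within a merge the subtree containing the smaller original
index comes first.

## Numerical and testing notes

- Clopper–Pearson bounds are Beta quantiles; tests cross-check a
  bisection-on-binomial-tails oracle (1e-9) and statsmodels.
- UPGMA heights are cross-checked against scipy's `average` linkage and a
  brute-force re-averaging oracle; MDS against exact reconstruction of
  planar configurations.
- Simulation-scale choices (2 000-region null and separator fixtures,
  10 + 10-sample type-I simulation at 2 000 regions, 10⁴ Monte-Carlo
  replicates for CI coverage) keep the full suite to a few minutes on one
  core while leaving comfortable sampling-error headroom for the asserted
  bands (e.g. type-I error asserted within [0.03, 0.07]).
- Degenerate inputs raise: empty groups, zero library sizes, out-of-range
  scores/probabilities, all-removed QC, n < 2 clustering, denominator-0
  metrics (undefined, not an error).

## Known limitations

Tagwise/trended dispersion, GLM designs, multi-group comparisons, ROC
analysis, marker correlation structure, and rendering of the heatmap/MDS
figures are out of scope; plot-ready TSVs are exported instead. The
inactivity filter's "both subtypes" reading (logical AND, strict >) follows
the literal wording; the pooled variant is provided but not default.
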