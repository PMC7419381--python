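# Methods

## The measurement model

MSAP genotyping digests genomic DNA in parallel with EcoRI/HpaII and
EcoRI/MspI. HpaII and MspI recognize the same CCGG site but are blocked by
different cytosine-methylation configurations, so the joint presence pattern
of a fragment across the two profiles encodes the methylation state of its
site: (+,+) unmethylated, (−,−) full methylation of both cytosines (mCmCGG),
(+,−) internal-CG methylation (CmCGG), and (−,+) a pattern that plant
genomes (which methylate both CG and CHG contexts) cannot resolve uniquely
(mCCGG or CmCGG) and that we carry as an explicit indeterminate state rather
than discarding. MSAP markers are dominant: band presence is blind to allele
dosage, so ploidy is carried as metadata only and never modelled.

Two caveats are inherent to the assay and shape the design throughout:

1. **(−,−) is ambiguous.** At a methylation-variable locus it means full
   methylation; at a methylation-insensitive locus it means the band is
   simply absent (an ordinary AFLP presence/absence polymorphism). The
   MSL/NML partition below is what disambiguates it, and it is why the
   partition must precede every downstream statistic.
2. **Matches can be coincidental.** In the inheritance analysis, an
   offspring state equal to a parental state cannot be distinguished from
   independent reorganization that happens to coincide. All inheritance
   categories are therefore match-based descriptions, not transmission
   proofs.

## Peak scoring

Peak tables (sample, enzyme, run, fragment size in bp, height in RFU) are
consumed as produced by the genotyping software; electropherogram signal
processing is out of scope. Scoring applies three rules:

- **RFU floor, strict:** peaks must exceed 100 RFU; a peak at exactly the
  threshold is background by the threshold's definition. The floor is
  applied per peak, before binning.
- **Size window, closed:** [150, 500] bp, endpoints included. Both
  thresholds are configurable.
- **Binning:** half-open intervals [k·w, (k+1)·w) with w = 0.5 bp, anchored
  at 0 bp. Fixed anchoring makes scoring deterministic; every retained peak
  maps to exactly one bin. Bins empty in every sample cannot arise (bins are
  created from peaks); monomorphic-present bins are kept because they feed
  the non-methylated-fraction statistics.

When pairing the two enzymes' matrices, loci are the union of occupied
bins, a bin absent from one enzyme scored as no band there. This is
deliberate: a band present only in the MspI profile *is* the CmCGG
signature, so intersecting bins would delete exactly the signal of
interest.

Run-to-run reproducibility is monitored through a control sample included
in every electrophoresis run; the per-pair fraction of disagreeing bins is
reported and flagged above a configurable tolerance (default 0.05).

## MSL/NML partition

A locus is **methylation-susceptible (MSL)** when the frequency of
HpaII/MspI-discordant patterns ((+,−) or (−,+)) across its non-missing
samples exceeds the scoring error rate (default 0.05, the per-primer-
combination error rate of the assay); otherwise it is **non-methylated
(NML)**. Discordance is the only pattern that *requires* methylation;
classifying on it keeps segregating NML loci — where (−,−) codes band
absence — in the methylation-insensitive channel, which is what lets the
NML fraction serve as a quasi-genetic control. Raising the error rate can
only shrink the MSL set (monotonicity).

Polymorphism flags: an MSL locus is polymorphic when at least two distinct
states each exceed the error-rate frequency; an NML locus when band
presence and absence both do.

Binarization for downstream statistics: in the MSL fraction a cell is 1
when its call is methylation-indicative ({FULLMETH, CG_METH, INDET}) and 0
for NONMETH; in the NML fraction 1 means a band in at least one profile and
0 means (−,−) absence. Methylation levels and state proportions are
computed over non-missing cells (a per-locus modal variant is available
behind a flag). Missing data arise only from explicit masking, never from
(−,−).

## Diversity and differentiation

- **Shannon index.** Per locus with band frequency *p*, the two-term binary
  entropy S = −(p log₂ p + (1−p) log₂(1−p)), bounded in [0, 1] bits, with
  0·log 0 := 0. The one-term variant −p log₂ p sometimes quoted for
  dominant markers is available behind a flag; the two-term form is the
  default because it is the convention of the standard MSAP analysis
  packages and keeps per-locus values on the [0, 1] scale that reported
  SDs imply.
- **Distances.** Squared Euclidean (for 0/1 data, the mismatching-locus
  count) over pairwise-shared non-missing loci; simple matching is offered
  for exploration only. AMOVA consumes the squared-Euclidean form directly.
- **AMOVA φST.** Classical analysis of molecular variance on the pairwise
  squared dissimilarities: SS_total = ΣΣ d²/N and within-group sums give
  mean squares, converted to variance components with the unequal-group-
  size coefficient n₀; φST = σ²ₐ/(σ²ₐ+σ²_w), unconstrained (slightly
  negative estimates are reported as such). P-values permute the
  sample-to-group assignment, P = (1 + #{φ_perm ≥ φ_obs})/(n_perm + 1),
  with a mandatory seed; default 999 permutations. The overall multi-group
  φST over the MSL fraction is the overall epigenetic differentiation
  (βST). Pairwise tables carry raw permutation P's, flagged unadjusted.
- **Mantel test.** Pearson correlation of off-diagonal entries; two-sided
  permutation of one matrix's labels, default 1000 permutations.
- **Rank tests.** Kruskal–Wallis (tie-corrected, scipy) with a hand-rolled
  Dunn post hoc (mean-rank z statistics with tie correction; adjustment
  configurable among none/Bonferroni/Holm/BH, default Bonferroni since the
  choice is otherwise unspecified in common workflows), Wilcoxon rank-sum
  with continuity correction for two groups, and one-way ANOVA with Tukey
  HSD (statsmodels). Dunn tables carry (+/−) direction flags: the
  first-named group has the larger mean rank.

## Ordination and trees

- **PCoA** is classical scaling: eigendecomposition of the double-centered
  −½D² matrix; coordinates are eigenvectors scaled by √λ for positive
  eigenvalues. Negative eigenvalues (non-Euclidean inputs) are reported,
  not corrected; a Cailliez constant-addition correction exists behind a
  flag, default off. Axis signs follow a deterministic convention (the
  largest-magnitude coordinate on each axis is positive).
- **BPCA** eigendecomposes the size-weighted covariance of the group
  centroids of the column-centered matrix; the headline number is the
  percentage of total inertia carried between groups, tested by label
  randomization (default 10⁴ permutations).
- **NJ trees** use the Saitou–Nei agglomeration (scikit-bio); negative
  branch lengths, possible on non-additive inputs, are clamped to zero with
  the event recorded. On additive matrices the tree reproduces all input
  path lengths exactly, which is the oracle used in the tests.
- **Evanno ΔK** post-processes an external model-based clustering program's
  log-likelihoods; the program itself is never run here. With mean L(K)
  over replicates: L′(K) = L(K) − L(K−1), L″(K) = L′(K+1) − L′(K), and
  ΔK = |L″(K)|/SD(L(K)), defined for interior K, requiring ≥ 3 consecutive
  K and ≥ 2 replicates per K; zero SD raises rather than dividing by zero.
  A convenience parser extracts (K, logL) pairs from clustering output
  files.

## Inheritance scoring

Matching is on the full four-state call, not on binarized presence — the
per-state breakdowns of the family tables require it. Per offspring locus,
rules apply in order: state matches any parent → *inherited*; otherwise a
methylation-indicative state → *novel*; otherwise (offspring unmethylated,
all informative parents methylated) → *lost*. The three classes partition
the scored loci; loci with a missing offspring call or no informative
parent are excluded from denominators.

Origin attribution: F1 loci are maternal-only / paternal-only /
both-parents / de novo against the F0 pair. F2 loci are traced through the
F1 generation — an F0-origin category requires the state to match both the
F1 mother and the F0 mother (plus the F0 father for the both-F0-parents
category); a state shared with the F1 mother but absent from the F0s is
F1-maternal novel; shared with the F1 father (the improved male of the
second cross), F1-paternal; shared by both F1 parents but no F0, F1 M+P;
matching nobody, de novo. Any locus whose required ancestor profile is
missing goes to an explicit *unattributable* bucket (this generalizes the
absent-founder case: an entire missing parental profile simply routes every
traceable locus there). Clonal offspring are scored by the fraction of
non-missing shared loci with an identical call to the mother plant.

Epimutation rates collapse calls to methylated/unmethylated and pool all
mother→sucker transmissions: gain = (# unmethylated→methylated)/(#
unmethylated at risk), the binomial MLE, symmetrically for loss; percentile
bootstrap intervals (default 500 resamples) resample loci, the unit within
which transmissions are correlated. Zero at-risk cells or zero observed
transitions are reported as rate 0 with a degenerate flag.

## The synthetic-data generator

The generator emulates the two study designs the package models: a
population survey (default 5 groups × 18 samples × 724 loci — about 700
loci per primer combination is also the geometric ceiling of one peak
table, see below) and an inheritance design (four sexual families with 13
F2 offspring each, nine clonal families with 2–3 suckers; ~1.9k loci when
configured to the inheritance scale). Default baseline state frequencies
(0.214, 0.463, 0.140, 0.183) follow the genome-wide proportions reported
for the surveyed germplasm; default gain/loss switch rates are 0.02/0.05
per locus per generation.

- **Populations:** per group and locus, state frequencies are Dirichlet
  draws centered on the baseline with concentration baseline/divergence;
  divergence 0 gives exchangeable groups (the null used for calibration
  tests), larger values monotonically increase downstream φST.
- **Pedigrees:** sexual offspring inherit each locus from a uniformly
  chosen parent, then apply gain/loss switches (gains land on a
  methylated state drawn from the baseline's methylated profile); clonal
  offspring copy the mother and switch. Founders are drawn first and any
  observability fix (below) is applied to them before propagation, so
  parent–offspring closure is exact when switch rates are zero.
- **Peak tables:** each present band becomes one peak at its bin midpoint
  plus Gaussian size jitter truncated at ±0.45 bin widths — the truncation
  is what makes the round trip (peaks → filter → bin → call) exactly
  reconstruct the source matrix; spurious peaks are added below the 100-RFU
  floor so the filter removes them deterministically. One peak table models
  one primer combination, so at 0.5-bp bins in a 150–500 bp window at most
  700 loci fit; multi-combination surveys are represented by state matrices
  directly.
- **Observability:** a real scored locus is, by construction, a band seen
  somewhere; loci that would produce no band in some enzyme across all
  samples get one random sample set to unmethylated (on by default,
  `ensure_observable`).

What the generator does *not* emulate: restriction-site sequence content,
dosage (deliberately, as the markers are dominant), size-standard
miscalibration, dye pull-up, run effects, or linkage between loci (loci are
independent). Tests passing on these simulations therefore validate the
arithmetic and the statistical calibration of the estimators, not the
wet-lab scoring pipeline upstream of the peak tables.

## Numerical and edge-case conventions

- All randomized procedures (permutation tests, randomization tests,
  bootstrap, simulation) take an explicit seed; fixed seed ⇒ bit-identical
  results.
- Permutation P-values use the add-one form (1 + hits)/(n + 1), which is
  exact under exchangeability; the type-I error of the AMOVA test is
  verified to sit in [0.03, 0.07] at nominal 0.05 over 1000 null data sets.
- Degenerate inputs fail loudly rather than silently: all-missing loci are
  excluded with a warning, constant matrices raise in Mantel, zero-SD
  log-likelihoods raise in ΔK, singleton groups raise in AMOVA; the one
  exception is an all-zero distance matrix, where φST is reported as 0 with
  a degenerate flag.
- Proportions over cells sum to 1 to machine precision; eigenvalue
  positivity uses a relative tolerance of 1e-10 of the leading eigenvalue.

## Problem sizes used in the validation suite

Oracle-equivalence checks run 100 random instances per estimator at ≤ 10
samples × ≤ 30 loci (tolerance 1e-9); parameter recovery uses 50 replicates
of the nine-family clonal design at 2000 loci; the null calibration uses
1000 simulated data sets of 2 × 6 samples × 30 loci with 999 permutations
each; the round-trip check runs 100 seeds at 12 samples × 40 loci. These
sizes keep the full suite in the low minutes while leaving every stochastic
check amply powered.

## Known limitations

- Four-state calls inherit every MSAP ambiguity: the (−,+) state is
  irreducibly indeterminate, and (−,−) at an MSL locus could in principle
  be a sequence polymorphism rather than methylation; this is tolerable
  in near-isogenic material and wrong for diverse panels.
- βST is computed as the overall multi-group φST over the MSL fraction;
  other definitions of overall differentiation exist.
- Inheritance categories are match-based; no attempt is made to model the
  probability of coincidental matching.
- Pairwise φST tables are intentionally unadjusted for multiple testing
  (flagged in the output).
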