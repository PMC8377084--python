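# Methods

## The generative model behind the synthetic libraries

The analyses in this package are validated against a generator
(`synthetic_data`) that encodes the search-time hypothesis directly.  A
"species" is a `ContextEffectMap`: for each of the $4^k$ PAM-proximal
k-mers (default $k=5$, spacer positions 16–20) a **ceiling** $c(\kappa) \in
(0,1]$, interpreted as the maximal activity a guide ending in that k-mer can
reach in that genome, because its PAM-proximal word determines how much time
the Cas9/gRNA complex wastes on the genome's pool of inhibitory non-target
sites.  Measured activity of guide $i$ is

$$a_i = c(\kappa_i)\; f(\mathrm{pam4}_i)\; A_i + \varepsilon_i,
\qquad \varepsilon_i \sim \mathcal N(0, \sigma^2),$$

clipped to $[0, 1.05]$, where

* $f$ is a species-independent multiplicative preference for the genomic
  nucleotide 3′ of the NGG PAM (the NGGH preference).  Factors are drawn
  once from an *intrinsic* seed shared by all species, uniform on
  $[0.85, 1]$ with the G factor forced lowest — the effect is real but weak,
  so the band is narrow;
* $A_i$ is a one-sided attenuation: $A_i = 1$ with probability `p_full`,
  else $A_i \sim \mathrm{U}(0,1)$.  It lumps together everything that only
  ever *reduces* activity below the ceiling (gRNA secondary structure,
  target accessibility, repair differences).

Ceilings are i.i.d. logit-normal (logit-scale sd 1) from a species seed and
rescaled so the best k-mer has ceiling exactly 1.  Dinucleotide-scale
structure is obtained purely by marginalizing the 5-mer map; there are no
separate dinucleotide effects.  Attenuation is multiplicative, not additive,
so residuals of a ceiling-scale predictor are one-sided by construction.

### Defaults and what they mean

| parameter | default | units / range | rationale |
|---|---|---|---|
| `k` | 5 | k-mer length | contiguous PAM-proximal word the lookup predictor uses |
| `p_full` | 0.85 | probability | attenuation is the exception: most guides realize their ceiling, giving activity distributions that hug the ceiling with a left tail |
| `noise_sd` | 0.02 | activity units on the [0,1] scale | small measurement noise |
| `PAM4_FACTOR_LOW` | 0.85 | lower edge of $f$ | a weak, nuclease-intrinsic preference |
| shrink `lam` | — | $[0,1]$ | interpolates ceilings toward their mean; models interventions (higher expression, stricter PAM recognition) that shorten search times and flatten context structure |

`simulate_planted_window_effect` is a second, deliberately different
generator: activity is an *additive* function of the dinucleotides inside
one spacer window plus Gaussian noise.  It exists because the i.i.d. k-mer
ceiling map has almost no additive structure for a linear model to find
(each dinucleotide marginal averages 64 independent ceilings, shrinking its
signal by $8\times$), so positional-ablation correctness is tested with a
signal the encoding can represent exactly, planted where the test expects
it.

### What the generator does and does not emulate

It emulates: libraries of $10^2$–$10^5$ guides; species-specific
PAM-proximal preferences with a species-independent PAM 4th-nt effect;
one-sided, ceiling-limited activity; design filters seen in real libraries
(T-free PAM-proximal positions; constant PAM 4th nt); nuclease-null-like
assays via lower `p_full` (extra requirements attenuate more guides); and
varied readout shapes (continuous or thresholded binary).

It does not emulate: mechanistic genome-wide binding kinetics, chromatin
accessibility, real k-mer composition biases of genomes, guide-specific
repair outcomes, or any correlation between spacer sequence and the
attenuation factor.  Passing tests therefore show the *analyses* behave as
designed on data generated under the model's assumptions — not that real
genomes satisfy those assumptions.

## Analysis procedures

**Normalization.**  Activity is kept on its native scale until explicitly
transformed: sign inversion (an involution; refused on min–max scaled data)
for assays where more negative means more active, then min–max scaling to
$[0,1]$.  A dataset whose activities are all equal scales to all zeros with
a warning rather than an error, to keep batch runs alive.  Filters (exact
spacer+NGG occurrence in a genome FASTA on either strand, case- and
wrapping-insensitive, ambiguity codes never matching; redundancy removal
against a reference library) default to running before scaling; the order
is configurable.  Note that min–max scaling makes cross-dataset residuals
sensitive to the sampled extremes of each dataset: with noise, the scale
divisor can differ a few percent between replicates, which visibly moves
the exceedance fraction between seeds.

**Group preference.**  Group means are arithmetic; every observed group
enters regardless of size (counts are always reported; a `min_n` mask is
available but off by default).  Pairwise correlations use only k-mers
observed in both datasets — designed exclusions simply leave groups absent —
and pairs sharing fewer than 3 k-mers, or with a zero-variance mean vector,
are reported missing.  Datasets lacking 4-nt PAM contexts or showing no
variability in the 4th nucleotide are excluded from the PAM-4 analysis and
logged.

**Regression.**  "10-fold cross validation" is implemented as ten
*independent* random 80/20 splits (Monte-Carlo CV), matching the procedure
as described rather than ten disjoint folds.  The model is plain OLS with an
intercept and no regularization; scikit-learn's lstsq solve returns the
minimum-norm solution under collinearity, so rank deficiency is not an
error.  Split RNGs are keyed by `(seed, split_index)`, and records are
canonically sorted by guide id before splitting, so results are invariant
to input record order.  Ablation masks each 5-bp quarter
(1–5, 6–10, 11–15, 16–20); a dinucleotide feature is dropped if *either*
of its positions is masked, so each mask also removes one boundary pair.
Full and masked runs share the same splits.  A dataset whose full-sequence
mean Pearson falls below 0.1 (configurable) is flagged excluded — its
ablation fractions are ratios of noise.

**Ceiling predictor.**  Training datasets are pooled guide-by-guide before
grouping (pooled weighting, not a mean of per-dataset means).  Prediction is
a lookup of the PAM-proximal k-mer's trained mean; unseen k-mers fall back
to the count-weighted (k−1)-suffix marginal, then the global training mean,
with fallback counts reported so comparability is never silent.  Residuals
are `actual − predicted`.  Skewness is the adjusted Fisher–Pearson
coefficient; the exceedance fraction uses $\delta = 0.1$ on the min–max
scale by default ($\delta$ is configurable and always reported).  A genuine
caveat, verified on the generator: the trained group mean estimates
$c \cdot E[f] \cdot E[A]$, so when attenuation is *common* in the training
data (low `p_full`) the mean sits well below the ceiling and held-out
unattenuated guides exceed it by $\mathcal O((1-E[A])\,c)$ — the strict
upper-bound geometry (exceedance near zero) is a property of
rare-attenuation regimes, not of the lookup construction itself.

**Feature assessment.**  Tertiles use $m = \lfloor n/3 \rfloor$ after a
stable descending sort (ties resolve by input order).  The discrete
statistic is a natural-log odds ratio with the Haldane–Anscombe 0.5
correction, so zero counts are defined and an everywhere-absent feature
scores exactly 0.  Consistency is sign agreement over datasets with a
defined statistic; species with fewer than two such datasets get no
within-species verdict.

**Pipeline.**  All outputs are plain TSV/JSON; the JSON report is written
with sorted keys and contains no timestamps, so identical manifests produce
byte-identical reports.  Every exclusion (no PAM-4 variability, low
full-sequence Pearson, redundancy drops) is recorded in both the report and
the run log with counts — no silent drops.

## Problem sizes

The validation suite uses library sizes a laptop handles in seconds to
minutes: 50,000 guides for ceiling recovery and residual geometry (≈49
draws per 5-mer), 20,000 for group-preference correlations (≈1,250 per
dinucleotide group), 800 × 10 repetitions for ablation localization, and
2,000 for regression null/recovery checks.  These sizes sit inside the
range of real libraries and give the group statistics standard errors an
order of magnitude below the effects being measured.

## Known limitations

* The logit-normal / multiplicative form of the search-time → activity map
  is a stand-in; nothing quantitative is claimed about real search kinetics,
  and the truth manifests label it as synthetic.
* The lookup predictor is an analysis instrument for bound geometry and
  cross-context transfer, not a general guide-design scorer for real
  genomes.
* Folding energies and melting temperatures are accepted only as
  precomputed numeric columns; they are not computed internally.
* Exact-match target filtering ignores mismatched or bulged sites by
  design (existence of a perfect site is the criterion, not uniqueness).
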