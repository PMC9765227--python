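# Methods

This note records the models implemented by `gtadapt`, the numerical and
design choices that were genuinely open, and what the synthetic-data
generator does and does not emulate.

## Effective number of codons

Codon counts use the bacterial/archaeal genetic code (translation table
11), under which the degeneracy classes are 9 twofold, 1 threefold (Ile),
5 fourfold and 3 sixfold amino acids.  A terminal stop codon is stripped
before counting; internal stops and codons containing ambiguous bases are
skipped and do not count toward the gene's codon total.

Per amino acid with `n ≥ 2` observed codons, codon homozygosity is
estimated by `F̂ = (n·Σp̂² − 1)/(n − 1)`; amino acids with `n < 2` or
`F̂ ≤ 0` are omitted from their class average.  `ENC = 2 + 9/F̄₂ + 1/F̄₃ +
5/F̄₄ + 3/F̄₆`.  Conventions:

* a missing threefold class (Ile unobserved) is filled by
  `F̄₃ = (F̄₂ + F̄₄)/2`, the classic fallback; if any other class is missing
  the gene's ENC is undefined and the gene is dropped from ENC analyses
  with a logged reason;
* the raw statistic is capped into [20, 61] — the finite-sample estimator
  can stray outside the definitional range in both directions.

GC3s is the G+C fraction at third positions of codons of amino acids with
at least two synonyms (ATG and TGG excluded from numerator and
denominator).  The no-selection expectation given GC3s `s` is the Nc-plot
null `2 + s + 29/(s² + (1−s)²)`.  A gene's bias score is the *relative*
deviation `(ENC_exp − ENC_obs)/ENC_exp`; the expectation is the natural
denominator for "deviation from a null expectation", and genes whose
observed ENC exceeds the expectation carry no bias signal and are flagged
excluded.  Wright's estimator is noisy at realistic gene lengths: at 300
codons its sampling sd around the null curve is ≈ 1.6 ENC units
(≈ 0.9 at 500), which the generator tests account for.

## tRNA adaptation index

tRNA gene copy number (tGCN) proxies tRNA abundance.  Absolute
adaptiveness per codon sums, within the codon's own four-codon box, the
Watson-Crick anticodon plus the wobble-capable anticodon, the latter
down-weighted by a selective constraint:

| codon 3' base | Watson-Crick anticodon 34 | wobble pairing | default s |
|---|---|---|---|
| U | A | G:U | 0.41 |
| C | G | I:C (A34) | 0.28 |
| A | U | I:A (A34) | 0.9999 |
| G | C | U:G | 0.68 |

AUG is decoded only by its Watson-Crick CAU anticodon.  Bacterial AUA
(Ile) receives the lysidine-modified CAU tRNA with constraint 0.89; when
the tRNA inventory carries isotype labels (tRNAscan-SE output does), CAU
copies are split between the Met and Ile2 isotypes, otherwise the single
CAU count is shared by both equations — a documented approximation forced
by label-free inventories.  Pseudogene rows in tRNAscan-SE output are
excluded: the index is about the functional tRNA pool.

Relative adaptiveness is `w = W/max(W)`; codons with `w = 0` receive the
geometric mean of the nonzero values so that gene-level geometric means
stay positive (the standard convention).  tAI is the count-weighted
geometric mean of `w` over the gene's sense codons, and ptAI is the
percentage of the genome's analyzed genes with *strictly* smaller tAI
(ties share the strict count; values lie in [0, 100)).

### Species-specific wobble constraints

The constraints can be re-estimated per genome by maximizing the Spearman
correlation between gene tAI and a per-gene proxy of expression, via
coordinate-descent hill climbing from the defaults (steps coarse to fine,
finishing at 0.01; deterministic sweep order; Watson-Crick fixed at 0).
Without expression data the default proxy is the ENC-deviation score.
Identifiability caveat: a rank-correlation objective against a noisy proxy
is nearly flat in the individual constraints, so point recovery of the
generating constraints should only be expected with a sharp proxy (the
recovery test uses the planted adaptation itself, where the optimum is
exact); with noisy proxies the optimizer is a mild refinement, not an
identification procedure.  Fixed-default mode is the pipeline default.

## Phylogenetic GLS

For tips i, j of a rooted tree, the Brownian covariance is the shared
root-to-tip path length.  Internally every (pruned) tree is held as an
edge incidence decomposition `C = U·diag(ℓ^κ)·Uᵀ`, so pruning a tree to a
genome subset (with serial-edge merging and stem removal, equivalent to
pruning + unifurcation suppression) and applying Pagel's transformations
are cheap matrix operations.  Transformation order is the standard one:
κ exponentiates branch lengths, δ exponentiates the covariance entries
(applied directly — the input tree need not be ultrametric), λ scales the
off-diagonal.  Bounds: λ ∈ [0, 1], δ, κ ∈ (0, 3] (the usual software
convention; the profile likelihood frequently sits on the δ or κ boundary
without harming the slope inference).

Estimation profiles β and σ² analytically and maximizes the Gaussian
log-likelihood over (λ, δ, κ) by bounded L-BFGS-B from three fixed starts,
(1,1,1), (0,1,1) and (0.5,1,1); the best converged start wins and a fully
non-convergent search is returned flagged rather than dropped.  Reported
`sigma2` uses the n−2 denominator and the slope p-value is the two-sided
t-test with n−2 df; with the identity covariance the fit reduces exactly
to OLS and its classical t-test.  An exactly collinear pair (σ² = 0) is
given a huge finite likelihood and reported with p = 0 and a degenerate
flag.  A singular covariance (near-duplicate tips) receives a single ridge
of `1e-8·mean(diag)` with a warning; if still singular the offending tip
pair is named in the error.

Calibration, measured by the test suite on 100-tip Yule trees: empirical
type-I error of the slope test on independent Brownian traits is ~5–7% at
α = 0.05 (400 replicates); the slope is recovered without detectable bias
(50 replicates at true slope 0.8); λ̂ ≈ 1 under Brownian residuals and
λ̂ ≤ 0.2 in ~93% of white-noise replicates.

## Screening decision procedure

Candidate families are regressed (their per-genome ptAI, median over
paralogs) on each reference family over the genomes where both are
present.  Decision rules: n ≥ 40 genomes → pass iff *every* reference fit
has p < α (default 0.05; no multiple-testing correction across families,
matching the original procedure — the α is per-family, and the all-of-12
conjunction is itself a stringent filter); 10 ≤ n < 40 and located in the
head-tail cluster regions → pass iff ≥ `ceil(0.4·k)` of k reference fits
are significant ("at least 40%"); otherwise the family is not screened.
Reference-set coherence is validated by all-pairs PGLS (α = 0.001), and a
reference gene non-significant against ≥ two thirds of the others is
flagged discordant (the rule that removes a misbehaving gene from the
reference set).  Paralog robustness refits the screen across per-genome
paralog selections — all of them when fewer than 1000 combinations exist,
otherwise exactly 1000 seeded draws — and reports the passing fraction.

## Synthetic-data generator

The generator emulates the statistical structure of a multi-genome
codon-usage study; all randomness fans out deterministically from one
master seed.

* **Tree.** Yule (pure birth), conditioned on the tip count by extending
  every terminal branch with the exponential waiting time to the next
  speciation (the simulator otherwise stops exactly at the last birth,
  leaving zero-length tips); rescaled to mean root-to-tip depth 1; branch
  lengths floored at 1e-6.
* **Latent activity.**  One shared trait per genome: Brownian motion on
  the tree (σ² = 1) *plus* a genome-specific white component (sd 0.6).
  The white component models ecology not explained by phylogeny and is
  what makes co-adaptation identifiable: were the shared trait a pure
  Brownian path, "family y tracks family x" and "family y is an
  independent Brownian trait on the same tree" would be nearly
  indistinguishable to PGLS, and the maximum-likelihood fit can
  legitimately prefer the latter.  Reference and planted families add
  i.i.d. noise (sd 0.1) to the shared trait; null families draw their own
  independent Brownian + white traits.  Traits map to per-gene selection strength through a logistic
  link (scale 2.0) times the coupling `beta_sel`.
* **tRNA pools.**  A bacteria-like template: every codon box keeps a
  high-copy G34 anticodon; half the boxes carry the U34 anticodon that
  reads A/G-ending codons and the rest only a single C34 copy, leaving
  their A-ending codons nearly unreadable.  This skew — present in real
  bacterial tRNA sets — is what makes codon choice informative about
  adaptation.  Per-genome pools are Poisson perturbations of the template
  (occasional zeros exercise the wobble-only and zero-replacement paths).
* **Sequences.**  Gene bodies of 250–500 amino acids drawn from a fixed
  bacteria-like composition (optionally tilted toward cheap side chains in
  proportion to selection strength when cost coupling is on); each codon
  comes from a mixture: with probability `s_gene` proportional to raw
  adaptiveness under the genome's own pool (zero-adaptiveness codons are
  never chosen by this component), otherwise proportional to a GC-driven
  background with independent positions.  ATG start and TAA stop are
  appended.
* **Families.**  12 reference (prevalence 1.0), 10 planted (0.95), 200
  null (per-family prevalence uniform on [0.55, 1]); each present
  genome-family cell duplicates into two paralogs with probability 0.1.

Default signal-strength parameters (family noise sd 0.1, link scale 2.0,
gene lengths 250–500 codons in the study config) were calibrated once so
that the reference set reproduces the coherence observed in the real data
this design emulates — every pairwise reference PGLS significant — rather
than a marginal signal; with weaker settings the all-reference screening
rule has essentially no power, which is a property of the rule, not of the
estimator.

What the generator does **not** emulate: real alphaproteobacterial genome
composition, amino-acid-level sequence homology within families (members
share a family label and a latent trait, not an alignment), horizontal
transfer, genome-specific amino-acid usage, or expression data.  Passing
tests therefore demonstrate that the pipeline recovers planted
co-adaptation under its own stated model of the data, not that any
particular biological dataset would yield the same families.

## Problem sizes used by the tests

The end-to-end screen runs the default study (60 genomes, 222 families,
~11,600 genes, ~2,600 ML PGLS fits); estimator calibration uses 400 null
and 50 alternative replicates on 100-tip trees; the paralog machinery is
exercised at 2³ (enumerated) and 2¹¹ (1000 seeded draws) combination
counts.  These sizes keep the full suite in the tens of minutes on one
core while leaving every decision rule of the method exercised at the
prevalence thresholds (40 and 10 genomes) that gate it.

## Known limitations

* The ENC deviation denominator (`ENC_exp`) is a documented choice; other
  groups normalize by `ENC_obs` or report absolute differences.
* The wobble-constraint optimizer inherits stAI-style identifiability
  limits (above).
* PGLS assumes the residual covariance is a Pagel transform of the input
  tree; gene-specific histories (transfer, loss) are not modelled beyond
  presence/absence pruning.
* ptAI is a within-genome rank: it removes genome-level scale but also any
  genuine between-genome differences in absolute adaptation.
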