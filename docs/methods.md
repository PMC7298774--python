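# Methods

This note documents the models and procedures implemented in `paradiverge`,
the parameters that matter, and the choices made where the design was open.

## Pattern classification

Differential expression of a single gene under one (stress, time) condition
is a strict threshold call: expressed AND padj < α AND |log2FC| > ℓ, with
defaults α = 0.05 and ℓ = 1 and strict inequalities at both boundaries. A
missing record is "not DE". The pair-level pattern is then a pure function
of the two calls — FF (both), FP (exactly one), PP (neither) — so the three
patterns partition the pairs under every condition.

Single-condition calls use one analysis time point per stress (the last of
the three, `analysis_time_index = 3`, configurable), reflecting designs in
which the response is sampled until fully developed. Trajectories use all
three time points of a stress: with rank(PP)=0, rank(FP)=1, rank(FF)=2, a
pair is *enhancing* when its rank sequence is non-decreasing, ends at 2 and
starts below 2; *decreasing* is the mirror image; a constant sequence is
*stable* (a flat FF is deliberately not "enhancing" — the arrow notation
implies change); everything else is *mixed*. Reversing time exactly swaps
enhancing and decreasing and fixes stable/mixed, which the tests assert over
all 27 rank triples.

Stress-sharing clusters map the set of stresses in which a pair shows the
focal pattern to seven named clusters (all four; abiotic Dr+Cd; biotic
Bc+Pr; four stress-specific singletons). The remaining Venn regions (e.g.
{Dr, Bc}) are collected in an explicit `other` cluster and counted rather
than dropped.

## Ka/Ks (Nei–Gojobori 1986)

Sites: each position of a sense codon contributes f = (synonymous
single-nucleotide changes)/3 to S, the rest to N; changes to stop codons are
nonsynonymous; S + N equals the sequence length. S and N are averaged over
the two sequences (standard NG86).

Differences: codons differing at k positions are connected by k! single-step
orders; each step is classed synonymous/nonsynonymous by amino-acid identity
and counts are averaged over pathways. Pathways passing through a stop codon
are excluded; if every pathway is blocked, all are kept (steps into and out
of stops then count via '*'-as-amino-acid comparison). This
exclude-unless-all-blocked rule is common NG86 practice; note that other
implementations (e.g. Biopython's `cal_dn_ds`) keep all pathways, which
differs at the percent level on multi-position codons.

Distances: Ks = −¾ ln(1 − 4(Sd/S)/3) and likewise Ka (Jukes–Cantor).
Proportions ≥ 3/4 are saturated: the distance, the ratio and the selection
class are reported as undefined (encoded `NA` on disk) and excluded from
downstream statistics with a logged count — no exception is raised. The
selection call is positive (Ka/Ks > 1), negative (< 1) or neutral (equal
within 1e-9). When Ks = 0 the ratio is undefined.

## Synthetic data generator

The generator is the testbed for every downstream stage; its defaults are
the study conditions used throughout the tests and the acceptance script.

* **Design**: 4 stresses × 3 time points × 3 treated replicates plus one
  control per condition; 300 pairs of 100-codon genes by default.
* **Sequences**: an ancestral CDS of uniform sense codons is duplicated and
  each copy evolved by single-nucleotide proposals; proposals creating stops
  are rejected; for ω < 1 nonsynonymous proposals are accepted with
  probability ω (for ω > 1, synonymous proposals with 1/ω). Each lineage
  stops when its accepted synonymous substitutions per NG86 synonymous site
  reach half the pairwise target Ks — divergence is split symmetrically, as
  Ks is a pairwise quantity. A guard of 50·L proposals per lineage raises if
  the target is unreachable. The acceptance-ratio construction sets the
  Ka/Ks expectation that NG86 estimates without a full codon rate matrix;
  recovery is attenuated for ω > 1 (stop-proposal rejection and multiple
  hits), so planted ω = 2 is recovered as a median near 1.5 — well above 1,
  which is what the recovery checks assert.
* **Expression**: per pair, log-scale profiles over treated samples are
  bivariate normal with unit variances and correlation ρ = exp(−λ·Ks);
  per-gene baselines are N(3, 1) on the natural-log FPKM scale and values
  are exponentiated; controls are independent draws at baseline. λ = 1 by
  default; per-pair Ks is drawn uniformly on [0.05, 2.0] so the regression
  has leverage. Correlations in the analysis are computed on log(FPKM + 1);
  the +1 pseudocount means exactly collinear pairs score r ≈ 0.99 rather
  than 1.
* **DE tables**: a gene × condition call is DE with probability
  `de_fraction` (0.3 default) — padj ~ U(0, 0.049) and
  |log2FC| = 1 + Exp(mean `effect_mu` − 1 = 1.5), random sign — and
  otherwise fails both thresholds (padj ~ U(0.05, 1), |log2FC| ~ U(0, 1)).
  padj is generated directly rather than via simulated counts and a DE
  test: the classifier consumes calls, so only the threshold structure
  matters. A configurable fraction of pairs per stress is planted with an
  enhancing or decreasing rank trajectory (a rank triple drawn from the
  five valid monotone triples and translated into per-time DE flags); the
  planted truth is returned so recovery can be asserted exactly.

What the generator does **not** emulate: count noise and dispersion
(padj/log2FC are drawn, not estimated), expression autocorrelation across
time points, shared regulatory programs beyond the pairwise coupling, any
dependence of DE status on sequence divergence, and genome-scale pair
counts. Passing tests therefore demonstrate the correctness and calibration
of the machinery, not the biological effect sizes of any real dataset.

## Expression-divergence statistics

r is the product-moment correlation of the two genes' log-expression
profiles across treated samples (≥ 3 samples required; zero variance gives
an undefined r that is excluded and counted). The rescaled coefficient is
r′ = ln(1 + r)/(1 − r), implemented exactly as printed in the antecedent
literature's typesetting; a `fisher` mode gives ln((1 + r)/(1 − r)). Both
are strictly monotone on (−1, 1), so the sign of the r′-vs-Ks slope — the
scientific claim — is invariant to the choice. The regression is ordinary
least squares with the usual t-test p-value; points with undefined r′ or Ks
are excluded with a logged count, and no multiple-testing correction is
applied across stresses. The Mann–Whitney U test uses the exact null
distribution when min(n) ≤ 8 without ties, otherwise the normal
approximation with tie correction; fully tied inputs short-circuit to
p = 1.

## Randomized-pair null

The null distribution of a class statistic (median Ka/Ks by default; mean
and Ka/Ks/Ks variants selectable) is built by drawing equal-size sets of
pairs uniformly without replacement from the full pool, independently per
replicate, 10,000 times by default. The empirical p uses the add-one
correction (so the smallest reportable p at 10⁴ replicates is just under
10⁻⁴ and p is never 0), and the invariant
p = (#{null as-or-more extreme} + 1)/(n + 1) holds for the one-sided tails.
The model runs directional tests (FF: less; FP: greater), matching the
hypotheses that FF pairs sit under stronger purifying selection and FP
pairs under relaxed/positive selection; two-sided p (doubled smaller tail,
capped at 1) is available per call. Replicates with a fully undefined
statistic are dropped from the count.

## Co-expression network

Adjacency is |r|^power with power = 10 on log expression over treated
samples. The display filter removes edges with weight < 0.3 first, then
nodes whose maximum |r| to any retained neighbour is < 0.5 (a scalar node-r
threshold is otherwise undefined; edges-then-nodes is the stated order, and
the operation is idempotent). WGCNA's module detection (minModuleSize,
mergeCutHeight, dynamic tree cut) is not reproduced; those two parameters
are recorded in the settings for provenance only. TF family labels are an
input mapping, not inferred.

## Numerical and scale choices

Problem sizes in the tests and the acceptance script — 200-pair recovery
runs, 100 regression replicates of 300 pairs, 200 calibration trials of 500
permutation replicates, 60–100-codon genes — are chosen so each check has
clear statistical resolution (3σ binomial bands, KS uniformity at n = 200)
while a full run of suite plus script completes in about a minute. Floats
are written with 6 significant digits; undefined values are `NA` on disk
and NaN in memory. All randomness flows through `numpy.random.Generator`
seeds; identical configs produce byte-identical outputs.

## Known limitations

* NG86 with Jukes–Cantor assumes equal substitution rates among the four
  nucleotides; at high divergence (Ks ≳ 1.5) the estimator is noisy and a
  0.1-binned modal bin at n = 200 wanders ±0.3 around the target even
  though the median recovers it.
* CDS pairs must arrive codon-aligned and gap- and stop-free; no aligner is
  bundled and ambiguity codes are rejected (NG86 site counting is undefined
  for them). Terminal stop codons must be trimmed by the caller.
* The ω acceptance-ratio simulator sets a substitution-level Ka/Ks, not a
  mechanistic codon model; it is deliberately transparent rather than
  realistic.
* Maximum-likelihood dN/dS, sliding-window Ka/Ks and cross-species ortholog
  analyses are out of scope.
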