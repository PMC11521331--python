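# Methods

This note documents the models, numerical choices and limitations behind
`giacall`. The package infers the ancestry of one query sample at a time
against a labeled reference panel of up to eight world populations, using
three independent methods and a consensus rule.

## Data model and merging

Genotypes are alt-allele dosages (0/1/2) of biallelic autosomal SNVs,
keyed by (chrom, pos, ref, alt) and sorted by position. Indels and
multiallelic records are excluded at read time so that a dosage has a
single well-defined meaning. Coordinates are 1-based (VCF convention);
query and panel must be on the same genome build — no liftover is
performed.

Merging appends the query to the panel on the union of variant keys.
Where (chrom, pos) matches but ref/alt are swapped, the query dosage is
complemented (d → 2 − d); strand-ambiguous swaps (A/T, C/G) cannot be
distinguished from strand flips and are conservatively dropped (logged),
as are irreconcilable allele conflicts. Every absent or missing genotype
becomes homozygous reference. This hom-ref fill is deliberate: it avoids
missingness-driven batch effects and pushes query-private calls (e.g.
somatic mutations in tumor-derived genotypes) to a minor-allele frequency
of ~1/(2N), so the MAF filter removes them.

## Quality control

* **MAF filter** — variants with minor-allele frequency ≤ 0.001 in the
  merged matrix are removed.
* **Hardy–Weinberg mid-p exact test** — retention requires mid-p > 1e-6.
  The test enumerates the conditional distribution of the heterozygote
  count h given the minor-allele count n_m among N diploids,
  P(h) ∝ 2^h · N! / (n_hom-maj! · h! · n_hom-min!) over h with the parity
  of n_m, and returns the mid-p value: the probability of strictly less
  probable tables plus half the probability of equally probable tables
  (the observed table included at half weight). Probabilities are
  computed in log space (gammaln / logsumexp); equality of table
  probabilities is detected with a 1e-10 relative log tolerance, since
  genuinely tied tables exist but float noise must not manufacture or
  destroy ties. Monomorphic variants have a single possible table and
  receive mid-p 0.5, so they pass HWE and are removed by the MAF
  criterion instead — this avoids an undefined-test special case. All
  merged samples (references plus query) enter the test.
* **Relatedness pruning** — KING-robust kinship
  φ = (N_AaAa − 2·N_AA,aa) / (N_Aa^(i) + N_Aa^(j)) is computed for all
  panel pairs on the full QC'd variant set (more loci, lower estimator
  variance; the estimator is robust to population structure, which
  matters because the panel deliberately mixes populations). Pairs with
  φ > 0.09375 (first/second degree) are resolved greedily: repeatedly
  remove the sample in the most above-threshold pairs, ties broken by
  lexicographic id. Greedy max-degree removal is deterministic and
  near-optimal on pedigree-like graphs; equivalence with any particular
  external implementation's selection is not claimed. φ is undefined
  (NaN) when neither sample carries a heterozygote. Note that at this
  cutoff, half-siblings (φ = 0.125) are also pruned, so a parent with
  several offspring forms a complete relatedness graph, not a star.
* **Sample exclusion** — a configurable id list, supporting removal of
  subpopulations whose high within-population similarity would skew the
  PCA.

## LD pruning

A window of 100 variants slides by 1 along each chromosome (both are
config knobs; step 1 is the strictest choice and makes the no-high-LD
guarantee hold over all windows). Within a window, any retained pair with
squared Pearson genotype correlation > 0.2 loses one member — the one
with lower MAF, ties broken by later position. The implementation is an
incremental sweep (each variant is checked against retained predecessors
within the window span), which is equivalent to the literal
repeat-scan-per-window loop because a removal can never create a new
violation. The acceptance surface is the invariant — no retained
within-window pair above r² 0.2, and idempotence — not any particular
kept-set. Constant columns are uncorrelatable and get r² = 0.

## Principal components

Dosages are standardized per variant as (d − 2p̂)/√(2p̂(1−p̂)) with p̂ the
sample alt-allele frequency (well-defined because the MAF filter removes
monomorphic columns). Scores are the variance-scaled projections
U_k·S_k from the thin SVD, so k-NN distances weight each axis by its
explained variance; the eigenvalues are S_k²/(n−1). Whether the original
workflow's classifiers consumed variance-scaled projections or unit-norm
eigenvectors is not documented; both of this package's classifiers
consume the same convention, which is what the end-to-end recovery tests
validate. Component signs are fixed (largest-magnitude loading positive)
for reproducibility. PCA is recomputed jointly for panel + query on each
query, matching the per-patient design; this is O(N²·J) per query and is
the dominant cost at scale.

## Classifiers

* **k-NN (k = 8)** — Euclidean distance over all 20 PCs; distance ties at
  the k-th neighbor admit all tied samples; label-frequency ties break by
  smaller summed neighbor distance, then lexicographically. Deterministic
  tie-breaking is preferred over random for testability.
* **PC correlation (top 1%)** — Pearson correlation between the query's
  20-coordinate score vector and each reference's (a 20-point
  correlation across heterogeneous-variance coordinates, by design);
  the top ⌈0.01·N_ref⌉ references vote (ceil avoids an empty set on small
  panels; ranking ties at the cutoff are admitted). An exact tie for the
  top count yields Mixed Ancestry.

## Supervised admixture

Population frequencies F come from reference genotypes only — the query
is excluded from the F update, since with hundreds-to-thousands of
references one query's contribution is negligible, and the fit then
becomes a deterministic one-sample problem. Frequencies are clipped to
[1e-6, 1 − 1e-6] to prevent −∞ log-likelihoods at fixed sites. EM runs
from the uniform start with update
q'_k = (1/2J)·Σ_j [ g_j·q_k f_kj / Σ_l q_l f_lj + (2−g_j)·q_k(1−f_kj) / Σ_l q_l(1−f_lj) ],
stopping when the log-likelihood improves by < 1e-6 or after 1000
iterations; the trace is recorded every iteration and is non-decreasing
by the EM ascent property. A flat likelihood leaves the uniform vector
fixed. EM optimality is checked against a 0.01-resolution simplex grid
search: the check is one-sided (EM's final log-likelihood is never below
the grid optimum by more than 1e-3), because at J ≥ 100 the grid's own
resolution error already exceeds 1e-3 in the other direction. The
discrete call requires a unique fraction strictly > 0.54; a fraction of
exactly 0.54 yields NO_MAJORITY.

## Consensus

Two-of-three agreement is evaluated first (so PC-pair agreement can call
OCN even though the admixture model cannot); otherwise NO_MAJORITY routes
to Mixed Ancestry and a present-but-unmatched majority fraction routes to
Inconclusive. A Mixed-Ancestry correlation call never matches a
population; consensus can still be reached through k-NN + admixture
agreement. Threshold comparisons are strict on both sides, so a fraction
exactly at 0.54 blocks the Inconclusive arm and falls through to Mixed
Ancestry. An exhaustive decision-table test confirms exactly one rule
fires for every input combination.

## Synthetic data

The simulator draws ancestral frequencies uniformly on [0.05, 0.95],
population frequencies from the Balding–Nichols Beta distribution
(variance F·p(1−p)), reference dosages as Binomial(2, f_kj), and admixed
queries as Binomial(2, Σ_k q_k f_kj) — exactly the admixture
likelihood's generative model, so parameter recovery is a well-posed
test. Pedigree pairs are built by explicit Mendelian transmission.
Default study conditions: 3 populations at F_ST 0.1, 100 references per
population, 2000 variants for end-to-end tests; 5000 loci for kinship and
admixture recovery. All randomness flows from a single integer seed
through `numpy.random.default_rng`, giving byte-identical reruns.

What the simulator does **not** emulate: linkage disequilibrium (LD
pruning is instead tested on constructed correlated columns), somatic
mutations and tumor contamination, sequencing/genotyping error,
platform-specific target enrichment, and real human population history
(continuous clines, bottlenecks, real admixture LD). Passing simulation
tests therefore demonstrates correctness of the algorithms under their
own model assumptions, not field performance on clinical panels.

Two emergent behaviors of real pipelines do appear at these scales and
are worth knowing: (i) with ~1000–2000 loci, KING-robust estimates for
truly unrelated pairs have enough variance that an occasional pair
crosses the 0.09375 cutoff and a sample is pruned — harmless, and exactly
what the estimator would do on real data at low marker counts; (ii) the
HWE filter on a merged multi-population matrix removes the most
differentiated loci (Wahlund effect), slightly reducing but never
destroying the ancestry signal.

## Limitations

* One query per inference; batch runs loop and recompute the joint PCA
  per query (quadratic in panel size).
* Unsupervised admixture, phasing, imputation, haplotype-based LD and
  kb-based pruning windows are out of scope.
* The metrics module's macro SD uses ddof = 1 across classes; undefined
  per-class ratios (empty denominators) are NaN and excluded from macro
  averages.
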