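# Methods

## Abundance model

For each cell subset *s* in a stratum (brain, meninges, or both pooled),
cells are cross-classified focal-vs-rest by genotype, and the TG-vs-WT
odds ratio is computed from the group proportions,

OR = (p_TG/(1−p_TG)) / (p_WT/(1−p_WT)),

with the Woolf standard error of log(OR),
SE = √(1/n_WT,yes + 1/n_WT,no + 1/n_TG,yes + 1/n_TG,no), and the 95%
Wald interval exp(log OR ± 1.96·SE). The CI constant is fixed at exactly
1.96 rather than a normal-quantile call. "Rest" means all other cells of
the same stratum, so each compartment is analysed as its own closed
composition.

**Zero cells.** If any of the four counts is zero the Haldane–Anscombe
correction adds 0.5 to all four before anything is computed, which keeps
log(OR) and its SE finite; the result carries a `corrected` flag. The
same rule is applied inside the permutation loop so the null sample is
always finite. The proportion form (`odds_ratio_from_proportions`)
carries no SE — that requires counts — and rejects boundary proportions.

**Inference.** The headline test is permutational, not Wald: each
iteration reshuffles the genotype labels over the stratum's cells while
holding both group totals fixed, and recomputes every subset's OR from
the *same* shuffle — one shared shuffle per iteration preserves the
cross-subset dependence of a composition and is S times cheaper than
independent nulls. The empirical *P* is the raw fraction of permuted ORs
with |log OR| at least the observed |log OR|. Two deliberate choices:

- deviation is measured as |log OR|, symmetric on the multiplicative
  scale, so enrichment (OR > 1) and depletion (OR < 1) are treated
  identically;
- no (b+1)/(m+1) smoothing and the observed statistic is not added to the
  null, so *P* = 0 is attainable at finite n_perm. Users who need
  strictly positive p-values should raise n_perm rather than expect
  smoothing.

An exhaustive mode enumerates all C(n, n_TG) relabelings instead of
sampling; it is the reference the sampled null converges to and is capped
at 500,000 relabelings.

**Multiplicity.** Benjamini–Hochberg step-up with enforced monotonicity,
implemented directly (and checked against independent references in the
tests). The default correction family is the subsets of one compartment
analysis — brain, meninges and pooled are corrected separately, mirroring
three separate per-tissue analyses; `fdr_family="global"` pools all rows
into one family.

**Defaults.** n_perm = 10,000; α = 0.05; per-compartment FDR; unassigned
cells excluded from denominators (`include_unassigned` to keep them —
they then form their own category and enter every "rest" count). With
n_perm iterations the smallest nonzero p is 1/n_perm, so q-values inherit
that granularity.

## Annotation stage

Cells are labelled from expression by recovery-curve AUC scoring. Genes
are ranked per cell (rank 1 = highest count; ties broken by ascending
gene index, a deterministic policy chosen over randomized tie-breaking so
annotation needs no ranking seed). For a signature S and window
k = ⌈top_fraction·n_genes⌉, the score is Σ_{x=1..k} |{g ∈ S : rank(g) ≤ x}|
normalized by its maximum Σ_{x=1..k} min(x, |S|), so full recovery scores
exactly 1 regardless of |S| and no recovery scores 0. Scores depend only
on ranks, hence are invariant under strictly monotone transforms of a
cell's counts — normalization is unnecessary by construction.

A cell's label is the argmax signature if the maximum score is unique and
≥ min_score, else "unassigned". Defaults: top_fraction = 0.05 (the
conventional top-5% ranking window), min_score = 0.1. Signatures sharing
no gene with the matrix are skipped with a warning; an explicitly scored
empty intersection is an error.

## Synthetic data generator

The generator emulates the study design the statistics assume: five CD8⁺
subsets (Tcm, T effector, CD103⁻ Trm, proliferating Trm, CD103⁺ Trm) in
four strata (WT/TG × brain/meninges). Subset labels are drawn i.i.d. per
cell from the stratum's categorical distribution — no per-animal
hierarchy is modelled, because the test itself treats cells as
exchangeable units within genotype; consequences of real within-animal
correlation (overdispersion of composition, pseudoreplication) are
outside what passing tests demonstrate.

Default composition: brain CD103⁻ Trm 0.459 (WT) vs 0.7369 (TG) and
CD103⁺ Trm 0.2744 vs 0.098 — the observed genotype contrast (true ORs
3.30 and 0.29); meningeal CD103⁺ 0.1197 vs 0.1901 (true OR 1.73). The
meningeal CD103⁻ per-group fractions are not constrained by the observed
data, so the WT fraction is anchored at 0.50 and the TG fraction derived
from a mild depletion odds ratio of 0.72 (p = 0.72/1.72 ≈ 0.4186). The
remaining mass of each stratum is split across Tcm : T effector :
proliferating at 4.52 : 11.43 : 4.29, their pooled relative frequencies.
Proportions are validated to sum to 1 per stratum within 1e-9.

Counts are negative binomial with mean μ and size (dispersion) r:
Var = μ + μ²/r; the Poisson model is the documented r → ∞ limit. A
marker gene's mean in its own subset is baseline_mean × marker_fold_change,
baseline_mean everywhere else. Defaults: n_genes = 200 (33 marker genes
from the subsets' published marker lists, padded with g0001… fillers),
baseline_mean = 2 counts, r = 2 (typical scRNA-seq overdispersion),
marker_fold_change = 8, 1,000 cells per stratum (the real per-stratum
cell counts are unpublished — only 3,098 CD8⁺ cells in total — so the
size is a free parameter sized for fast, well-powered tests). Not
modelled: library-size variation, doublets, batch effects, gene–gene
correlation; annotation accuracy measured here is therefore an upper
bound on real-data performance.

Everything is seeded through `numpy.random.default_rng`; one run seed
drives labels, counts and the permutation streams (each analysed
compartment gets an independent child stream via `SeedSequence`), and
identical seeds give byte-identical artifacts.

## Test and acceptance problem sizes

The statistical checks run at sizes chosen to keep the suite fast while
leaving the binomial error bands narrow: type-I error over 1,000 null
replicates of 2,000 cells/group at n_perm = 500 (nominal 0.05, accepted
band 0.03–0.07); CI coverage over 2,000 tables of 500 cells/group
(accepted 93–97%); parameter recovery at 5,000 cells/group with
n_perm = 2,000; permutation-vs-enumeration agreement on ≤ 8-cell strata
where all C(n, n_TG) relabelings are enumerable exactly.

## Known limitations

- Wald CIs and the Woolf SE are large-sample devices; for tiny strata the
  permutation p is the trustworthy quantity and the CI only descriptive.
- The +0.5 correction biases the OR toward 1 in sparse tables (visible in
  the corrected single-subset identity value).
- Empirical p-values have resolution 1/n_perm; FDR on few subsets (5 per
  compartment here) is coarse.
- The annotation assignment rule (unique argmax over a fixed threshold)
  is intentionally simple; no bimodality-based per-signature thresholds.
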