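# trmshift

Permutation-calibrated analysis of cell-type composition shifts in
single-cell RNA-seq, built for the comparison of CD8⁺ T-cell subsets
between wild-type (WT) and 3xTg-AD (Alzheimer's model, "TG") mice across
two tissue compartments (brain and meninges).

## The problem and the method

Brains of 3xTg-AD mice accumulate CD103⁻CD8⁺ tissue-resident memory (Trm)
T cells while losing CD103⁺ Trm cells. To ask whether a subset's abundance
differs between genotypes, each cell is classified as belonging to the
focal subset ("yes") or any other subset in the same compartment ("no"),
giving a 2×2 table per subset. With per-group focal proportions
*p*<sub>WT</sub> and *p*<sub>TG</sub>, the effect size is the odds ratio

    OR = [ p_TG / (1 − p_TG) ] / [ p_WT / (1 − p_WT) ],

with log-scale standard error

    SE = sqrt( 1/n_WT,yes + 1/n_WT,no + 1/n_TG,yes + 1/n_TG,no )

and 95% CI `exp(log OR ± 1.96·SE)`. Zero cells get the Haldane–Anscombe
+0.5 correction (flagged in the output). Significance is not taken from
the Wald interval: group labels are reshuffled over the stratum's cells
(10,000 iterations by default, group totals fixed), every subset's OR is
recomputed from each shuffle, and the empirical *P*-value is the fraction
of permuted ORs deviating from 1 (on the log scale) at least as much as
the observed one — so *P* = 0 is attainable. Benjamini–Hochberg FDR is
applied across subsets within each compartment analysis (brain, meninges,
pooled).

Two supporting stages make the pipeline self-contained:

- **annotate** — rank-based gene-signature scoring: each cell's genes are
  ranked by count, each signature scored by the normalized area under its
  recovery curve over the top 5% of the ranking (an AUCell-style score),
  and cells labelled by their best signature above a threshold.
- **simulate** — a seeded generator producing per-cell label tables with
  the five-subset CD8⁺ composition (Tcm, T effector, CD103⁻ Trm,
  proliferating Trm, CD103⁺ Trm) per genotype and compartment, and
  negative-binomial count matrices with subset-specific elevated marker
  genes, so every stage is testable without downloading data.

## Worked example

```sh
trmshift simulate --seed 17 --n-cells 1000 --labels-only --out demo
trmshift test --cells demo/cells.tsv --n-perm 2000 --seed 17 \
    --out demo/report.tsv --json demo/report.json
```

prints, among other rows,

```
[brain] (alpha = 0.05)
  Tcm: depleted in TG (OR = 0.46, 95% CI 0.30-0.72, p = 0, q = 0)
  Teff: depleted in TG (OR = 0.55, 95% CI 0.42-0.71, p = 0, q = 0)
  Trm_CD103neg: enriched in TG (OR = 3.87, 95% CI 3.20-4.69, p = 0, q = 0)
  Trm_CD103pos: depleted in TG (OR = 0.28, 95% CI 0.22-0.36, p = 0, q = 0)
  Trm_prolif: depleted in TG (OR = 0.39, 95% CI 0.25-0.62, p = 0, q = 0)
```

The simulated brain stratum was generated at true ORs 3.30 (CD103⁻) and
0.29 (CD103⁺); at 1,000 cells per stratum the estimates (3.87 and 0.28)
carry sampling noise but land inside their Wald intervals, and both
subsets clear FDR with empirical *P* = 0 at 2,000 permutations.
`demo/report.tsv` holds the full per-subset table (counts, proportions,
OR, CI, p, q); `demo/report.json` adds the permutation-null percentiles.

The same analysis runs on real data from a labelled cell table
(`cell_id  group  compartment  subset`, TSV), or from a Matrix-Market
count matrix plus a GMT signature file via `trmshift annotate`.
`trmshift run --config cfg.yaml` chains simulate → annotate → test and
writes all artifacts plus a resolved config and run log into one
directory.

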