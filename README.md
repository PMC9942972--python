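# attractorscape

Gene-expression landscapes of cancer: reference-anchored PCA of bulk
expression cohorts, treating the normal and tumor states of a tissue as
attractors in gene-expression space.

Given a gene × sample FPKM matrix with normal and tumor samples, the
package

1. regularizes the data (`+0.1` pseudocount) and normalizes each gene by
   the **geometric mean over normal samples**, working in log2 fold space
   `e_fold = log2((e + 0.1) / e_ref)`;
2. performs an **uncentered PCA** about the normal reference — the
   second-moment matrix `σ_ij = Σ_s e_fold_i(s) e_fold_j(s) / (N−1)` is
   eigendecomposed through an exact SVD factorization without ever forming
   the G × G matrix — so PC1 is a *cancer axis* and `x1 = e_fold·v1`
   measures a sample's progression from the normal to the tumor attractor;
3. derives the per-tissue **cancer gene profile** from `v1` (signed
   rankings, top-k gene sets) and the **integrated expression distribution
   functions** of the tumor center, whose over/under tails are power-like
   (Pareto) and are fitted in log-log coordinates;
4. compares profiles **across tumor localizations**: pairwise shared-gene
   counts, subgroup and pan-cancer intersections, distances between tumor
   centers in fold space, and the inverse distance-vs-shared-genes
   relation;
5. runs **attractor diagnostics**: age-stratified (NY/NO/TY/TO)
   distribution functions split at the cohort's median age, and
   stage-stratified normal-minus-tumor sample-density fields in the PC
   plane;
6. builds the **multi-tissue landscape**: normal/tumor centers per tissue,
   a common reference at the centroid of normal centers, and landscape PCA
   coordinates (e.g. the PC1/PC3 plane separating normal tissues from
   tumors).

A synthetic-cohort generator with planted ground truth (cancer axis with
Pareto fold magnitudes, structural zeros, aging genes, stage-dependent
progression, a cross-tissue shared DE core) makes every step testable
end-to-end; see `docs/methods.md` for the model and its assumptions.

Intended users: computational biologists analyzing bulk normal/tumor
expression cohorts (TCGA-style), and anyone who needs a tested
reference-anchored PCA with planted-truth simulations.

## Worked example

Simulate a default tissue (2,000 genes, 50 normal + 50 tumor samples,
200 planted differentially expressed genes) and run the pipeline:

```bash
attractorscape simulate --preset desk --seed 7 -o sim
attractorscape validate sim/SIM.matrix.tsv sim/SIM.samples.tsv
attractorscape fold sim/SIM.matrix.tsv sim/SIM.samples.tsv -o folds.tsv
attractorscape pca folds.tsv sim/SIM.samples.tsv -o model
attractorscape profile model sim/SIM.matrix.tsv sim/SIM.samples.tsv --top-k 210 -o prof
```

which prints

```
wrote 1 tissue(s) to sim/
ok: 2000 genes x 100 samples (50 normal, 50 tumor); 500 silent genes, 1499 above 0.1 FPKM
wrote folds.tsv and folds.reference.tsv
wrote model to model/
wrote profile to prof/
```

`model/report.json` shows the cancer axis carrying the bulk of the
variance about the normal reference — PC1 alone holds 41% of the trace
(`variance_fractions_of_trace: [0.408, 0.012, 0.009]`) — and records that
`v1` was flipped to the tumor-positive orientation. `prof/ranking.tsv`
ranks genes by |weight| on the axis:

```
gene_id  weight                sign  rank
G01620   -0.1937313981417599   -1    1
G00302    0.1655669419573135    1    2
G00152   -0.15806931042507     -1    3
```

and for this seed the top-210 set contains all 200 planted DE genes. The
tail fit in `prof/fits.json` reports the power-law slope of the tumor
center's over-expression tail (`alpha 2.46, R² 0.991`; the planted
per-gene Pareto(1.5) magnitudes are attenuated by the stage progression
factor, steepening the center tail) and the over/under balance at 2-fold
(`n_over 58, n_under 72`).

The same steps work on real data: any TSV expression matrix (genes ×
samples, FPKM) plus a sample table with `sample_id`, `tissue_code`,
`condition` (`normal`/`tumor`) and optional `age_years`/`stage` columns.
Multi-tissue runs use `attractorscape compare` for shared/pan-cancer gene
sets and `attractorscape landscape` for the cross-tissue picture; all
commands are thin wrappers over the library API (`attractorscape.pca`,
`.profile`, `.crosstumor`, `.attractor`, `.landscape`, `.synthetic`).

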