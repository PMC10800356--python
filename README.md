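# escreg

Inference of an embryonic-stem-cell-like co-expression **regulome** from
expression data, and the downstream single-cell analyses that regulome
supports: transcription-factor/histone-mark co-occupancy correlation,
per-cell signature scoring, cell-cycle phase assignment with exemplar
selection, and quantile-gated classification of quiescent stem-like cells.
The intended users are computational biologists studying primitive
haematopoietic and leukaemic stem cell states (e.g. CD34+CD38− compartments
in chronic myeloid leukaemia), where the quiescent, regulome-low fraction is
the therapeutically relevant one.

## The method

**Regulome construction.** Candidate genes are the intersection of pooled
signature gene sets (e.g. embryonic/adult stem-cell signatures) with the
union of differentially expressed genes passing `padj ≤ 0.05` and
`|log2FC| ≥ 0.5`. For every candidate pair (i, j) the Pearson correlation

    r_ij = Σ_c (x_ic − x̄_i)(x_jc − x̄_j) / √(Σ_c (x_ic − x̄_i)² Σ_c (x_jc − x̄_j)²)

is computed over cells c on log-normalized expression
`x = ln(1 + count · 10⁴ / cell_total)`. A gene joins the regulome when it
shows `r > 0.4` (strict) with at least `min_partners` other candidates
(default 1; the all-partners reading is available via `min_partners`).

**Co-occupancy.** Given a binary genes×factors occupancy matrix, the
correlation of two factors' 0/1 columns restricted to regulome genes equals
the phi coefficient `(ad − bc)/√((a+b)(c+d)(a+c)(b+d))` of their 2×2
co-occupancy table. Over-representation on the regulome is made testable by
subtracting the mean grid over size-matched random background gene draws.

**Cell states.** Signature scores are mean log-normalized expression over
the signature genes. Cell-cycle S/G2M scores subtract expression-matched
control genes (25 mean-expression bins, 50 controls per phase gene); phase
is the argmax when positive, else G1, and G1 cells with zero MKI67 are
relabeled G0. Quiescent cells are those below the median regulome score
with MKI67, CD38 and TP53 each below the 95th quantile among expressing
cells. Differential expression between cell groups uses the two-sided
Wilcoxon rank-sum test (exact enumeration for groups ≤ 8) with
Benjamini–Hochberg correction.

**QC** follows the standard single-cell gates: cells with fewer than 500
detected genes or more than 10% mitochondrial counts are excluded
(peripheral-blood mode) or 200 / 20% (PDX mode).

A synthetic-data generator (`escreg.simulate`) plants exactly this
structure — a lognormal-latent-driven gene module, phase programs, a
quiescent G0 subpopulation, mito-content bands, complex-structured binding
matrices, and two-condition bulk counts — so every stage is testable against
ground truth without downloads.

## Worked example

```
$ python examples/02_build_regulome.py
65 candidate genes (signatures ∩ significant DEGs)
regulome membership at PCC > 0.4: 50 genes (50/50 planted module genes recovered, 0 decoys admitted)
mean off-diagonal PCC across candidates: 0.306 over 2080 gene pairs
median within-module PCC: 0.531
```

The 65 candidates are the planted 50-gene module plus 15 decoys that pass
the DEG cutoffs but carry no correlation structure; the `r > 0.4` membership
gate keeps every module gene and rejects every decoy, because planted module
pairs correlate at ≈ 0.53 while decoy pairs sit near zero.

```
$ python examples/04_cell_states.py
phase counts: {'G0': 250, 'G1': 100, 'G2M': 75, 'S': 75}
accuracy vs planted phases: 0.936
quiescent gate: 250 cells called, precision 1.00, recall 1.00 (regulome-score threshold 0.497)
```

93.6% of cells receive their planted cycle phase, and the default
quiescence gate recovers the planted G0 subpopulation exactly: quiescent
cells occupy the regulome-low half of the score distribution with silent
markers. The remaining examples cover QC (`01`), co-occupancy contrast
(`03`), enrichment plus the worked Fisher statistic (`05`) and the
single-configuration pipeline (`06`). A thin CLI mirrors the stages
(`escreg simulate|qc|normalize|regulome|cooccupancy|de|enrich|fisher|run`).

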