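# nof1pathways

Pathway-level analysis of a **single pair** of transcriptomes.

Conventional differential-expression and geneset-enrichment pipelines need
replicated cohorts; a single case sample with its matched control (a
knockdown line vs its parental control, a tumor vs adjacent normal, a
patient before vs after treatment) leaves them powerless, because no
per-gene p-value exists at n = 1. `nof1pathways` treats the pair itself as
the statistical universe: a geneset ("mechanism" — a GO biological-process
term or KEGG pathway) contributes many paired gene measurements, enough to
support a within-pair test.

## The statistic

For one pair and one geneset *S*, form the paired log2 differences
d<sub>g</sub> = case<sub>g</sub> − control<sub>g</sub> for the measured
genes g ∈ S and apply the Wilcoxon signed-rank test: drop zeros, rank
|d| with midranks, and sum ranks of positive and negative differences into
W⁺ and W⁻. The comparison of W⁺ and W⁻ gives the geneset's direction
(up- or down-regulated); the two-sided p-value is exact (convolution over
the midranks, equivalent to enumerating all 2ⁿ sign assignments) for
n ≤ 25 and an Edgeworth-corrected normal approximation above that. Per
pair, p-values are adjusted across all m tested genesets (Benjamini–
Hochberg FDR and Bonferroni) and mapped to signed Z-scores
z = ±Φ⁻¹(1 − p/2).

Across multiple pairs, mechanisms are prioritized by the number of pairs
reaching Bonferroni ≤ 1%, listed from most to least shared. Mechanism
lists from different methods or studies are compared with a Fisher-exact
overlap odds ratio and with precision–recall curves in which a prediction
may match the gold standard either exactly or through Jiang's
information-theoretic GO similarity (ITS ≥ 0.7 counts as related).

## Worked example

Simulate a single-pair study with one planted up-regulated geneset, then
score it:

```bash
nof1 simulate --preset pair --n-genes 1200 --n-sets 25 --n-planted 1 \
    --delta 2 --seed 7 --out sim/
nof1 score --expr sim/pair1.tsv --case case --control control \
    --gmt sim/genesets.gmt --criterion bonf_01 --out pair1_scores.tsv
```

which prints

```
wrote 1 pair(s), 25 genesets, 1 planted, to sim
case_vs_control: 25 genesets scored, 1 significant at bonf_01
```

The planted set (`sim/truth.json` names it) is the single mechanism at
Bonferroni ≤ 1%; `pair1_scores.tsv` holds, per geneset, W⁺, W⁻, the
direction, raw/FDR/Bonferroni p-values and the signed Z. With several
scored pairs, `nof1 cohort --pairs pair1.tsv pair2.tsv ... --out cohort.tsv`
ranks mechanisms by the number of significant pairs, and `nof1 compare` /
`nof1 pr` quantify agreement between two mechanism lists (overlap odds
ratio + Fisher p; precision–recall with optional `--matching its`).

The same steps work on real data: a tab-delimited expression table
(`nof1 prepare` collapses alternative transcripts to the highest-expressed
one, log2-transforms linear RPKM values, and size-filters genesets to
15–500 measured members), any GMT geneset collection, and an OBO ontology
plus GAF/TSV annotations for the ITS layer.

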