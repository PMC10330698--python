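# txresponse

Comparative analysis of transcriptomic and immune-repertoire response to two
melanoma therapies — immune checkpoint inhibition (ICI) and MAPK-pathway
inhibition (MAPKi) — from paired pre-treatment (PT) and on-treatment (OT)
tumor biopsies.

The package is aimed at computational biologists who have, per patient, a
PT and one or more OT bulk RNA-seq biopsies with a clinical response label
(responder R = CR/PR/SD, non-responder NR = PD), and who want to ask: *which
genes, gene programs, and B/T-cell repertoire features distinguish a durable
response to one therapy from the other, and do they stratify survival?*

## What it computes

**Paired fold-change differential expression.** Counts are TMM-normalized
(trimmed mean of M-values) to log2 CPM and optionally batch-centered. For
each gene the per-patient paired change is

    log2FC(g, patient) = log2CPM(g, OT) − mean over that patient's PT samples

and the therapy-level responder contrast is

    Δlog2FC = mean(log2FC over OT-R pairs) − mean(log2FC over OT-NR pairs)

A gene is a responder-associated DEG when Δlog2FC ≥ 1 (a two-fold
difference of the arithmetic averages) and the BH-adjusted two-sample
t-test q-value is < 0.05. Therapy-specific response genes come from the
second difference

    ΔΔFC = Δlog2FC(therapy A) − Δlog2FC(therapy B)

selected at ΔΔFC ≥ 1 together with Δlog2FC(A) ≥ 1 (and symmetrically for
B).

**Gene-set machinery.** GMT parsing (the two tertiary-lymphoid-structure
signatures of 9 and 7 genes ship as a bundled fixture), rank-based
single-sample enrichment scores (weighted KS running sum, exponent 0.25,
with a mean-z alternative), marker-mean cell-population abundance, and
one-sided Fisher-exact over-representation with BH correction.

**Immune repertoire.** From AIRR-style clonotype tables: productive
filtering, convergent-clonotype merging (same CDR3aa, different CDR3nt),
richness, Shannon diversity H = −Σ pᵢ ln pᵢ, clonality = 1 − H/ln(richness),
and for IGH repertoires somatic-hypermutation lineage inference:
single-linkage clustering of CDR3 nucleotide sequences under normalized
Hamming distance within each (V, J, junction-length) partition, cut at a
threshold read automatically off the bimodal nearest-neighbor distance
distribution. The SHM frequency is the fraction of germline clones carrying
more than one mature clone.

**Survival.** Kaplan–Meier curves, log-rank tests, a Newton–Raphson Cox
proportional-hazards fit (Efron or Breslow ties), median stratification
("high" = median and above), and the 2×2 joint stratification of two
features with a Cox interaction model on the two high-indicators and their
product.

**Synthetic cohorts.** A first-class generator produces paired-biopsy
negative-binomial expression cohorts with planted responder effects,
power-law repertoires with SHM lineages, and proportional-hazards survival —
each with stored ground truth, so every stage is testable at desk scale.

## Worked example

Generate a miniature cohort and run the responder contrast for ICI:

```sh
txresponse simulate --out-dir demo/fixtures --seed 7 --n-per-arm 10 --n-genes 500
txresponse deg --counts demo/fixtures/counts.tsv \
    --annotation demo/fixtures/annotation.tsv \
    --therapy ICI --out demo/deg_ICI.tsv
# 9 up, 0 down -> demo/deg_ICI.tsv
```

The fixture plants 10 genes at Δlog2FC = 2 in ICI responders; 9 of the 10
are recovered with no false calls. The top of the result table:

```
gene    delta_fc    q
G00202  2.618       0.001
G00466  2.909       0.001
G00294  2.463       0.002
G00408  1.947       0.003
```

`delta_fc` is the responder-minus-non-responder mean paired log2 fold
change; `q` the BH-adjusted t-test p-value. Repertoire metrics on the same
fixture:

```sh
txresponse repertoire --clonotypes demo/fixtures/clonotypes.tsv --out demo/rep.tsv
```

```
sample_id  chain  richness  shannon  normalized_diversity  clonality  shm_frequency
S1         IGH    54        3.1410   0.7874                0.2126     0.2
```

i.e. 54 merged clones whose size distribution has Shannon entropy 3.14 nats
(evenness 0.79, clonality 0.21), and 20% of inferred germline clones carry
more than one SHM-derived mature clone. Joint survival stratification by the
two simulated protective features:

```sh
txresponse survival --records demo/fixtures/survival.csv \
    --feature1 feature1 --feature2 feature2 --out demo/surv.json
# log-rank p = 1.368e-05 over 4 strata -> demo/surv.json
```

The whole pipeline (normalize → paired FC → DEG/ΔΔFC → scores → repertoire →
survival) runs from one YAML config via `txresponse run-all --config
pipeline.yaml` and writes every intermediate table plus a JSON manifest.

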