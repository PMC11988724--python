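# promotif

Analysis toolkit for transcription-factor binding-site surveys of gene
promoters, built around the regulatory-genomics question of whether the
metabolic transcription factors **KLF14** and **SREBF-1** preferentially
bind the distal promoter region of orphan G-protein-coupled receptor
(oGPCR) genes, and how that compares with receptors already linked to
metabolic syndrome (GPCR-MetS).

It is aimed at computational biologists who have per-gene promoter
sequences (1000 bp upstream of the transcription start site, TSS) and
JASPAR-style motif matrices, and who want a reproducible path from raw
sequence to count-regression inference.

## What it computes

1. **Motif scanning.** A position frequency matrix is converted to a
   log-odds position weight matrix,
   `log2((n_bj + s·q_b) / (N_j + s) / q_b)`, and a per-site score
   threshold is calibrated to a target p-value (default 0.01) from the
   *exact* score distribution of a random background word, obtained by
   column-wise convolution on a discretized score grid. Both strands are
   scanned; hits carry TSS-relative positions (−1000…−1).
2. **Site classification.** Only plus-strand hits are "viable"; each is
   flagged as distal (position in [−1000, −750]) and as overlapping
   annotated enhancer/silencer intervals. Summaries aggregate per
   receptor class (A, B/Adhesion, C) and per gene.
3. **Similarity covariates.** Smith–Waterman local alignment of each
   site's sequence against the motif consensus, normalized by the maximal
   attainable score, averaged per gene — a [0, 1] covariate. Gene–gene
   distances (1 − Pearson r of promoter score profiles) feed a UPGMA tree.
4. **Clustering diagnostics.** Standardization, VAT reordering, PCA,
   k-means with K chosen by majority vote of elbow, silhouette and gap
   statistic, plus bootstrap Jaccard stability (recovery > 0.75,
   dissolution < 0.5).
5. **Count regression.** Distal-site counts are modelled as
   `log μ = β0 + β1·(plus-strand count) + β2·(similarity) [+ group terms]`
   under Poisson or NB2 (`Var = μ + μ²/θ`) likelihoods, with the
   residual-deviance overdispersion test, exponentiated effect tables
   (rate ratio `exp(β)`, percent change `100·(exp(β)−1)`), AIC/BIC, the
   Vuong comparison, and delta-method prediction intervals.

A synthetic-data module generates every input with known ground truth
(planted motif occurrences, known β and θ, planted clusters), and the
published per-class count tables are embedded as fixtures.

## Worked example

```python
import numpy as np
from promotif import (SimulationConfig, gen_pwm, gen_promoter_set,
                      build_log_odds, scan_promoters, filter_viable,
                      gen_count_dataset, fit_negbin, percent_change)

cfg = SimulationConfig(seed=11, n_genes=60, plant_rate=2.0)
pfm = gen_pwm(8, seed=4, sharpness=1.0)          # synthetic motif
promoters, truth = gen_promoter_set(cfg, pfm)    # 60 x 1000 bp
hits = scan_promoters(build_log_odds(pfm), promoters, alpha=0.01)
print(len(truth.planted_hits), len(hits), len(filter_viable(hits)))
# 121 614 317   -> every planted site is recovered; the remaining hits are
#                  background words passing the permissive p = 0.01 cutoff

df, truth = gen_count_dataset(SimulationConfig(seed=0, n_genes=2000,
                                               theta=1.3,
                                               beta=np.array([-0.8, 0.11, 4.3])))
fit = fit_negbin(df)
print(fit.beta.round(3), round(fit.theta, 3))
# [-0.733  0.11   4.188] 1.323
print(percent_change(fit.beta[1]))
# 11.6   -> each extra plus-strand site raises the expected distal count ~12%
```

The fitted dispersion θ̂ ≈ 1.32 matches the generating θ = 1.3, and the
plus-strand coefficient recovers the true 0.11 within its Wald interval —
the same magnitudes (θ ≈ 1.27, β ≈ 0.110, i.e. an 11.6 % increase per
site) reported for the KLF14 distal-count model in the motivating study.

The command-line interface mirrors the stages:

```sh
promotif run --mode synthetic --out-dir out --seed 42 --n-genes 30
promotif scan KLF14.pfm promoters.fasta hits.tsv --pvalue 0.01
promotif regress gene_features.tsv fit.tsv --tf klf14 --family auto
```

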