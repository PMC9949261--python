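# otsp — spike-in based amplification-bias normalization for TCRβ repertoires

Bulk TCRβ CDR3 sequencing from genomic DNA needs a multiplex PCR — here 20
V-segment forward primers crossed with 13 J-segment reverse primers — and
each of the 260 primer pairs amplifies with its own efficiency. The
resulting amplification bias distorts clonotype abundances and every
downstream repertoire metric. `otsp` implements the computational core of
an open TCR sequencing protocol that corrects this bias with equimolar
synthetic-template (ST) spike-ins: one 200-bp template per primer pair,
identified after sequencing by a 9-bp universal barcode and a 16-bp
pair-specific barcode.

## The model

Replicate counts for template *i* across a batch are modeled as negative
binomial with template-specific mean and common dispersion,

```
C_ij ~ NB(m_i, d),    E C = m,    var C = m + d m²,
```

so `d = 0` is Poisson and, for large m, `log v ≈ log d + 2 log m` (slope
≈ 2 on a log-log mean-variance plot). The MLE of `m_i` is the arithmetic
mean of template *i*'s counts, and `d` is the median of the per-template
profile-likelihood MLEs. Scaling factors are either batch means
`SF_i = C_i• / C••` or NB means `m_i / m•` (identical on a single batch);
primer-pair totals are divided by their factor and clonotype counts are
redistributed proportionally within each pair, which leaves within-pair
proportions untouched and conserves the ST grand total exactly for
batch-mean factors. Signed Pearson residuals `(O − E)/√E` on the V × J
grid diagnose dependence between primer pairs, and Shannon diversity /
clonality / hyperexpanded-fraction metrics summarize the normalized
repertoire.

The package ships a seeded simulator (NB count matrices, biased
repertoires, barcoded FASTQ fixtures) so the full pipeline is testable
without sequencing data, a barcode demultiplexer tolerant to one mismatch
or indel, sklearn-style estimators (`NegativeBinomialPanelModel`,
`SpikeInNormalizer`) wrapped by plain functions, and an `otsp` CLI.

## Worked example

```python
import numpy as np
from otsp import (PrimerPanel, BiasModel, simulate_st_counts, fit_panel,
                  nb_scaling_factors, spread_report)

panel = PrimerPanel.default()                      # 20 V x 13 J = 260 pairs
model = BiasModel.separable(panel, seed=1)         # ~55-fold efficiency spread
matrix = simulate_st_counts(model, n_samples=20, seed=2)

fit = fit_panel(matrix)
print(f"common dispersion d = {fit.common_dispersion:.4f}")
print(f"mean of template means m_bar = {fit.m_bar:.1f}")

sf = nb_scaling_factors(fit)
rep = spread_report(matrix, sf)
print(f"median Q3/Q1 raw        = {rep.per_sample['qratio_raw'].median():.2f}")
print(f"median Q3/Q1 normalized = {rep.per_sample['qratio_normalized'].median():.2f}")
print(f"max Q3/Q1 normalized    = {rep.per_sample['qratio_normalized'].max():.2f}")
```

prints

```
common dispersion d = 0.1164
mean of template means m_bar = 5005.7
median Q3/Q1 raw        = 3.39
median Q3/Q1 normalized = 1.62
max Q3/Q1 normalized    = 1.72
```

The fitted common dispersion recovers the simulated truth (d = 0.125)
from 20 replicates, and the within-sample template-to-template spread —
several-fold before correction — drops below two-fold in every sample
after NB-mean normalization.

The same stages are available from the shell:

```bash
otsp simulate --design-out design.yaml --counts-out st.tsv --seed 1
otsp fit --counts st.tsv --out fit.tsv
otsp factors --fit fit.tsv --out sf.tsv
otsp normalize --factors sf.tsv --clones clones.tsv --out normalized.tsv
otsp metrics --clones normalized.tsv --normalized --out metrics.tsv
```

or end to end via `otsp run --config config.yaml` (see
`otsp.pipeline.RunConfig`).

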