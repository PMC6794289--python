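# pmrna — post-mortem RNA degradation kinetics and PMI estimation

After death, transcription stops but RNA degradation continues, and each
transcript decays at its own rate. Because RNA sequencing observes a fixed
number of reads per sample, uniform decay is invisible: only decay
*relative to the transcriptome average* shows up, so slowly decaying genes
appear relatively upregulated ("preserved") and fast decayers relatively
downregulated ("degraded"). This matters to anyone analysing tissues
collected post-mortem — eye banks, brain banks, GTEx-style cohorts — where
the post-mortem interval (PMI, death to RNA stabilisation) varies between
donors and can masquerade as disease signal.

`pmrna` implements that whole analysis as a tested, reusable pipeline on
synthetic data:

- **Compositional decay simulator** — per-gene exponential decay
  `a_g e^{-λ_g t}` with no synthesis term; expected counts at depth `L` are
  `L · p_g(t)` with `p_g(t) = a_g e^{-λ_g t} / Σ_h a_h e^{-λ_h t}`;
  negative-binomial replicate noise with variance `μ + BCV²·μ²`
  (BCV 0.1 ≈ genetically identical model organisms, 0.4 ≈ human data).
  Also simulates qRT-PCR Ct panels (`Ct = c₀ − log₂ abundance + ε`) and
  homolog maps.
- **Preserved/degraded classifier** — CPM normalisation, the
  CPM ≥ 1-in-≥ 4-samples expression filter, Cox–Reid adjusted-profile
  common and empirical-Bayes tagwise dispersion (BCV = √φ), a
  negative-binomial likelihood-ratio test of each PMI against the 0 h
  baseline, Benjamini–Hochberg adjustment per contrast, and classification
  at q ≤ 0.05 with MD-plot data and per-PMI count tables.
- **Marker selection** — per-timepoint BCV < 0.075 filter, Z-score
  timelines of mean log₂ CPM, OLS slope/R² screening, top 9 positive- and
  9 negative-slope candidates.
- **PMI estimator** — within-animal ΔCt normalisation, ordinary least
  squares of `PMI ~ 1 + ΔCt_g1 + ΔCt_g2 + ΔCt_g3` over **every** 3-gene
  combination of the 18-gene panel (C(18,3) = 816 models), F-test p-value
  screening, and the unweighted mean of the retained models' estimates as
  the final PMI; leave-one-animal-out (LOAO) cross-validation.
- **Homolog overlap** — drop-unmapped / keep-lowest-numeric-ID homolog
  resolution, cross-species and cross-tissue overlap tables, biotype
  breakdowns, and the intra-species vs intra-tissue overlap ratio.

## Worked example

```python
from pmrna import (DecayDEModel, PmiEnsembleModel, SimDesign,
                   generate_decay_model, simulate_counts, simulate_ct_panel)

model = generate_decay_model(n_genes=5000, seed=1)
design = SimDesign(species="mouse", tissue="retina",
                   library_size=1_000_000, bcv=0.1, seed=2)
experiment = simulate_counts(model, design)

results = DecayDEModel(experiment, alpha=0.05).fit(contrasts=[0.25, 6.0, 24.0])
print(results.summary())

panel = simulate_ct_panel(model, model.genes[:18], ct_noise_sd=0.25, seed=3)
fit = PmiEnsembleModel(panel, p_threshold=0.05).fit()
print(fit.summary())
loao = fit.loao()
print(f"LOAO MAE: {loao.mae:.2f} h, RMSE: {loao.rmse:.2f} h")
```

prints

```
Post-mortem decay DE classifier
===============================================
genes tested:        5000
samples:             36
common BCV:          0.1002
tagwise prior df:    10.0
alpha (q threshold): 0.05

DE calls vs 0 h baseline:
           n_preserved  n_degraded  n_not_de
pmi_hours
0.25                 0           0      5000
6.00               453         510      4037
24.00             1291        1910      1799

PMI regression ensemble
===============================================
panel genes:             18
animals:                 20
candidate 3-gene models: 816
retained models:         760 (p <= 0.05)
skipped singular:        0
aggregation:             mean
retained model r2:       median 0.869, range [0.383, 0.987]
LOAO MAE: 1.85 h, RMSE: 2.35 h
```

The classifier recovers the generating replicate noise (common BCV 0.100),
calls no genes at 15 min but thousands by 24 h — the compositional
relabelling of slow vs fast decayers — and the exhaustive 3-gene ensemble
(816 candidate regressions, 760 retained at p ≤ 0.05) predicts each
held-out animal's PMI to within about two hours here. A marker panel
chosen by the selection stage, rather than the first 18 simulated genes,
does substantially better (fractions of an hour; see the pipeline report).

The same flow is available from the shell:

```bash
pmrna config-template --out config.yaml
pmrna run-all --config config.yaml --out runs/demo
cat runs/demo/report.md
```

`run-all` chains simulate → filter → de → select → train-pmi → eval-pmi →
overlap, writes every stage table as TSV/CSV with `#seed`/`#config_hash`
headers, and renders a markdown report.

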