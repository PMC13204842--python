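# cd138sno

Compartment-specific CD138 (syndecan-1) analysis for invasive breast cancer:
four-group tumor/stroma immunohistochemistry (IHC) classification, a
TPM-based differential-expression screen, snoRNA host-gene annotation, ssGSEA
signature and snoRNA module scoring, and the survival/association statistics
that tie them together — plus a synthetic-cohort generator so the entire
pipeline can be exercised and validated without access to patient data.

## The problem and the model

CD138 is a transmembrane heparan sulfate proteoglycan expressed by both tumor
epithelial cells and tumor stroma, and its prognostic meaning depends on
*which compartment* expresses it. Each tumor is scored separately in the two
compartments on the usual semi-quantitative intensity scale (0 negative, 1+
weak, 2+ moderate, 3+ strong). Intensity cutoffs — chosen by ROC analysis
against the recurrence endpoint, maximizing Youden's J = sensitivity +
specificity − 1 — dichotomize each compartment (tumor positive at 2–3,
stroma positive at 1–3), giving four groups:

| group | tumor | stroma | phenotype |
|---|---|---|---|
| 0 | − | − | double negative |
| 1 | + | − | aggressive phenotype |
| 2 | − | + | stroma only |
| 3 | + | + | double positive |

Downstream, Group 1 (tumor-positive/stroma-negative) is contrasted with the
pooled other groups:

* **DEG screen** — on log₂(TPM+1), a gene is differentially expressed when
  |Δ mean log₂(TPM+1)| ≥ 1 between Group 1 and the rest and the two-sided
  Welch *p* < 0.05; Benjamini–Hochberg FDR is attached for volcano plots and
  enrichment use.
* **snoRNA annotation** — Group-1-enriched snoRNAs are mapped to host genes,
  box class (H/ACA → pseudouridylation Ψ, C/D → 2′-O-methylation), and rRNA
  targets; host genes are deduplicated before hypergeometric
  over-representation testing against any GMT collection.
* **Signature scoring** — per-sample ssGSEA enrichment scores (rank weight
  α = 0.25) for the CD138-positive (S100A7, CD24, GLYATL2) and CD138-negative
  (RERG, SLC39A6, NAT1, SCUBE2, PIP, NPY1R, SLC7A2, GRIA2, FSIP1, PTPRT,
  SERPINA3) programs, and a snoRNA module score = mean TPM over the
  Group-1-enriched snoRNA set.
* **Survival statistics** — Kaplan–Meier/log-rank for recurrence-free
  survival, Cox proportional hazards (Efron ties, Wald CIs, Schoenfeld
  residual check, Harrell's C-index), chi-square/Fisher association tables,
  Mann–Whitney and Spearman comparisons of the scores.

The synthetic generator plants all of this structure — group proportions
45/35/19/12 per 111 cases, signed log₂ marker shifts for Group 1, a Group-1
recurrence hazard ratio of 4.877 with ~20% events — so recovery of the known
truth is a testable property.

## Worked example

Run the full pipeline on a simulated default cohort:

```bash
cd138sno run --config config.yaml --out out/ --seed 19
```

with `config.yaml` simply containing `simulate: {}`, or from Python:

```python
from cd138sno import PipelineConfig, SimulationConfig, run_pipeline

report = run_pipeline(PipelineConfig(simulate=SimulationConfig(),
                                     outdir="out", seed=7))
print(report.metadata["group_counts"])
print(int(report.degs["is_deg"].sum()), "DEGs")
print(report.host_genes)
print(round(report.survival["cox_univariable"]["cd138_group1"]["hr"], 2))
```

which prints (seed 7):

```
{'0': 38, '1': 42, '2': 19, '3': 12}
25 DEGs
['RPL23', 'TAF1D', 'HSPA8', 'RPL10', 'TOMM20', 'CCT6P3', 'SF3B3', 'EIF4A1']
5.1
```

Read: the cohort split across the four IHC groups roughly as 45/35/19/12
would predict; the DEG screen recovered exactly the 25 planted marker genes
(11 snoRNAs, 3 up- and 11 down-regulated protein-coding genes); the up-regulated
snoRNAs annotate to 8 unique host genes; and the univariable Cox hazard ratio
for Group 1 (5.1) recovers the planted 4.877 within sampling error at n=111.
Stage outputs (`groups.tsv`, `degs.tsv`, `volcano.tsv`, `annotations.tsv`,
`scores.tsv`, `survival.json`, `contingency.tsv`, `report.json`) are written
under `out/`.

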