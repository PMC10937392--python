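# dccd — TME-based molecular subtyping of ccRCC and DCCD scoring

`dccd` is a Python library for tumor-microenvironment (TME) based
molecular subtyping of clear cell renal cell carcinoma (ccRCC) bulk
transcriptomes, and for quantifying **de-clear-cell differentiation
(DCCD)** — the loss of the lipid-laden "clear cell" phenotype — per
sample or per cancer cell. It is aimed at computational biologists who
have a bulk TPM cohort (and optionally labeled single-cell data, a
metabolite matrix, and clinical follow-up) and want the complete
subtyping workflow as tested, importable functions.

The pipeline:

- derives cell-type **signature genes** from labeled single-cell data
  (one-vs-rest Wilcoxon, |log2FC| > 1, adjusted p < 0.001, top 60 per
  cluster, de-duplicated union);
- assigns four immune subtypes **IM1–IM4** by resampled consensus
  clustering on the signature-gene TPM submatrix, with k selected by the
  CDF delta-area criterion (pinned at k = 4 in the pipeline);
- extends the subtypes to new cohorts by **nearest-template prediction**
  (NTP): correlation distance to binary subtype templates with
  gene-permutation p-values and BH FDR;
- computes the **DCCD score** per entity from single-sample GSEA
  (ssGSEA) scores of the IM2 and IM4 signatures,

      DCCD = z(ssGSEA_IM4) − z(ssGSEA_IM2),

  calling entities IM4-like (DCCD > 0) or IM2-like (DCCD < 0), and ranks
  samples by the score as the bulk pseudotrajectory;
- provides the surrounding statistics: odds-ratio grids for subcluster ×
  subtype preference (enriched if OR > 1.5, adj. p < 0.05), Wilcoxon
  differential abundance, the metabolomic DA score
  (n_up − n_down)/n_measured, Kaplan–Meier curves and gated pairwise
  log-rank tests.

A synthetic-data module plants all of this structure (subtypes, markers,
mixing gradients, pathway shifts, subtype-dependent hazards) with a
recorded ground truth, so the whole pipeline is testable end to end
without any download. See `docs/methods.md` for the models, defaults and
limitations.

## Worked example

Score a synthetic IM2↔IM4 gradient cohort (from `examples/04_dccd_scoring.py`):

```python
from dccd import (default_bulk_signatures, simulate_bulk_cohort,
                  dccd_score, pearson)

sigs = default_bulk_signatures()
expr, meta, truth = simulate_bulk_cohort(
    n_samples=150, signatures=sigs, dccd_gradient=True, seed=2)
res = dccd_score(expr, sigs["IM2"], sigs["IM4"])
print(res.head(3)[["entity_id", "dccd_score", "label", "rank"]])
r, _ = pearson(res.set_index("entity_id")
               .loc[truth.dccd_mixing_fraction.index, "dccd_score"],
               truth.dccd_mixing_fraction)
print(f"correlation with planted mixing fraction: r = {r:.3f}")
```

prints

```
  entity_id  dccd_score     label  rank
0     B0000   -1.096395  IM2-like    56
1     B0001   -2.390916  IM2-like    26
2     B0002    2.370466  IM4-like   133
```

followed by `correlation with planted mixing fraction: r = 0.989` — each
sample's DCCD score (difference of z-scored IM4 and IM2 ssGSEA scores)
recovers its planted position on the IM2→IM4 continuum almost exactly;
positive scores are IM4-like samples, and `rank` orders the cohort along
the pseudotrajectory.

Other capabilities are demonstrated the same way in `examples/`
(signature extraction, consensus subtyping, NTP classification,
metabolite DA scores, survival), and the full driver is available as
`dccd run` or `dccd.run_pipeline(RunConfig(...))`. A thin CLI mirrors
each stage (`dccd simulate|score|markers|cluster|classify|dccd|enrich|survival|run`).

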