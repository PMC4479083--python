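# serialdex

Serial tumor gene-expression analysis for neoadjuvant chemotherapy (NAC)
cohorts. Patients in a neoadjuvant trial are biopsied up to three times —
before treatment (**T1**), 24–96 hours after the first chemotherapy dose
(**T2**) and at surgery (**TS**) — yielding paired log2-ratio expression
profiles with incomplete pairing, print-batch artifacts, and clinical
annotations: residual cancer burden (RCB, dichotomized 0/I = responder vs
II/III = nonresponder) and recurrence-free survival (RFS). `serialdex`
implements the full analysis workflow for such cohorts as a tested Python
library, plus a synthetic-cohort generator so every stage is verifiable
without clinical data.

## What it computes

- **Normalization** — replicate probes collapsed by per-gene averaging;
  print-batch effects removed per gene by the residuals of the one-way fit
  `x ~ batch` (closed-form: batch-mean subtraction).
- **Paired time-point contrasts** (T1 vs T2; T1 vs TS in residual disease) —
  paired permutation test on `t = d̄ /(s_d/√n)` with a sign-flip null
  (exhaustive when `2^n` fits the budget), Benjamini–Hochberg adjustment,
  adjusted *p* < 0.05.
- **Outcome contrasts** (responder vs nonresponder at T1, T2 and for the
  early change T2−T1) — label-permutation test on the Welch *t* statistic,
  relaxed raw *p* < 0.005 without multiplicity correction.
- **Molecular subtyping** — nearest-centroid calls against a user-supplied
  panel (Spearman or Pearson), paired concordance as
  `round(100 · identical/pairs)` with a label-transition table.
- **Survival screens** — per-gene Cox proportional hazards
  (`h(t|x) = h₀(t)·e^{βx}`, Breslow ties, Newton–Raphson), likelihood-ratio
  *p* on 1 df, optional hormone-receptor adjustment; TS and TS−T1 screens
  restricted to residual disease (RCB I/II/III); tertile dichotomization,
  Kaplan–Meier curves and log-rank tests for illustration; paired Wilcoxon
  signed-rank with an exact small-sample null.
- **Overrepresentation** — one-sided Fisher exact test of each gene set
  against the tested universe, *p* < 0.05.
- **Synthetic cohorts** — a documented generative model planting
  subtype-centroid structure, batch offsets, a T2 downshift of
  proliferation/immune genes, response-linked early changes and
  TS-expression-linked recurrence hazards, with a truth record for
  sensitivity/FDR scoring.

## Worked example

```python
from serialdex import SimConfig, residualize_batch, run_contrast, simulate_cohort, truth_eval

expr, meta, truth = simulate_cohort(SimConfig(seed=1))   # 2000 genes, 48 patients
norm = residualize_batch(expr, meta)
res = run_contrast(norm, meta, "t1_vs_t2", n_perm=10_000, seed=1)
print(len(res.significant), res.n_up, res.n_down)
sens, fdr = truth_eval(set(res.significant), truth.t2_marginal_shift_genes,
                       list(norm.feature_ids))
print(round(sens, 3), round(fdr, 3))
```

prints

```
283 16 267
0.996 0.085
```

i.e. 283 of 2000 genes change significantly between T1 and T2 across the 36
complete pairs, overwhelmingly *down* at T2 — the planted
chemotherapy-induced suppression of proliferation/immune genes — recovered
with 99.6 % sensitivity at an observed false-discovery proportion of 8.5 %.
The scripts in `examples/` walk through each capability the same way
(simulation, DE, subtype concordance, survival screens, enrichment, and the
one-command `run_all` pipeline); a thin CLI (`serialdex simulate|normalize|
de|subtype|survival|enrich|run-all`) wraps the same functions for shell use.

## Documentation

`docs/methods.md` describes the statistical model of each stage, the
generative model and defaults of the synthetic cohort, numerical and
tie-breaking conventions, and known limitations.
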