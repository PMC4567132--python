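# xciscope

Calling X-chromosome-inactivation (XCI) status in tumor cohorts from
CpG-island methylation, *XIST* expression and copy-number segments — with the
downstream association and survival statistics, and a synthetic-cohort
generator so the whole pipeline is testable end to end without any external
data.

## The scientific problem

Female somatic cells silence one X chromosome (the inactive X, Xi) for dosage
compensation; the long noncoding RNA *XIST* coats and maintains it, and the
Xi's CpG islands are characteristically methylated. Tumors — particularly
serous carcinomas with high copy-number instability — can lose XCI in two
ways: by mitotic segregation error that leaves two active X copies (**two
Xa**: X-wide CpG-island hypomethylation, low *XIST*, no whole-X deletion), or
by partial demethylation of the Xi that accompanies global hypomethylation
(**Xa+**: partial hypomethylation with retained *XIST*). Because many
cancer-testis antigens (CTAs) — candidate immunotherapy targets — are
X-linked and epigenetically silenced, XCI loss is a candidate mechanism for
their aberrant expression, confounded with global hypomethylation.

`xciscope` infers a three-way XCI status per tumor and quantifies its
associations with CTA expression, global methylation and clinical outcome.

## The procedure

1. **Cluster**: per histology stratum, hierarchical clustering (complete
   linkage, Euclidean distance) of samples on X-chromosome CpG-island beta
   values, cut to *k* = 3 clusters. Clusters whose two subtrees carry
   different evidence signatures are split further (see
   `docs/methods.md`).
2. **Characterize**: each cluster's median sample-mean beta → hyper / partial
   / hypo; median *XIST* log2(RSEM+1) → high / low.
3. **Arm evidence**: per sample, length-weighted mean seg-mean over each chrX
   arm (deleted ≤ −0.3, gained ≥ +0.3) and per-arm island methylation.
4. **Assign**: (hyper, high) → preserved Xi; (partial, high) → Xa+;
   (hypo, low) → two Xa. A sample whose *selective* one-arm hypomethylation
   coincides with a deletion of the same arm has lost an arm of the Xi, not
   of the Xa — it keeps an intact Xi and is reassigned to preserved Xi
   (the override). Hypomethylation with both arms deleted is whole-X loss
   (one Xa, no dosage gain) and is reported as preserved-Xi-equivalent.

Downstream: CTA-panel means (mean over panel genes of log2(RSEM+1)) and
global CpG-island methylation compared by Welch *t* / one-way ANOVA; clinical
covariates by a generalized **r×c Fisher exact test** (exact enumeration of
the fixed-margin distribution, seeded Monte-Carlo above a size bound);
survival by Kaplan–Meier with the k-group log-rank test and stage-adjusted
Cox proportional hazards (Efron ties).

## Worked example

```python
from xciscope import (SimulationConfig, generate_cohort, classify_cohort,
                      crosstab, fisher_exact_rxc, km_logrank, cox_stage_adjusted)

meth, expr, seg, clin, man, truth = generate_cohort(SimulationConfig(seed=1))
calls = classify_cohort(meth, man, seg, expr, clin)

print(calls["xci_group"].value_counts().to_string())
# preserved_Xi    120
# Xa_plus         120
# two_Xa          120
print((calls.set_index("sample_id")["xci_group"] == truth.df["true_xci"]).mean())
# 1.0         <- every sample recovers its simulated XCI state
print(int(calls["override_applied"].sum()))
# 5           <- simulated Xi-arm-deletion cases rescued to preserved Xi

merged = calls.set_index("sample_id").join(clin.df, rsuffix="_clin")
res = km_logrank(merged["os_time"], merged["os_event"], merged["xci_group"])
print(f"logrank chi2={res.logrank_statistic:.2f} p={res.logrank_p:.4g}")
# logrank chi2=9.54 p=0.008483
cox = cox_stage_adjusted(merged["os_time"], merged["os_event"],
                         merged["xci_group"], merged["stage"])
print(cox.cox.round(3).to_string())
#                 hr  ci_low  ci_high      p
# stage_III    3.781   2.791    5.123  0.000
# stage_IV     5.719   3.561    9.183  0.000
# xci_Xa_plus  1.452   1.042    2.022  0.027
# xci_two_Xa   1.532   1.104    2.128  0.011
```

The cohort is generated with a true XCI-loss hazard ratio of 1.6 plus a stage
confounder, so the marginal log-rank difference is significant while the
stage-adjusted per-group hazard ratios land near 1.5 — the attenuation
pattern the survival stage is designed to expose.

There is also a CLI:

```bash
xci-scope run --config examples/demo_config.yaml
xci-scope simulate --seed 1 --outdir cohort/
xci-scope classify --methylation cohort/methylation.tsv --manifest cohort/probe_manifest.tsv \
    --seg cohort/copy_number.seg --expression cohort/expression.tsv \
    --clinical cohort/clinical.csv --out calls.tsv
```

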