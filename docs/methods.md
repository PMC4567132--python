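# Methods

## Data model

All stages operate on five in-memory containers: a probes × samples matrix of
methylation **beta values** (the fraction of methylated signal, in [0, 1],
NaN = missing) with a probe manifest (chromosome, 1-based position,
CpG-island flag; chr1–chr22 and chrX only — XCI analysis concerns female
karyotypes, so the Y is not modeled); per-sample copy-number **segments**
with log2 tumor/normal seg-means (SEG dialect, 1-based inclusive,
non-overlapping per sample and chromosome); a genes × samples **RSEM**
expression matrix (non-negative); and a clinical table (histology, TCGA
molecular subtype, age, stage grouped as I–II / III / IV, menopause, race,
ethnicity, residual tumor, OS/DFS times in days with event indicators).
Expression is analyzed throughout as log2(RSEM + 1); "log-transformed RSEM"
is otherwise ambiguous and this choice keeps zeros finite.

## XCI classification

**Probe selection.** X-chromosome CpG-island probes only: CpG islands are the
principal methylation substrate of the inactive X, so island probes carry the
XCI signal while non-island probes mostly add noise.

**Missing betas** are imputed per probe by the median over the histology
stratum; probes with no observed value in a stratum are dropped (logged).

**Clustering.** Agglomerative clustering with complete linkage on Euclidean
distances between samples' X-island beta vectors, separately per histology
(serous and endometrioid tumors differ too much in baseline methylation to
share a dendrogram). The distance metric is a design choice; complete linkage
is the procedure's defining agglomeration rule. The dendrogram is cut into
`k` = 3 clusters (three biological states are expected per stratum) by
splitting the highest merge first, ties broken by node id, so degenerate
inputs (all samples identical) still yield exactly `k` deterministic
clusters. Inference uses no random numbers anywhere.

**Refinement of the cut.** A fixed `k`-cut can fuse two biologically distinct
groups. The failure mode is concrete: Xa+ and two-Xa tumors are closer to
each other in island-methylation space (mean beta ≈ 0.25 vs ≈ 0.10) than
either is to preserved-Xi tumors (≈ 0.45), so whenever a few Xi-arm-deleted
samples — whose profiles are half preserved-Xi, half two-Xa — form a cluster
of their own, the third cut merges Xa+ with two-Xa and the cluster-level
assignment mislabels an entire state. The classifier therefore treats a
cluster as heterogeneous, and splits it along its top merge, when (a) its
two subtrees differ in evidence signature (methylation class or XIST class),
or (b) its own signature is biologically contradictory — island
hypomethylation with high XIST (no methylated Xi yet XIST present) or
hypermethylation with low XIST. Refinement recurses until all clusters are
signature-homogeneous or smaller than `min_split_size` (default 4).
Contradictions that survive refinement are flagged on the calls
(`conflict_meth_xist`) and resolved by the methylation class, which is the
better-measured axis.

**Thresholds.** Cluster methylation class uses the median over members of the
sample-mean island beta: hyper ≥ `t_hyper` = 0.35, hypo ≤ `t_hypo` = 0.18,
partial between. XIST class uses the median member log2(RSEM+1) against
`t_xist` = 6.5, or `unknown` when more than half the members lack expression
data (such samples are still classified, by methylation and copy number
alone, and flagged `low_confidence_no_xist`). Arm-level copy number uses the
length-weighted mean seg-mean over the arm with a ±0.3 cutoff; an arm with
under 50% segment coverage, or no data, is treated as neutral (absence of
evidence), with a warning. All four numbers are calibration constants
exposed in `InferenceConfig` — the underlying assignment procedure is
visual/qualitative, and these defaults were chosen to separate the
generator's states, not estimated from any external cohort.

**Assignment.** (hyper, high) → preserved_Xi; (partial, high) → Xa_plus;
(hypo, low) → two_Xa. Two per-sample overrides:

* *Xi-arm loss*: selective hypomethylation of exactly one arm (mean island
  beta ≤ `t_hypo` on that arm, not on the other) coinciding with a deletion
  call on the **same** arm means the deleted arm belonged to the Xi — the
  remaining Xi is intact, so the sample is reassigned preserved_Xi with
  `override_applied = true`. p and q arms are treated symmetrically.
* *Whole-X loss*: a hypomethylated sample with both arms deleted has a single
  Xa and no X dosage gain; it is reported as preserved-Xi-equivalent with a
  `whole_X_loss` flag rather than as two_Xa.

Every call stores its evidence fields, and the assignment rule is a pure
function of them (`rederive_group`), so emitted calls are auditable: the test
suite re-derives each group from its stored evidence.

A purely per-sample mode (`per_sample_assignment=True`) classifies each
sample on its own mean beta and XIST value, bypassing clustering, for
robustness studies.

## Synthetic cohorts

The generator emulates the joint structure the classifier exploits, with
known ground truth. Defaults (all exposed in `SimulationConfig`):

| quantity | default | rationale |
|---|---|---|
| samples per histology × state cell | 60 | a 360-tumor cohort, comparable to a TCGA-scale study |
| X-island beta mean (preserved / Xa+ / two Xa) | 0.45 / 0.25 / 0.10 | half-methylated Xi; partial demethylation; near-complete loss |
| beta concentration (pseudo-counts) | 50 | per-probe SD ≈ 0.07, a clean-but-noisy array |
| XIST log2(RSEM+1) mean per state | 7.9 / 8.3 / 5.4 (SD 1.0) | typical endometrial-carcinoma group means |
| autosomal island beta mean per state | 0.35 / 0.28 / 0.25 | global hypomethylation coupled to XCI loss |
| CTA coupling | log2 expr = 6 · (1 − global methylation) + N(0, 0.5) | CTA expression driven by global hypomethylation **only** |
| Xi-arm deletion fraction | 5% of preserved-Xi tumors | rare arm-level losses of the Xi; arm p/q chosen at random; seg-mean −0.8 on the deleted arm, island betas drop to the two-Xa level there, XIST stays high |
| survival | exponential, baseline 2.5×10⁻⁴/day; log-HRs: stage III ln 4.24, stage IV ln 7.31, XCI loss ln 1.6; uniform censoring 1–10 years | stage is the deliberate confounder; XCI-loss HR 1.6 is the effect the Cox stage should recover |

Beta values are Beta(mean·c, (1−mean)·c) draws — the natural bounded
distribution, with separation tunable through one concentration parameter.
The chrX geometry is synthetic: 155 Mb with the centromere at 60 Mb
(configurable). Age, menopause, race, ethnicity, residual tumor and TCGA
subtype are drawn from per-state categorical distributions typical of an
endometrial-carcinoma cohort (XCI-loss patients older and postmenopausal).
Everything derives from a single `numpy` generator, so config + seed is
fully reproducible.

Two deliberate design points: CTA expression depends on global methylation,
*not* on XCI state per se, so the CTA/XCI association downstream is genuinely
confounded — the association stage demonstrates the confounding rather than a
direct effect. And Xi-arm-deleted samples are generated **within** the
preserved-Xi truth state, so the classifier's override rule is directly
scored by the ground truth.

**What the generator does not emulate:** probe-specific 450K noise and
bimodal probe-type effects, allele-specific methylation, spatial correlation
along the chromosome, copy-number noise beyond a single seg-mean jitter,
competing risks, or cohort-level missingness patterns (missing betas / XIST
are available as options but default to 0). Passing tests therefore show the
procedure is correct and well calibrated under its stated model, not that
real 450K/SNP6/RNA-seq data meet that model.

## Statistics

**Group comparisons.** Two groups: Welch's unequal-variance *t*-test (group
sizes in practice differ severalfold, making the pooled-variance assumption
unattractive). Three or more: one-way ANOVA, with the three pairwise Welch
tests attached for three-level groupings. Panel summaries are the mean of
log2(RSEM+1) over panel genes (mean of logs, not log of means — the log
scale is where expression is approximately additive). Identical data across
groups reports p = 1 by convention (an epsilon guard handles zero variance).
Significance bands: * < 0.05, ** < 0.01, *** < 0.001, strict inequalities.
P-values are per comparison; Benjamini–Hochberg adjustment is available
behind a flag but off by default to mirror per-comparison reporting.

**Generalized Fisher exact test.** For an r×c table the p-value is defined by
the conditional-probability ordering: conditional on both margins, sum the
multivariate-hypergeometric probabilities of all tables no more probable than
the observed one (relative tolerance 1e-7, as is conventional, to absorb
roundoff at ties). Implementation: rows are reordered (the conditional law is
row-exchangeable) so a python loop enumerates compositions of the smallest
rows, the second-largest row runs over a vectorized numpy grid, and the
largest row is margin-determined; log-probabilities come from `gammaln`. A
cheap product bound on the number of feasible tables decides between exact
enumeration (up to 10⁷ tables) and a seeded Monte-Carlo fallback (10⁶
fixed-margin tables via Patefield's algorithm, `scipy.stats.random_table`;
the add-one estimator keeps p > 0). The result records which method ran.
Zero margins are degenerate (p = 1, flagged). The test suite checks exact
agreement with an exhaustive brute-force oracle on every 2×2 and 2×3 table
with N ≤ 12 and with the 2×2 hypergeometric special case.

**Survival.** Kaplan–Meier curves per group with the k-group log-rank test
(univariate), and Cox proportional hazards with categorical stage (reference
I–II) and XCI group (reference preserved_Xi), Efron tie handling, Wald CIs.
Missing covariates: complete-case per test. Non-convergence raises; the one
systematic cause — complete separation when a rare covariate level has no
events — triggers a ridge-penalized refit (penalizer 0.1) flagged
`separation_penalized`. Covariate levels absent from a cohort are dropped
from the design rather than fit at zero variance.

## Numerical and degenerate-input choices

* Exact-test p snaps to 1.0 when the enumerated mass reaches 1 within 1e-9
  (roundoff), and is floored at the smallest positive float.
* Cluster labels are canonicalized (by first-appearing member, or by
  descending methylation for reported cluster ids), so results are invariant
  to sample and probe order.
* All-identical samples split deterministically by index; k = n returns
  singletons.
* Survival times are rounded to 0.1 day in the generator; KM/log-rank handle
  the resulting ties exactly, Cox via Efron's approximation.
* Problem sizes in the test suite and acceptance script (20 seeds for
  recovery, 200 replicates for Cox recovery and coverage, 500 for
  type-I-error calibration, N ≤ 12 for exhaustive oracle sweeps) were chosen
  to give Monte-Carlo standard errors comfortably inside the asserted
  tolerances.

## Known limitations

* Thresholds are calibration constants, not estimates; on real arrays they
  would need cohort-specific inspection.
* The refinement rule assumes the evidence signature is meaningful at every
  subtree size ≥ `min_split_size`; heavily missing XIST data weakens it
  (clusters then split only on methylation class).
* The generator's states are exchangeable across probes (no spatial
  structure), so probe-level methods (e.g., segmentation of methylation)
  cannot be validated against it.
* The exact test's enumeration bound is a product upper bound; pathological
  margins below the bound but with huge table counts are impossible by
  construction, but wide tables (c ≥ 6) with moderate N may route to Monte
  Carlo earlier than strictly necessary.
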