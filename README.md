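# chemomir

miRNA expression signatures for gastric cancer chemotherapy response:
who has cancer, and who will progress quickly on cisplatin/fluorouracil?

`chemomir` is a Python package and command-line pipeline for the analysis
design in which endoscopic biopsy miRNA profiles are used to (1) separate
gastric cancer from normal stomach epithelium, (2) screen every miRNA
against time to progression (TTP) after chemotherapy, (3) build a survival
risk predictor from the screened miRNAs, and (4) test whether tumors that
acquired resistance moved toward the high-risk expression state. It is
aimed at statisticians and computational biologists who want the full
protocol — including its cross-validation and permutation machinery — as
reusable, tested code that runs end to end on synthetic cohorts shaped like
the study (1,667 miRNAs × 4 replicate probes, 90 cancer vs 34 normal
samples, an 82-patient survival training set with ~3.1-month median TTP and
~20% censoring, 8 pre/post-treatment pairs).

## The model at the core

Each miRNA x_j is screened with a univariate Cox model,
h(t | x_j) = h₀(t)·exp(β_j x_j) (Efron ties, Wald p); features with
p < α split into a chemoresistance list (HR = e^β > 1) and a
chemosensitivity list (HR < 1). The risk predictor is a supervised
principal-component index: with V the first two PC loading vectors of the
screened, training-mean-centered submatrix and (β₁, β₂) the Cox
coefficients of TTP on the two PC scores, each sample receives a
predictive index

    PI(x) = β₁·u₁ + β₂·u₂,   u_k = Σᵢ V_ik (xᵢ − mᵢ)  =  Σᵢ wᵢ (xᵢ − mᵢ)

with w = Vβ. High PI means rapid progression. A sample is high-risk when
its midrank percentile on the training PI distribution exceeds 67%.
Significance of the expression–TTP association is the permutation tail
probability of the log-rank statistic of leave-one-out cross-validated risk
groups, with the entire pipeline (screening → PCs → Cox) refit inside every
fold of every permutation. A pre/post pair is called correctly when the
post-treatment (resistant) tumor receives a strictly higher PI than its
pre-treatment (sensitive) counterpart.

The class-prediction protocol and the ΔΔCt qPCR module round out the
analysis: six classifiers (compound covariate predictor, diagonal LDA,
1-/3-nearest neighbours, nearest centroid, linear SVM) over 100 random
stratified 1:1 partitions with in-partition feature selection, and relative
quantification 2^(−ΔΔCt) against an RNU6-normalized control baseline.

## Worked example

Run the whole pipeline on a synthetic study-scale cohort:

```sh
chemomir run-all --seed 1 --out results/run1
```

or from Python:

```python
import chemomir as cm

cfg = cm.SimulationConfig(n_cancer=82, seed=1)        # survival training set
cohort = cm.generate_survival_cohort(cfg)
X = cohort.mirna_expression()                         # collapse 4 replicates
t = cohort.survival["ttp_months"].to_numpy()
e = cohort.survival["event"].to_numpy().astype(bool)

sel = cm.select_survival_features(X, t, e, alpha=0.05)
model = cm.fit_risk_model(X, t, e, selection_alpha=0.05)
perm = cm.permutation_significance(X, t, e, n_perm=200, seed=1)
print(len(sel.resistance), len(sel.sensitivity), perm.lr_observed, perm.p)
```

On the seed-1 cohort the pipeline prints (via
`scripts/acceptance.py --seed 1`):

```
median_ttp_months: 2.36 (n=82)
median_accuracy_ccp_pct: 100.0 (n=124)     # likewise DLDA/1NN/3NN/NC/SVM
n_survival_selected: 117 (n=1667)
n_chemoresistance_features: 60 (n=1667)
n_chemosensitivity_features: 57 (n=1667)
loocv_logrank_statistic: 21.48 (n=82)
permutation_p: 0.01 (n=200)
pairs_pretreatment_low_risk: 8 (n=8)
pairs_overall_correct: 8 (n=8)
qpcr_min_group_p: 0.0011 (n=4)
```

Reading these numbers: of 1,667 synthetic miRNAs, 117 screen as
TTP-associated at p < 0.05 (60 with HR > 1, i.e. chemoresistance-linked; 57
with HR < 1; the cohort plants a 58-feature signature, so roughly half of
the selections here are the expected false positives at α = 0.05). The
cross-validated risk groups separate with a log-rank statistic of 21.5,
significant at the permutation test's resolution (p = 1/201 ≈ 0.005,
printed as 0.01 after rounding the (1+k)/(1+B) estimate). All 8 synthetic
pre-treatment responders are called low-risk and all 8 post-treatment
resistant samples receive a higher predictive index. The six classifiers
all reach a median test accuracy of 100% on the planted diagnostic
signature — the planted 2-SD shifts are cleaner than real biology, which is
exactly what makes them useful as a correctness check.

## Command-line stages

`chemomir` exposes each stage as a subcommand over TSV files:
`simulate`, `preprocess`, `class-predict`, `survival-screen`,
`risk-predict`, `evaluate-pairs`, `qpcr`, and `run-all` (driven by a flat
YAML config; every default is echoed into `config.yaml` and `report.json`
in the output directory, and reruns are byte-identical under a fixed seed).

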