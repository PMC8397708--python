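# cnsig

Copy-number (CN) and structural-variant (SV) signature analysis for
multiple myeloma genomes: per-sample feature matrices, de novo signature
extraction, complex-rearrangement classification, and a cross-validated
signature-based chromothripsis prediction score (CN_pred).

## The problem

Chromothripsis — catastrophic chromosome shattering with near-random
rejoining — is present in roughly a quarter of newly diagnosed multiple
myeloma genomes and carries strong adverse prognosis. Calling it directly
requires whole-genome SV + CN data and expert curation. This package
implements the alternative route: summarize each genome's copy-number
profile as a vector of feature-category counts, extract signatures (latent
category distributions) de novo across a cohort, and predict chromothripsis
from each sample's signature exposures alone.

For each sample the segmentation profile is reduced to six features:
breakpoints per 10 Mb, absolute segment CN, CN jump between adjacent
segments, breakpoints per chromosome arm, lengths of oscillating CN chains,
and segment size. Cohort-wide, each feature's value distribution is cut
into categories (Poisson/Gaussian mixture components chosen by BIC; the
absolute-CN feature instead uses five fixed states: 0 = bi-allelic
deletion, 1 = monoallelic deletion, 2 = diploid, 3 = single gain, ≥4 = two
or more gains). Tallying values per category gives the count matrix
**X** ∈ ℕ^(n×C). Signature extraction factorizes

    X_jc ≈ N_j · Σ_k  θ_jk · φ_kc,    θ_j ∈ Δ^(K−1),  φ_k ∈ Δ^(C−1)

with signatures φ_k and exposures θ_j on the probability simplex. The
number of signatures K is inferred by a hierarchical Dirichlet process
(HDP) Gibbs sampler (a KL-NMF backend with stability-based rank selection
is also provided). SVs get the analogous 32-category treatment
({clustered, non-clustered} × {DEL, DUP, INV} × 5 size bins + TRA), with
clustering detected by a piecewise-constant fit of inter-breakend
distances. Complex events are classified from the breakpoint
interconnection graph: chromothripsis (>10 interconnected pairs +
oscillating CN), chromoplexy (>2 chromosomes + CN loss), templated
insertion (translocation + focal gain), complex-NOS (≥3 pairs).
Chromothripsis prediction is a stratified 10-fold cross-validated logistic
regression on exposures, summarized by the mean per-fold ROC AUC; CN_pred
is the binarized call at probability ≥ 0.6. Two feature sets are compared
by the bootstrap SD of their CV-AUC difference.

Real cohorts of this kind are controlled-access, so the package ships a
simulator of myeloma-like cohorts (hyperdiploid baselines, planted
chromothripsis/chromoplexy/templated-insertion/complex-NOS events at
configurable prevalence, default 24%) that makes every stage testable.

## Worked example

```bash
python examples/05_chromothripsis_prediction.py
```

simulates a 150-sample mm-like cohort, builds the CN count matrix, extracts
signatures and cross-validates the chromothripsis prediction. It prints:

```
7 CN signatures extracted from 24 categories
mean 10-fold CV AUC: 1.000 (per-fold 1.00, 1.00, ..., 1.00)
CN_pred(high) calls at threshold 0.6: 8 / 150
sensitivity 0.25, specificity 1.00
```

The 24 categories are the data-dependent outcome of the per-feature BIC
scans plus the five fixed CN states; the AUC says the exposures separate
planted chromothripsis perfectly on this synthetic cohort, and the CN_pred
line shows the effect of the conservative 0.6 probability cut (full
specificity, reduced sensitivity). The other `examples/` scripts cover
simulation, feature/category construction, complex-event classification
and signature recovery individually. A `cnsig` CLI wraps the same stages
(`cnsig simulate`, `cnsig run-all --simulate-n 100 out/`, ...).

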