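# Methods

This note documents the models, conventions and numerical choices behind
`cnsig`, in the order the pipeline runs them.

## Coordinates, filters and assets

Internal coordinates are 1-based inclusive for segments and SV breakends;
BEDPE is read/written in its native 0-based half-open dialect and
round-trips exactly. Chromosome names are normalized by stripping `chr`.
GRCh37 chromosome lengths, centromere intervals and the three
immunoglobulin loci (IGH 14q32, IGK 2p11, IGL 22q11) ship as editable text
assets; coordinates are data, not code.

Artefact filtering drops segments and SV breakends on excluded chromosomes
(X and Y by default — the Y exclusion is this package's addition, since a
near-haploid allosome makes integer CN states ambiguous), dissolves CN
breakpoints inside the Ig mask (the flanks merge, the longer flank's CN
wins — these junctions are artefacts of V(D)J/class-switch rearrangement
mapping, not somatic CN change), and removes CN changes shorter than 50 kb.
Removal merges the short segment into the flanking neighbor with the
closer total CN (ties to the preceding neighbor), which preserves genome
coverage instead of leaving gaps. Masking runs before the size filter; the
order is not dictated by the underlying methodology, so it is fixed here
and exposed for sensitivity testing via `min_seg_bp`. The whole filter is
idempotent. A lone segment on a chromosome is a baseline, not a CN change,
and survives the size filter regardless of length.

## CN features

Six per-sample value multisets. Breakpoints are junctions between adjacent
same-chromosome segments with different total CN, positioned at the start
of the right-hand segment. Windows are fixed 10 Mb tiles anchored at
position 1 (last partial tile kept; a junction exactly on a boundary
counts left). Arms split at the centromere interval; junctions inside it
belong to neither arm. Oscillating chains are maximal non-overlapping runs
of ≥3 segments alternating between exactly two CN values, scanned left to
right. Windows, arms and chromosomes with no events contribute explicit
zeros so the mixture fits see the zero mass; this zero-inflation
convention is the package's main interpretive choice and is pinned by
property tests against brute-force oracles.

## Category scheme

Count-valued features (breakpoints per 10 Mb, per arm, oscillation
lengths) get Poisson mixtures; CN jumps get Gaussian mixtures on the raw
values and segment sizes on log10 values. The component count is chosen by
BIC over 1..10 components; the Poisson EM is fit on the collapsed value
histogram with 20 quantile-jittered restarts, the Gaussian fits use
scikit-learn's `GaussianMixture` (k-means++ init, 20 restarts,
`reg_covar = 1e-4`). Pooled values are sorted before fitting, which makes
the fit exactly invariant to sample order. The absolute-CN feature skips
fitting entirely: five fixed states (total CN 0, 1, 2, 3, ≥4), reflecting
the narrow CN range of myeloma genomes; the fixed states *replace* the
mixture for that feature. Values are hard-assigned to the maximal
posterior-responsibility component (ties to the lower index), keeping the
matrix integer and making per-feature count conservation exact; this is
deliberate — the extraction sampler consumes integer counts. The total
category count is a data-dependent output (mid-20s on default simulated
cohorts), not a constraint.

## SV features

32 fixed categories: {clustered, non-clustered} × ({deletion,
tandem-duplication, inversion} × {1–10 kb, 10–100 kb, 100 kb–1 Mb,
1–10 Mb, >10 Mb} ∪ {translocation}). Size bins are half-open [low, high);
spans under 1 kb fall into the smallest bin with a warning. Clustering
follows the rearrangement-signature convention: breakends pooled and
sorted per chromosome, each scored by its mean flanking inter-breakend
distance, the score sequence segmented by an exact O(n²) penalized
least-squares fit on log10 distances (penalty γ = 25, configurable), and a
segment is clustered when its mean distance is ≤ 0.1× the sample's
genome-wide mean. A pair is clustered if either breakend is — one
clustered end suffices to implicate the event.

## Complex-event classification

Pairs are nodes; linking consecutive same-chromosome breakends within
1 Mb yields exactly the connected components of the full pairwise
within-radius graph. Classes apply in strict priority order:
chromothripsis (>10 pairs, strict, + oscillating CN in the padded
footprint), chromoplexy (>2 chromosomes + CN loss), templated insertion
(translocation + focal gain; complex when >2 chromosomes), complex-NOS
(≥3 pairs), single. Operationalized thresholds, all configurable:
oscillation in the footprint means ≥6 consecutive segments with every
adjacent pair differing over ≤3 distinct CN values; CN loss means a member
breakend abuts a segment below the chromosome's length-weighted modal CN;
focal gain is an above-modal segment ≤5 Mb containing a translocation
breakend. The qualitative fragment-join/order randomness criteria of the
chromothripsis literature have no published test statistic and are not
implemented; the >10-pair + oscillation rule is the operative definition.

## Signature extraction

The HDP backend is a direct-assignment Gibbs sampler for a two-level
Dirichlet process mixture over categorical events: every count unit is an
item; items in sample j are drawn from a sample-level DP (concentration
α = 1) whose base is a cohort-level DP (γ = 1) over component category
distributions with a symmetric Dirichlet(η = 0.2) base over categories.
Per sweep, items are reassigned by the Chinese-restaurant-franchise
conditional, empty components are compacted, table counts are sampled and
the top-level sticks redrawn. Four chains run 300 burn-in sweeps then 25
posterior draws thinned by 4 — the item-level sampler mixes quickly at
these matrix sizes, and recovery and seed-stability tests pin the
behavior; longer chains are a config away (`HdpConfig`). The inner sweep
is numba-compiled. Posterior components from all chains are consolidated
by greedy cosine clustering (threshold 0.9, heaviest components first);
clusters occupying <50% of posterior draws or <1% of total weight are
discarded as transient. Chains disagreeing on the component count by more
than 2 raise a convergence warning in the run metadata, never an
exception. Consensus exposures are obtained by projecting the count matrix
onto the consensus signatures with simplex-constrained multinomial EM, so
the simplex invariants hold exactly; the same projection serves
`fit_exposures` for new samples. Signatures are named by descending mean
exposure.

The NMF backend runs KL-divergence multiplicative-update NMF with random
restarts per candidate rank; the selected rank is the largest that is
stable (mean Hungarian-matched cosine across restarts ≥ 0.8) and still
improves reconstruction error by ≥5% over the previous rank.

## Prediction

Stratified k-fold (default 10; 5 supported for small cohorts) logistic
regression with L2 regularization (C = 1.0) on exposure fractions, all
signatures as input. Logistic regression is the minimal model producing a
calibrated "predicted chromothripsis probability"; the reported AUC is the
mean of per-fold AUCs (pooled out-of-fold AUC kept alongside). CN_pred is
high when the out-of-fold probability is ≥ 0.6 — at or above the
threshold, inclusively — a cut that holds specificity at/above 95% on the
cohorts this framework targets; `threshold_sweep`/`select_threshold`
re-derive it for any cohort. The bootstrap comparator resamples the cohort
with replacement, re-runs the full CV for both feature sets per replicate
(1000 replicates by default), reports the SD of the AUC difference and a
two-sided normal-approximation p-value; degenerate single-class replicates
are redrawn and logged, and replicates with a minority class smaller than
k shrink k for that replicate.

## Simulator

The simulator emulates the cohort conditions the framework targets:
hyperdiploid baselines (55% of samples; 4–8 trisomies from the canonical
odd-chromosome set) or quiet diploid; chromothripsis at 24% prevalence
with pair counts from round(LogNormal(log 24, 0.55)) clipped to [11, 60]
(median ≈24, IQR ≈12–35) and footprint CN oscillating between two adjacent
integer states; chromoplexy (rate 0.10) as translocation rings over 3–5
chromosomes with 60–400 kb deletion bridges; templated insertions (0.12;
30% complex) with 100–800 kb focal gains; complex-NOS (0.15) as 3–9
clustered balanced inversions; Poisson passengers (mean 8 SVs, 4 CNAs per
sample). Total CN is capped at 9 (the myeloma envelope; `solid_like`
raises it to 20 with larger events, `quiet` plants nothing). The
per-class rates beyond chromothripsis prevalence are invented defaults —
no public tabulation exists — chosen once to give each class enough
planted instances for recovery testing. Planted events and passengers
occupy disjoint chromosomes, so planted truth is unambiguous and
noise-free recall is exactly testable; this also means the simulator does
not model co-located events, caller noise, subclonal CN, or read-level
artefacts. Consequently, passing tests demonstrate correctness of the
machinery and recoverability under clean MM-like conditions, not
performance on real sequencing data. A WES-like lower resolution is
emulated by `coarsen_profile` (drop CN changes < 100 kb), not by capture
simulation. Same seed ⇒ byte-identical output.

## Problem sizes and determinism

Default verification sizes: 1000 random profiles for feature-oracle
equivalence; 200 samples × 28 categories × 3 planted signatures for
extraction recovery; n = 400 at 24% prevalence for the end-to-end
prediction check; 100 permutations for the null; 200 bootstrap replicates
for the comparator demonstration (the default for real comparisons stays
at 1000). All stochastic stages are seed-controlled; every pipeline output
carries the configuration hash, and re-running a configuration reproduces
the matrices byte-for-byte.

## Known limitations

Only total copy number drives the features (minor CN is carried but
unused). The exact category boundaries and signature vectors of any
specific controlled-access cohort are not reproducible by construction —
the scheme is data-dependent. The clustered-SV γ penalty and the 1 Mb
interconnection radius are literature-convention defaults, not fitted
values. Survival modeling on CN_pred, and the LOH/genomic-scar scores it
is compared against elsewhere, are out of scope (precomputed score columns
can be supplied to the AUC comparator directly).
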