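# Methods

## Overview

`palscreen` implements a gene-centric pathway activation analysis: molecular
pathways are constructed algorithmically as interaction neighborhoods of a
chosen central gene product in a merged interactome, each member is assigned
an activator/repressor role (ARR), per-sample pathway activation levels (PAL)
are scored against a cohort-average reference, and the scores are evaluated
as prognostic biomarkers (optimal-cutpoint survival stratification, Cox
hazard ratios) and predictive biomarkers (RECIST response-group comparison).

## Pathway construction

A pathway collection is a set of directed edge lists with one of nine typed
interactions: activation, coupling, inhibition, phosphorylation,
dissociation, repression, dephosphorylation, binding/association,
ubiquitination. Collections are merged into a single multigraph on shared
node identifiers; parallel edges of different types between the same ordered
pair are retained because role annotation aggregates all evidence. Weak
connectivity is reported, not enforced: a fragmented collection yields a
component report and analysis proceeds on the full graph.

A genecentric pathway for central gene *c* contains *c* plus every node with
at least one first-order edge to or from *c* (the union of in- and
out-neighbors; a `depth` parameter generalizes to breadth-first neighborhoods
but defaults to 1). Nodes may be genes or metabolites; metabolite members are
carried through construction but excluded from expression scoring, since
they have no transcript.

## Activator/repressor roles

ARR takes the five discrete values {−1, −0.5, 0, 0.5, 1}: repressor, mainly
repressor, neutral/ambiguous, predominant activator, activator. For depth-1
pathways the evidence for a member is its set of typed edges to/from the
central node. Each type carries a sign — activation and phosphorylation +1;
inhibition, repression, dephosphorylation and ubiquitination −1; coupling,
binding/association and dissociation 0 — following conventional signaling
semantics (covalent activating marks activate, removal/degradation marks
inhibit, physical association alone is uninformative). The mapping is
replaceable via a TSV file for alternative conventions. Aggregation:
unanimity among signed edges gives ±1, a strict majority ±0.5, a tie or
purely neutral evidence 0; the central node is +1 by construction. Edge
direction is ignored by default (`direction_mode="ignore"`); an
`incoming_only` mode restricts evidence to upstream regulators.

## PAL scoring

For pathway *p* and sample *s*,

    PAL_p(s) = 100 · Σ_n ARR_{n,p} · lg CNR_n(s) / Σ_n |ARR_{n,p}|

with lg = log₁₀ and CNR_n the case-to-normal ratio of gene *n*: its
normalized expression in *s* divided by the reference value. The sum runs
over gene-class members with nonzero ARR that are measured in the cohort;
genes absent from the matrix drop out of numerator and denominator alike. A
pathway with no usable member yields an undefined PAL, reported and skipped
rather than raised.

Raw counts are normalized by median-of-ratios size factors: genes with a
zero anywhere are excluded from the geometric-mean reference row, each
sample's factor is the median ratio of its counts to that reference, and the
sample column is divided by its factor. The reference profile is the
arithmetic per-gene mean of normalized values across the cohort (geometric
mean available as an option), plus a pseudocount. Positive signed PAL
therefore means "this sample's pathway is shifted up relative to the cohort
average", and the cohort mean PAL is near zero by construction.

Numerical choices: pseudocount 1 on the normalized scale added to both the
sample value and the reference before the ratio, which keeps every log
finite and is negligible at typical sequencing depth; scoring is vectorised
as a weight-vector × log-ratio-matrix product, with agreement to a
gene-by-gene evaluation of the formula verified to 1e-10 relative in tests.

## Survival screening

For each biomarker (pathway PAL or a central gene's log₁₀ CNR) and each
endpoint (OS, PFS), samples are dichotomized at the threshold minimizing the
two-sided log-rank p over all midpoints of consecutive distinct values whose
split leaves at least `minprop` (default 0.1) of samples in each group; ties
break toward the smaller threshold. The high-vs-low hazard ratio comes from
a univariate Cox model (Efron tie handling, Wald 95% CI); significance stars
are \*, \*\*, \*\*\* at p < 0.05, 0.01, 0.001, and a cell earns a direction
("negative" prognostic biomarker when HR > 1, "positive" when HR < 1) only
when p < 0.05 and the CI excludes 1. When one group has no events the
partial likelihood is monotone; the cell is flagged and excluded from
HR-profile clustering. Per-biomarker summary rows average the OS and PFS
hazard ratios and carry the lower of the two significance levels.

Minimum-p cutpoint selection is anti-conservative: under the null the naive
per-cell p rejects far above its nominal level (roughly 45% at α = 0.05 in
our null simulations). The per-cell stars deliberately reproduce this naive
behavior, because that is how such screens are conventionally reported. Two
corrections are emitted alongside: a Benjamini–Hochberg column across the
screen, and the Miller–Siegmund/Lausen–Schumacher approximation for the
maximally selected statistic,

    p_adj ≈ φ(b)(b − 1/b)·ln[ε₁(1−ε₀)/(ε₀(1−ε₁))] + 4φ(b)/b,

where b is the square root of the best split's chi-square and
[ε₀, ε₁] = [minprop, 1 − minprop]. The biomarker-level "flagged" verdict —
the package's answer to "is this pathway a biomarker in this cohort?" —
requires a consistent direction on every endpoint with the corrected p
below 0.05 on each. This two-tier design keeps the conventional per-cell
display while making the headline call robust to selection inflation.

HR profiles (cohorts × biomarkers) are clustered agglomeratively with
Euclidean distance and complete linkage; undefined cells are imputed with
HR = 1 (no effect) and flagged; the default cut returns two flat clusters.

## Response screening

Cohort inclusion rules for therapy-response records: therapy groups need at
least 20 distinct patients; only therapy lines 1–3 count; a patient's
retained lines collapse to the best response under CR > PR > SD > PD;
response classes with fewer than 3 patients are dropped. Responders (R) are
CR + PR, non-responders (NR) are PD, and SD is kept as its own class. Every
exclusion is logged with its rule name.

Group comparisons follow a decision tree: Shapiro–Wilk per group (all groups
must pass at α = 0.05 for the normal branch) and Brown–Forsythe
(median-centered Levene) across groups. Two groups: Student's t if normal,
else the Wilcoxon rank-sum (Mann–Whitney) test. More than two: ANOVA with
pairwise-t post hoc and Benjamini–Hochberg correction if normal and
homoscedastic, else Kruskal–Wallis with Dunn's post hoc (tie-corrected
rank z) and Holm correction. Constant inputs are flagged degenerate and not
tested. Under identical group distributions the end-to-end branch choice
rejects at the nominal 5% within the binomial envelope (400 simulations in
the acceptance checks).

## Synthetic cohorts

The generator emulates a mid-sized tumor RNA-seq cohort and is the test bed
for everything above. Defaults (the study conditions for all tests): 200
samples × ~500 genes; a 40-member star-topology genecentric pathway, 70%
activators; 3 disjoint decoy pathways with uniformly random edge types;
negative-binomial counts with dispersion 0.1 around a baseline mean of 500
scaled by log-normal (σ = 1) gene-level factors; half the samples form an
"activated" stratum whose activator-gene means are multiplied (and
repressor-gene means divided) by 2^logfc with logfc = 1 by default (2 in the
signal-recovery checks); survival exponential with a baseline hazard of
1/365 per day, activated hazard multiplied by exp(β) with β = ln 2, and
independent exponential censoring calibrated to 30%; RECIST labels from a
proportional-odds model (slope 2 toward Progressive Disease for activated
samples), one therapy label, lines 1–3 plus a few later-line records to
exercise the filters. Effects are injected at the gene-mean level, never at
the score level, so normalization, referencing, CNR and PAL are all in the
causal path of every recovery test.

What the generator does not emulate — and hence what passing tests do not
establish about real tumor data: batch and platform effects, correlated
co-expression structure beyond the injected pathway shift, subtype mixtures,
non-proportional hazards, informative censoring, and interactome noise
(wrong or missing edges). Decoy pathways are expression-independent of
survival by construction, which is the cleanest null, not the hardest one.

## Problem sizes

Recovery and calibration checks use n = 300 patients for Cox estimator
properties (25 signal seeds, 40 null seeds, uncensored exponential survival),
the full 200-sample cohort for ten end-to-end round trips, 50 random
instances (n ≤ 60) for exhaustive cutpoint verification, 100 random
pathway/cohort instances for PAL oracle agreement, and 400 simulations for
type-I calibration of the response decision tree. These sizes give the
binomial envelopes quoted in the tests while keeping the whole suite inside
a few minutes on one core.

## Known limitations

- ARR aggregation is a depth-1 specialization; multi-hop role propagation
  through intermediate regulators is out of scope.
- The naive per-cell survival p-values are intentionally anti-conservative
  (see above); only the corrected biomarker-level flag controls selection.
- Reference averaging is on the linear normalized scale; a cohort dominated
  by extreme outliers would shift the reference (the geometric-mean option
  mitigates this).
- Undefined-HR imputation at 1.0 for clustering keeps rows comparable but
  shrinks distances for sparsely estimable cohorts.
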