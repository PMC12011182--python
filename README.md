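# palscreen

Gene-centric pathway activation scoring and biomarker screening for tumor
expression cohorts.

Signaling cascades such as the MAPK/ERK axis drive proliferation in many
cancers, but single-gene expression is a noisy readout of whether the
cascade is actually active in a given tumor. `palscreen` takes the
pathway-level view: it builds a molecular pathway algorithmically as the
first-order interaction neighborhood of a central gene product (e.g. ERK1 or
ERK2) in a merged interactome, annotates each member as an activator or
repressor of the pathway, and condenses a tumor's expression profile into a
single signed **pathway activation level (PAL)**:

    PAL_p = 100 · Σ_n ( ARR_{n,p} · lg CNR_n ) / Σ_n |ARR_{n,p}|

where CNR_n is the case-to-normal ratio of gene *n* (sample expression over
the cohort-average reference), ARR_{n,p} ∈ {−1, −0.5, 0, 0.5, 1} is the
member's activator/repressor role, and lg is log₁₀. PAL > 0 means the
pathway is up-regulated in that sample relative to its cohort.

Downstream, PAL (and central-gene expression, for comparison) is screened as
a clinical biomarker: samples are split at the optimal log-rank cutpoint,
Kaplan–Meier/Cox statistics give a hazard ratio with 95% CI per endpoint
(OS, PFS), hazard-ratio profiles are clustered across cohorts, and PAL is
compared between RECIST response groups (responders CR+PR, non-responders
PD, stable disease separate) through a normality-driven test decision tree.
A negative-binomial cohort simulator with known ground truth makes the whole
chain testable end to end.

Intended users: computational biologists evaluating pathway-activation
scores as prognostic or predictive biomarkers, and anyone needing a
self-contained, tested implementation of optimal-cutpoint survival screening
with honest handling of its selection bias.

## Worked example

Simulate a 200-patient cohort in which the true pathway's activators are
shifted up 4-fold in half the samples and that stratum carries a 2-fold
hazard, then run the full screen:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_build_pathways.py
python analysis/03_score_pal.py
python analysis/04_survival_screen.py
python analysis/05_response_screen.py
```

Output (abridged):

```
interactome: 164 nodes, 160 edges, 4 weak component(s), largest 41
ARR ground-truth recovery for CENTRAL: 41/41 members correct
PAL CENTRAL: activated stratum mean +25.4, baseline -34.4 (41 genes used)
PAL DECOY_HUB_0: activated stratum mean +0.8, baseline +0.4 (30 genes used)
per-cell verdicts (naive minimum-p stars):
  CENTRAL        OS   HR 2.70 [1.92, 3.81] *** corrected p 0.000 -> negative
  DECOY_HUB_0    OS   HR 1.71 [1.21, 2.42] **  corrected p 0.047 -> negative
  CENTRAL        PFS  HR 1.80 [1.30, 2.48] *** corrected p 0.010 -> negative
  DECOY_HUB_0    PFS  HR 0.59 [0.36, 0.97] *   corrected p 0.397 -> positive
biomarker-level flags (consistent direction, corrected p < 0.05 on both endpoints):
  CENTRAL: negative (mean HR 2.25)
ground-truth pathway CENTRAL: recovered
response cohort after filtering: {'NR': 79, 'SD': 61, 'R': 60}
  CENTRAL        kruskal-wallis     p 0.0000  medians R -33.4 / NR +24.5 -> lower activation responds better
```

Reading this: the true pathway separates the activated stratum by ~60 PAL
units, is called a *negative prognostic biomarker* (high activation, HR 2.25,
worse survival) and shows *lower activation in responders*. The decoy rows
illustrate why the naive per-cell stars cannot be trusted on their own —
minimum-p cutpoint selection hands a null pathway two stars — while the
selection-corrected biomarker-level flag keeps only the true pathway. See
`docs/methods.md` for the statistics.

The same functionality is exposed as a CLI (`palscreen simulate`,
`build-interactome`, `extract-pathway`, `score-pal`, `survival-screen`,
`response-screen`, `run-full`) and as a library (`palscreen.analyze`).

## Layout

- `src/palscreen/` — the library: `pathway_graph`, `arr_annotator`,
  `pal_engine`, `survival_stats`, `response_stats`, `synthetic_data`,
  `pipeline`, `cli`, `io`.
- `analysis/` — numbered narrative drivers for the worked example above.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
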