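# cnsubtype

Molecular subtyping of gastric tumors from somatic copy-number profiles.

Gastric adenocarcinomas that are EBV-negative and microsatellite-stable fall
into two TCGA copy-number classes — **genomically stable (GS)** tumors with
few chromosomal aberrations and **chromosomal instable (CIN)** tumors with
recurrent gains and losses. Crossing that molecular label with the Lauren
histotype (intestinal vs diffuse, mixed counted as diffuse) yields four
subgroups with distinct prognosis: GS-intestinal, GS-diffuse, CIN-intestinal
and CIN-diffuse. `cnsubtype` implements the full classification and analysis
pipeline for cohorts profiled by shallow whole-genome sequencing, plus a
synthetic-cohort generator so every stage is testable without patient data.

## What it computes

**Nearest-centroid GS/CIN assignment.** Per-bin log2 ratios r observed at
tumor purity p are corrected by inverting the admixture model
2^r = p·2^(r_t) + (1 − p), i.e. r_t = log2(max(ε, (2^r − (1 − p))/p)) with
floor ε = 2⁻¹⁰. Corrected segmented values are averaged
(length-weighted) over each recurrent peak region of a GISTIC-style catalog
(sex-chromosome peaks excluded), giving one vector x per tumor. Cluster
centroids μ_GS, μ_CIN are per-peak means over a labeled reference cohort, and
the tumor is assigned to argmin_k ‖x − μ_k‖₂ over its non-missing peak
dimensions.

**Genome instability index.** GII = 100 × (bp of usable bins with call ≠ 0)
/ (bp of usable bins), from 5-level calls c ∈ {−2,−1,0,1,2}. A survival-based
GII-low/high cutoff is the maximally selected two-group log-rank threshold
g\* = argmax_g |z(g)| under a minimum group-proportion constraint
(minprop = 0.1).

**Survival battery.** Kaplan–Meier with Greenwood log-scale CIs
(reporting right-truncated when <10% of a group remains at risk), log-rank
tests, Cox proportional-hazards fits (Efron ties) with stepwise backward
factor selection at p < 0.10, a simplified log-rank survival tree, Fisher's
exact test for r×c tables (full enumeration, or ≥10⁶ Patefield Monte-Carlo
draws when enumeration is infeasible) and one-way ANOVA.

**Region frequency comparison.** Calls are merged into regions of
near-constant cohort signature and each region's loss/neutral/gain
composition is compared between two subgroups by permutation chi-square with
a permutation FDR estimate.

## Worked example

`examples/01_simulate_and_classify.py` simulates a 309-tumor cohort on a
miniature 3-chromosome grid, builds centroids from a labeled reference panel
and classifies every sample:

```
four-subgroup composition (n, % of included):
                  n  percent
GS-intestinal    24      7.8
GS-diffuse       57     18.4
CIN-intestinal  142     46.0
CIN-diffuse      86     27.8

label recovery vs simulation truth: 100.0%
```

`examples/03_subgroup_survival.py` runs the survival battery on the same
cohort (survival calibrated per stratum to five-year rates
61.4/56.5/47.6/31.5%):

```
five-year CRS per stratum (%, with 95% CI):
  GS-intestinal   n= 24   67.5 (48.6-93.8)
  GS-diffuse      n= 57   58.1 (44.6-75.7)
  CIN-intestinal  n=142   46.4 (37.9-56.8)
  CIN-diffuse     n= 86   23.1 (14.4-36.9)

overall log-rank: chi2=18.19 p=0.0004

Cox hazard ratios vs GS-intestinal:
  stratum[CIN-diffuse]      HR=3.41 CI=[1.55, 7.513] p=0.002
  stratum[CIN-intestinal]   HR=2.14 CI=[0.988, 4.633] p=0.054
  stratum[GS-diffuse]       HR=1.54 CI=[0.668, 3.574] p=0.309

survival tree:
split subtype: ['CIN'] | ['GS'] (chi2=9.47, p=0.00209)
  split lauren: ['diffuse'] | ['intestinal'] (chi2=6.45, p=0.0111)
    leaf n=86 events=55
    leaf n=142 events=82
  leaf n=81 events=32
```

The estimated hazard ratios bracket the exponential calibration; the tree
recovers the three prognostic groups (GS, CIN-intestinal, CIN-diffuse) —
the GS branch is too small to split further by histotype. The remaining
examples cover the GII cutpoint, region comparison and the association
tests on published contingency tables.

A thin CLI wraps the same library calls
(`cnsubtype simulate|classify|gii|cutpoint|stratify|analyze|compare-regions|run-all`);
run `cnsubtype --help` for the flags. Deterministic stages write manifests
with input digests so reruns are reproducible.

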