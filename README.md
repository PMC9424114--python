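# tregspatial

Spatial immunophenotyping of multiplex-immunofluorescence tissue cores, built
for studying the prognostic heterogeneity of regulatory T cells (Tregs) in
colorectal cancer. The package takes per-cell tables exported from image
analysis software (coordinates, tissue region, mean fluorescence intensity
per marker), tissue masks and a clinical table, and provides:

* **Marker scoring** — per-cell positive/negative calls by intensity
  thresholding (per series and stain), mutually exclusive phenotype
  categories (CD8⁺, FOXP3⁺, triple-positive Treg CD4⁺/CD25⁺/FOXP3⁺, other),
  infiltration densities (positive cells/mm², analyzed as log₂(density+1)),
  and cancer cell/area fractions.
* **Treg subpopulation profiling** — the 2×2 of CD25 {High, Low} × FOXP3
  {High, Low} among triple-positive Tregs at the nearest-rank 75th-percentile
  thresholds, per-sample mean CD25/FOXP3, and the per-series
  High/Low/Negative mean-CD25 classification (with an automatic
  density-valley cutoff finder).
* **Spatial proximity testing** — Voronoi diagrams clipped to the tissue
  outline define cellular neighborhoods; a Monte-Carlo permutation test
  (2000 label permutations per sample, category counts and positions fixed)
  flags samples where the number of CD8⁺ cells neighboring at least one Treg
  strictly exceeds the 95th percentile of the permuted distribution.
* **Survival analysis** — 5-year relapse-free survival endpoint construction
  with the cohort filters (stage I–III, R0, no pre-operative radiotherapy,
  no synchronous primary), Kaplan-Meier/log-rank, stratified multivariable
  Cox models (via lifelines), and a bootstrap + backward-selection variable
  retention procedure.
* **A calibrated synthetic-cohort generator** — tissue cores with
  controllable CD8-Treg spatial attraction, marker intensities matched to
  the published across-sample distributions, and proportional-hazards
  clinical outcomes; synthetic and real exports are interchangeable in every
  stage.

## The core statistic

For a sample with cells at fixed positions and category labels
*c₁ … c_n*, let *k* be the number of CD8⁺ cells whose clipped Voronoi region
shares a boundary segment with at least one target cell (FOXP3⁺ or
triple-positive Treg). The permutation null draws *B* = 2000 uniform
relabelings of the same multiset of categories over the same positions,
giving *k₁ … k_B*; the sample shows **significant spatial proximity** when

    k_obs > q95,   q95 = nearest-rank 95th percentile of {k_1 … k_B}

Samples without CD8⁺ cells are excluded; samples without target cells are
non-significant. Unlike the naive neighbor fraction *k/n_CD8*, this score is
not driven by target-cell abundance.

## Worked example

```
$ python examples/02_spatial_proximity.py
theta=5.0: 189 CD8+ cells, 63 tp-Tregs
  observed CD8 cells with >=1 tp-Treg neighbor: 62
  95th percentile of 2000 permuted counts: 58
  classification: significant
theta=0.0: 189 CD8+ cells, 63 tp-Tregs
  observed CD8 cells with >=1 tp-Treg neighbor: 57
  95th percentile of 2000 permuted counts: 59
  classification: non_significant
```

Two synthetic cores with identical composition: in the first, Treg labels
were placed with a short-range attraction toward CD8⁺ cells (θ = 5), and the
observed neighbor count (62) exceeds the permutation critical value (58), so
the sample is flagged; in the null core the count sits inside the permuted
distribution. `examples/01_marker_scoring.py`, `03_synthetic_calibration.py`
and `04_survival_analysis.py` walk the scoring, calibration and survival
stages the same way.

A thin CLI mirrors the library (`tregspatial simulate|score|spatial|cohort|all`),
writing TSV outputs plus a JSON run manifest per invocation.

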