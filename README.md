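# immunobud

Quantitative profiling of the immune–stemness–budding architecture of
pancreatic ductal adenocarcinoma (PDAC) from multiplexed immunofluorescence
(mIF), with downstream prognostic modeling. The package is aimed at
computational pathology and tumor-immunology groups who want an open,
tested implementation of the full chain: nucleus segmentation from a
DAPI-weighted composite, threshold phenotyping of CD8 (opal 520), CD133
(opal 570) and CK19 (opal 690), tumor-budding detection, spatial statistics
of T-cell infiltration, and nomogram-based survival scoring — plus synthetic
generators that produce images, cell tables and survival cohorts with known
ground truth for validation.

## What it computes

* **Tumor budding (TB).** CK19+ cells are grouped into connected components
  (centroid contact distance, default 20 µm); a component of 1–5 nuclei is a
  bud, ≥ 6 a duct/nest. Densities are reported per mm².
* **Anti-/pro-tumor indices.** `CD8/TB = n_CD8 / n_TB` and
  `CD8/CD133 = n_CD8 / n_CD133` (count ratios), dichotomized at cohort
  medians (low ⇔ value ≤ cutoff).
* **Spatial statistics.** Distance-class counts of CD8+ cells in
  0–20, …, 80–100 µm annuli around bud/CSC nuclear centers; the adjacency
  ratio (fraction of CD8+ cells within 20 µm); and the cross-type Ripley
  statistic `L(r) = sqrt(K(r)/π)`, which equals `r` under complete spatial
  randomness.
* **Survival modeling.** Kaplan–Meier, log-rank, Efron-ties Cox models; a
  0–100-point nomogram over the eight prognostic factors (three densities,
  two indices, two adjacency ratios, TNM stage); the integrated
  immune-CSC-TB profile — the sum of the CD8/CD133 and CD8/TB point
  contributions of a refit two-factor nomogram; and the evaluation battery:
  Harrell's C, calibration by predicted decile, IPCW time-dependent ROC and
  survival-adapted decision curves.

## Worked example

```sh
python analysis/01_simulate_slide.py
python analysis/02_slide_quantification.py
python analysis/03_spatial_statistics.py
python analysis/04_cohort_survival.py
```

`01` simulates a 1 mm² field under the default study conditions and prints

```
simulated 1383 cells on 1.00 mm^2
truth: 285 CD8+, 124 CD133+, 1098 CK19+ cells, 329 buds
```

`04` simulates a 160-patient cohort whose hazards follow the published
direction of effects (protective CD8 and indices, adverse CD133/TB/stage),
recomputes median cutoffs and fits the models:

```
median cutoffs: {'cd8_density': 313.361, 'cd133_density': 131.06, 'tb_density': 325.244,
                 'cd8_tb_index': 3.624, 'cd8_cd133_index': 3.35,
                 'tb_adjacent_cd8_ratio': 0.229, 'csc_adjacent_cd8_ratio': 0.188}
C-index:  {'nomogram_8factor': 0.853, 'integrated_profile': 0.768, 'tnm_only': 0.642}
time-dependent AUC at 36 months: 0.921
```

Every dichotomized factor separates survival in the expected direction
(low CD8/TB median OS 8.7 vs 43.5 months, log-rank p < 1e-8), and the
two-factor integrated profile out-discriminates TNM stage alone — the
qualitative pattern the real cohorts show. Tables land in `results/`.

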