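# Methods

## Scope and model

The package reimplements, as open code, an mIF quantification chain for
PDAC tissue — segmentation, phenotyping, tumor-budding detection, spatial
statistics and prognostic modeling — together with synthetic generators
that put known ground truth behind every stage. The vendor system the
original workflow ran on is closed; where only parameter names and values
are public, the algorithms here are our own concrete, documented
interpretations driven by those printed values.

## Segmentation

The nuclear channel is a weighted composite (DAPI 5, opal 520/570/690 =
0.15/0.243/0.113) min–max normalized per field. Detection: Gaussian
smoothing (σ = 1 px); a pixel is foreground when its intensity is at least
0.032 (normalized) **and** it is either locally contrasted — pixel minus
the mean of a 15-px window ≥ 0.4 × the window's standard deviation — or
inside the half-maximum core of a bright region. The core clause exists
because a windowed contrast statistic is blind inside nucleus interiors and
in the waists between touching nuclei (the window is uniformly bright, so
pixel − mean ≈ 0); without it those pixels fall out of the mask and their
nuclear signal leaks into the ring measurements of neighboring cells.
Touching nuclei are split by a seeded watershed on the smoothed Euclidean
distance transform. "Segmentation aggressiveness" `a` maps to the peak
separation `(1 − a) × 2 × expected radius` (expected radius 5 µm): higher
aggressiveness permits closer peaks, hence more splitting; `a = 0` forbids
peaks closer than one nuclear diameter and merges dumbbells. Components
outside 1–450 µm² are discarded.

Compartments: the nucleus is the labeled region; the membrane is the 0.5-µm
ring of background just outside it and the cytoplasm the next 2-µm ring.
Contested background pixels go to the nearest nucleus (exact Euclidean
distance transform with index return), which the tests verify against a
brute-force per-pixel assignment. A nucleus with an empty ring falls back
to its nuclear mean rather than emitting a missing value.

## Phenotyping

A cell is marker-positive when **any** compartment mean reaches its
threshold (CD8: 0.344/0.025/0.025; CD133: 0.524/0.045/0.045; CK19:
0.624/0.025/0.025; comparison inclusive). The OR rule is a design choice:
the cytoplasm/membrane thresholds sit an order of magnitude below the
nuclear ones, which reads as "each alone suffices"; AND and nucleus-only
variants are a flag away. Markers are called independently; an optional
CK19-priority mode makes tallies disjoint.

## Tumor budding

CK19+ cells are vertices; edges join centroids within the contact distance
(default 20 µm ≈ two nuclear diameters — the grouping rule itself is not
published; a mask-adjacency mode is available when label masks exist).
Connected components of 1–5 nuclei are buds, ≥ 6 ducts/nests. Budding is
counted over the whole analyzed region; no invasive-front delineation is
attempted.

## Spatial statistics

Distance classes are half-open `[lo, hi)` µm bins of each CD8+ cell's
distance to its **nearest** reference center. The adjacency ratio divides
by all CD8+ cells in the region (making the published 0.21/0.19 cutoffs
slide-level fractions); a within-100-µm denominator is available. The
cross-type K uses the reduced-sample (border) correction by default —
at radius r only references ≥ r from the boundary count — and an
uncorrected mode for guard-banded synthetic windows. L is monotone in r
without edge correction; with border correction the changing reference set
can produce small non-monotonicities, which we leave visible rather than
enforce away. CSR envelopes re-randomize the query pattern uniformly; the
acceptance check uses a rank envelope (399 simulations, 10th extremes) so a
fresh CSR replicate falls inside with probability exactly 0.95.

## Indices and dichotomization

CD8/TB and CD8/CD133 are count ratios; with a zero denominator the index is
undefined (NaN) and resolves to the prognostically favorable high group —
a slide with no buds cannot be in the adverse low-CD8/TB group. For Cox
design matrices the same rule appears continuously: undefined indices are
imputed with the cohort maximum. Cohort cutoffs are per-feature medians,
lower-middle order statistic for even n so the inclusive "≤ cutoff" group
always contains the median patient. The published cohort cutoffs
(309.2/131.6/336.1 per mm², 3.73, 3.325, 0.21, 0.19) ship as constants for
scoring new slides against the original groups.

## Survival modeling

Cox fits use the Efron tie correction (month-resolution times tie heavily)
and the Breslow baseline, via lifelines. The nomogram assigns factor j the
points `100·β_j·(x − ref_j)/D`, where `ref_j` is the risk-minimizing end of
the factor's observed range and `D = max_k |β_k|·range_k`, so the most
influential factor spans 0–100 and total points are an exact affine image
of the linear predictor (round trip < 1e-9, asserted). Survival lookup at
12/24/36 months goes through the Breslow baseline at the covariate means.
The integrated immune-CSC-TB profile refits a two-factor Cox model
(CD8/CD133 and CD8/TB) and sums the two point contributions; refitting,
rather than slicing the 8-factor model, is the default because the
published description reads as a rescaled standalone score, and both modes
are exposed.

Evaluation: Harrell's C counts pairs whose earlier time is an event, ties
in score at one half (normal-approximation CI); calibration bins patients
by predicted-survival decile against within-group Kaplan–Meier;
time-dependent ROC uses cumulative/dynamic IPCW weights (1/G(t⁻) for
cases, 1/G(τ) for controls, G the censoring KM) and reduces exactly to the
binary empirical AUC when censoring is absent; decision curves estimate
the event probability in each treated stratum by KM so censoring is
respected, with treat-all/treat-none references.

## Synthetic generators

**Tissue.** Tumor cells follow a Thomas cluster process: Poisson parents at
`nest_rate` (offspring ≥ 6, mean 20, dispersion 30 µm) and `bud_rate`
(1–5 offspring uniform, dispersion 6 µm). CSC labels are Bernoulli —
0.12 inside buds, 0.02 elsewhere — making CD133 co-localize with budding.
CD8+ cells are an inhomogeneously thinned CSR process: intensity
`λ·exp(γ)` within the interaction radius (20 µm) of bud/CSC centers and
`λ` outside, so `γ = 0` is exact CSR, `γ < 0` repulsion, `γ > 0`
attraction. Defaults (1 mm² window, λ = 310 CD8/mm², 330 buds/mm²) land
the slide-level marginals near the published cohort medians.

**Intensities.** Per marker and compartment, negatives and positives are
log-normal classes with log-means `separation_sd/2` standard deviations
below/above the log threshold (σ_log = 0.25), truncated at 3 SD because
real normalized intensities occupy a bounded range. Separation ≥ 6 SD
therefore gives error-free phenotyping; shrinking it to 4/2/1 SD dials in
graded, monotone error — the axis along which truth-agreement is tested.

**Images.** Cells render as flat disks (DAPI 0.9) with marker values flat
over the same compartment geometry the measurement stage assumes; pixels
contested by overlapping disks go to the nearest center, mirroring the
nearest-nucleus measurement rule, and one-pixel guard bands absorb
mask-edge jitter. Flat profiles (rather than Gaussian blobs) keep the
rendered footprint and the segmented mask coincident — with Gaussian
profiles the contrast criterion would shrink masks to the blob tops and
corrupt ring measurements. Gaussian raster noise is added last. The
renderer does not attempt stromal texture, autofluorescence or intensity
vignetting: passing tests show the pipeline's operations are correct on
geometrically faithful tissue, not that the segmenter is robust to real
slide artifacts.

**Cohorts.** Eight latent standard normals with a block-sign correlation
(0.7·I + 0.3·ss^T, s = ±1: CD8-favorable factors move together and against
CD133/TB/stage) map to observable scales anchored at the published medians
(log-normal densities/indices, logistic ratios, tercile TNM stage). Event
times are Weibull proportional hazards (shape 1.3, scale 25 months ⇒
baseline median ≈ 19 months, a realistic resected-PDAC figure) with the
linear predictor `effects · z`; censoring is uniform on (0, 60] months
(five-year follow-up, ≈ 30% censoring). The default effect vector encodes
the published signs with moderate magnitudes (|β| 0.25–0.5 per latent SD),
sized so a median split of a driving factor yields a group hazard ratio
near 2. `design_matrix` inverts the observable transforms, so Cox fits on
it recover the generating coefficients exactly in expectation — the basis
of the recovery and coverage checks.

## Problem sizes and numerical choices

Tests run at window sizes of 0.09–1 mm², cohorts of 150–2000 patients,
200 null-coverage replicates and 100-instance oracle sweeps — sizes chosen
to keep the whole suite under a minute while leaving Monte-Carlo margins
(3-SE bands, binomial CIs, rank envelopes) decisive. Degenerate inputs are
errors, not silent zeros: empty reference sets, zero areas, single-group
log-rank, constant or collinear Cox covariates, horizons beyond follow-up.
Determinism is a contract: one master seed splits into fixed named streams,
so identical parameters and seed give byte-identical outputs.

## Known limitations

* Segmentation is a classical pipeline; bit-compatibility with the closed
  vendor system is impossible and not attempted — parameters are honored in
  role, not in implementation detail.
* The published numeric endpoints (C-index 0.746/0.755, the cohort
  cutoffs) derive from private patient cohorts; here they serve as scale
  anchors for the generators and shipped constants, not as reproduction
  targets. The package reproduces the *directional* findings on synthetic
  cohorts.
* Whole-slide tiling, invasive-front detection, exhaustion phenotyping and
  competing-risks modeling are out of scope.
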