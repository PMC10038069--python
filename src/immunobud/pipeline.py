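"""Slide- and cohort-level orchestration plus truth-based evaluation.

``run_slide`` chains segmentation -> phenotyping -> budding -> spatial
statistics -> feature assembly for one field of view, accepting either a
4-channel raster or an externally produced cell table.  ``run_cohort``
computes cohort cutoffs, per-factor survival splits, uni-/multivariate Cox
fits, the 8-factor nomogram, the refit 2-factor integrated profile and the
evaluation battery.  ``evaluate_against_truth`` scores detections against a
:class:`~immunobud.synthgen.SyntheticTruth` with sensitivity, specificity
and Youden index per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import budding, indices, phenotype, segment, spatial, survival
from .synthgen import SyntheticTruth


@dataclass(frozen=True)
class RunConfig:
    pixel_size_um: float = 0.5
    segmentation: segment.SegmentationParams = field(default_factory=segment.SegmentationParams)
    panel: phenotype.MarkerPanel = field(default_factory=phenotype.MarkerPanel)
    contact_distance: float = budding.DEFAULT_CONTACT_DISTANCE
    bin_edges: tuple = spatial.DEFAULT_BIN_EDGES
    adjacency_radius: float = spatial.DEFAULT_ADJACENCY_RADIUS
    ratio_denominator: str = "all"  # {all, within100}
    cutoff_mode: str = "median"  # {median, published, user}
    user_cutoffs: Mapping[str, float] | None = None
    horizons: tuple = survival.NOMOGRAM_HORIZONS
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel"] = {
            name: {
                "channel": thr.channel,
                "nucleus": thr.nucleus,
                "cytoplasm": thr.cytoplasm,
                "membrane": thr.membrane,
            }
            for name, thr in self.panel.markers.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        seg = d.pop("segmentation", {})
        panel = d.pop("panel", None)
        kwargs = dict(d)
        if isinstance(seg, Mapping):
            seg = dict(seg)
            for key in ("dye_weights", "area_range"):
                if key in seg:
                    seg[key] = tuple(seg[key])
            kwargs["segmentation"] = segment.SegmentationParams(**seg)
        else:
            kwargs["segmentation"] = seg
        if isinstance(panel, Mapping):
            kwargs["panel"] = phenotype.MarkerPanel(
                markers={
                    name: phenotype.MarkerThresholds(
                        p["channel"], p["nucleus"], p["cytoplasm"], p["membrane"]
                    )
                    for name, p in panel.items()
                }
            )
        elif panel is not None:
            kwargs["panel"] = panel
        for key in ("bin_edges", "horizons"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class SlideResult:
    cells: pd.DataFrame  # phenotyped cell table
    clusters: list
    tb_profile: spatial.DistanceProfile | None
    csc_profile: spatial.DistanceProfile | None
    features: indices.PatientFeatures


REQUIRED_TABLE_COLUMNS = ("cell_id", "x", "y", "nucleus_area")


def run_slide(
    config: RunConfig,
    image: np.ndarray | None = None,
    cell_table: pd.DataFrame | None = None,
    tissue_area_mm2: float | None = None,
    tnm_stage: int = 1,
    patient_id: object = None,
) -> SlideResult:
    """Full single-slide analysis from a raster or a pre-segmented table."""
    if (image is None) == (cell_table is None):
        raise ValueError("provide exactly one of image or cell_table")

    if image is not None:
        comp = segment.composite_nuclear_channel(image, config.segmentation.dye_weights)
        labels, _ = segment.segment_nuclei(comp, config.segmentation, config.pixel_size_um)
        measured = segment.measure_compartments(
            labels, image, config.segmentation, config.pixel_size_um
        )
        if tissue_area_mm2 is None:
            tissue_area_mm2 = image.shape[1] * image.shape[2] * config.pixel_size_um**2 / 1e6
    else:
        missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in cell_table.columns]
        if missing:
            raise ValueError(f"cell table is missing required columns: {missing}")
        if tissue_area_mm2 is None:
            raise ValueError("tissue_area_mm2 is required with a cell table")
        measured = cell_table

    cells = phenotype.phenotype_cells(measured, config.panel)
    ck19 = cells.loc[cells.is_ck19]
    clusters = budding.cluster_tumor_cells(ck19, config.contact_distance)
    buds = [c for c in clusters if c.is_budding]

    cd8_pts = cells.loc[cells.is_cd8, ["x", "y"]].to_numpy()
    bud_pts = np.array(
        [p for c in buds for p in c.member_centroids], dtype=float
    ).reshape(-1, 2)
    csc_pts = cells.loc[cells.is_cd133, ["x", "y"]].to_numpy()
    tb_profile = (
        spatial.distance_profile(cd8_pts, bud_pts, config.bin_edges)
        if len(bud_pts) and len(cd8_pts)
        else None
    )
    csc_profile = (
        spatial.distance_profile(cd8_pts, csc_pts, config.bin_edges)
        if len(csc_pts) and len(cd8_pts)
        else None
    )
    feats = indices.patient_features(
        cells,
        clusters,
        tissue_area_mm2,
        tnm_stage,
        patient_id=patient_id,
        adjacency_radius=config.adjacency_radius,
        ratio_denominator=config.ratio_denominator,
    )
    return SlideResult(cells, clusters, tb_profile, csc_profile, feats)


@dataclass(frozen=True)
class CohortResult:
    features: pd.DataFrame  # with group columns
    cutoffs: indices.CutoffSet
    logrank: pd.DataFrame  # per dichotomized factor
    univariate: pd.DataFrame
    multivariate: survival.CoxFit
    nomogram: survival.NomogramModel
    integrated_fit: survival.CoxFit
    integrated_nomogram: survival.NomogramModel
    integrated_scores: np.ndarray
    evaluation: Mapping


def run_cohort(
    config: RunConfig, features: pd.DataFrame, records: pd.DataFrame
) -> CohortResult:
    """Cohort-level modeling on a per-patient feature table.

    ``features`` needs the eight factor columns plus patient_id; ``records``
    needs patient_id, time, event with one row per patient.
    """
    if features["patient_id"].duplicated().any():
        raise ValueError("duplicated patient ids in the feature table")
    if len(features) < 20:
        raise ValueError("cohort modeling requires at least 20 patients")
    merged = features.merge(records, on="patient_id", validate="one_to_one")
    rec = merged[["time", "event"]]

    if config.cutoff_mode == "median":
        cuts = indices.median_cutoffs(merged)
    elif config.cutoff_mode == "published":
        cuts = indices.CutoffSet(dict(indices.PUBLISHED_CUTOFFS), provenance="published-constants")
    elif config.cutoff_mode == "user":
        if not config.user_cutoffs:
            raise ValueError("cutoff_mode='user' requires user_cutoffs")
        cuts = indices.CutoffSet(dict(config.user_cutoffs), provenance="user-supplied")
    else:
        raise ValueError(f"unknown cutoff mode {config.cutoff_mode!r}")
    grouped = indices.dichotomize(merged, cuts)

    lr_rows = []
    for f in cuts.cutoffs:
        stat, p = survival.logrank_test(grouped[f"{f}_group"], rec)
        med = {
            g: survival.km_estimate(rec.loc[(grouped[f"{f}_group"] == g).to_numpy()]).median
            for g in ("low", "high")
        }
        lr_rows.append(
            {
                "factor": f,
                "chi2": stat,
                "p": p,
                "median_low": med["low"],
                "median_high": med["high"],
            }
        )
    lr = pd.DataFrame(lr_rows)

    factor_list = list(indices.FEATURE_NAMES)
    model_X = merged[factor_list].copy()
    # undefined indices (zero denominators) cannot enter a Cox design matrix;
    # impute with the cohort maximum, the continuous analog of the
    # favorable-group rule
    for f in factor_list:
        if model_X[f].isna().any():
            model_X[f] = model_X[f].fillna(model_X[f].max())

    uni = survival.univariate_cox(model_X, rec, factor_list)
    multi = survival.cox_fit(model_X, rec, factor_list)
    ranges = {f: (float(model_X[f].min()), float(model_X[f].max())) for f in factor_list}
    nomo = survival.build_nomogram(multi, ranges, config.horizons)

    int_factors = list(survival.INTEGRATED_FACTORS)
    int_fit = survival.cox_fit(model_X, rec, int_factors)
    int_ranges = {f: ranges[f] for f in int_factors}
    int_nomo = survival.build_nomogram(int_fit, int_ranges, config.horizons)
    scores = survival.integrated_profile_score(int_nomo, model_X)

    evaluation = {}
    c_full, ci_full = survival.concordance_index(
        multi.linear_predictor(model_X), rec["time"], rec["event"]
    )
    c_int, ci_int = survival.concordance_index(scores, rec["time"], rec["event"])
    tnm_fit = survival.cox_fit(model_X, rec, ["tnm_stage"])
    c_tnm, ci_tnm = survival.concordance_index(
        tnm_fit.linear_predictor(model_X), rec["time"], rec["event"]
    )
    evaluation["c_index"] = {
        "nomogram_8factor": {"c": c_full, "ci": ci_full},
        "integrated_profile": {"c": c_int, "ci": ci_int},
        "tnm_only": {"c": c_tnm, "ci": ci_tnm},
    }
    horizon = config.horizons[-1]
    if horizon <= rec["time"].max():
        evaluation["calibration"] = survival.calibration_curve(
            lambda df: multi.predict_survival(df, horizon), model_X, rec, horizon
        )
        try:
            auc, _ = survival.time_dependent_roc(scores, rec, horizon)
            evaluation["tdep_auc"] = auc
        except ValueError:
            evaluation["tdep_auc"] = float("nan")
        risk = 1.0 - int_fit.predict_survival(model_X, horizon)
        evaluation["decision_curve"] = survival.decision_curve(
            risk, rec, horizon, np.linspace(0.05, 0.95, 19)
        )
    return CohortResult(
        features=grouped,
        cutoffs=cuts,
        logrank=lr,
        univariate=uni,
        multivariate=multi,
        nomogram=nomo,
        integrated_fit=int_fit,
        integrated_nomogram=int_nomo,
        integrated_scores=scores,
        evaluation=evaluation,
    )


# ---------------------------------------------------------------------------
# Evaluation against synthetic ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionMetrics:
    per_class: pd.DataFrame  # sensitivity, specificity, youden, TP/FP/FN/TN
    matched_pairs: int
    tb_sensitivity: float


def _greedy_match(pred_xy: np.ndarray, true_xy: np.ndarray, radius: float):
    """Greedy nearest-pair matching within ``radius``; each point used once."""
    if len(pred_xy) == 0 or len(true_xy) == 0:
        return []
    tree = cKDTree(true_xy)
    pairs = []
    for i, row in enumerate(pred_xy):
        for j in tree.query_ball_point(row, radius):
            d = np.hypot(*(row - true_xy[j]))
            pairs.append((d, i, j))
    pairs.sort()
    used_p, used_t, matches = set(), set(), []
    for d, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches.append((i, j))
    return matches


def evaluate_against_truth(
    predicted: pd.DataFrame,
    truth: SyntheticTruth,
    match_radius: float = 5.0,
    predicted_clusters: Sequence | None = None,
) -> DetectionMetrics:
    """Confusion statistics of predicted phenotypes against ground truth.

    Predicted and true cells are matched greedily by centroid distance
    within ``match_radius``; per marker, matched pairs populate the
    confusion matrix while unmatched true positives count as misses and
    unmatched predicted positives as false calls.  Tumor buds are scored at
    the cluster level: a true bud counts as found when some predicted
    cluster shares >= 0.5 Jaccard overlap of member ids.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    tc = truth.true_cells
    pred_xy = predicted[["x", "y"]].to_numpy(dtype=float)
    true_xy = tc[["x", "y"]].to_numpy(dtype=float)
    matches = _greedy_match(pred_xy, true_xy, match_radius)
    m_pred = [i for i, _ in matches]
    m_true = [j for _, j in matches]

    rows = []
    for marker in ("cd8", "cd133", "ck19"):
        col = f"is_{marker}"
        t_flags = tc[col].to_numpy(dtype=bool)
        p_flags = predicted[col].to_numpy(dtype=bool) if col in predicted else np.zeros(len(predicted), bool)
        tp = int(np.sum(p_flags[m_pred] & t_flags[m_true]))
        tn = int(np.sum(~p_flags[m_pred] & ~t_flags[m_true]))
        fp = int(np.sum(p_flags[m_pred] & ~t_flags[m_true]))
        fn = int(np.sum(~p_flags[m_pred] & t_flags[m_true]))
        unmatched_true = np.setdiff1d(np.arange(len(tc)), m_true)
        fn += int(t_flags[unmatched_true].sum())
        tn += int((~t_flags[unmatched_true]).sum())
        unmatched_pred = np.setdiff1d(np.arange(len(predicted)), m_pred)
        fp += int(p_flags[unmatched_pred].sum())
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        rows.append(
            {
                "class": marker,
                "sensitivity": sens,
                "specificity": spec,
                "youden": sens + spec - 1.0,
                "TP": tp,
                "FP": fp,
                "FN": fn,
                "TN": tn,
            }
        )

    tb_sens = float("nan")
    true_buds = [m for m, is_bud in truth.true_clusters if is_bud]
    if predicted_clusters is not None and true_buds:
        # translate predicted member ids into the truth id space via matches
        pred_ids = predicted["cell_id"].to_numpy()
        true_ids = tc["cell_id"].to_numpy()
        to_true = {pred_ids[i]: true_ids[j] for i, j in matches}
        pred_sets = [
            {to_true[m] for m in c.member_ids if m in to_true}
            for c in predicted_clusters
            if c.is_budding
        ]
        found = 0
        for tb in true_buds:
            tb = set(tb)
            for ps in pred_sets:
                inter = len(tb & ps)
                union = len(tb | ps)
                if union and inter / union >= 0.5:
                    found += 1
                    break
        tb_sens = found / len(true_buds)
    return DetectionMetrics(
        per_class=pd.DataFrame(rows).set_index("class"),
        matched_pairs=len(matches),
        tb_sensitivity=tb_sens,
    )
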