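"""Per-patient feature assembly, median cutoffs and dichotomization.

The eight prognostic factors: CD8+, CD133+ and tumor-bud densities
(counts/mm^2), the anti-/pro-tumor count ratios CD8/TB and CD8/CD133, the
20-um adjacency ratios of CD8+ cells to buds and to CSCs, and TNM stage.
Cohort cutoffs default to per-feature medians; the published cohort values
are shipped as :data:`PUBLISHED_CUTOFFS` for scoring new slides against the
original groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import spatial
from .budding import TumorCluster

FEATURE_NAMES = (
    "cd8_density",
    "cd133_density",
    "tb_density",
    "cd8_tb_index",
    "cd8_cd133_index",
    "tb_adjacent_cd8_ratio",
    "csc_adjacent_cd8_ratio",
    "tnm_stage",
)

# Published cohort cutoffs (medians of the primary training cohort).
PUBLISHED_CUTOFFS: Mapping[str, float] = {
    "cd8_density": 309.2,
    "cd133_density": 131.6,
    "tb_density": 336.1,
    "cd8_tb_index": 3.73,
    "cd8_cd133_index": 3.325,
    "tb_adjacent_cd8_ratio": 0.21,
    "csc_adjacent_cd8_ratio": 0.19,
}

# Indices undefined through a zero denominator (no buds / no CSCs detected)
# resolve to the prognostically favorable high-index group: a slide without
# buds cannot sit in the adverse low-CD8/TB group.
UNDEFINED_GROUP = "high"


@dataclass(frozen=True)
class PatientFeatures:
    patient_id: object
    cd8_density: float
    cd133_density: float
    tb_density: float
    cd8_tb_index: float  # NaN = undefined (zero denominator)
    cd8_cd133_index: float
    tb_adjacent_cd8_ratio: float
    csc_adjacent_cd8_ratio: float
    tnm_stage: int
    groups: Mapping[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"patient_id": self.patient_id}
        for f in FEATURE_NAMES:
            d[f] = getattr(self, f)
        return d


@dataclass(frozen=True)
class CutoffSet:
    cutoffs: Mapping[str, float]
    provenance: str  # "cohort-median" | "user-supplied" | "published-constants"

    def __post_init__(self) -> None:
        for k, v in self.cutoffs.items():
            if not math.isfinite(v):
                raise ValueError(f"cutoff for {k} is not finite")


def patient_features(
    phenotyped: pd.DataFrame,
    clusters: Sequence[TumorCluster],
    tissue_area_mm2: float,
    tnm_stage: int,
    patient_id: object = None,
    adjacency_radius: float = spatial.DEFAULT_ADJACENCY_RADIUS,
    ratio_denominator: str = "all",
) -> PatientFeatures:
    """Assemble the eight-factor feature vector for one slide.

    The CD8/TB and CD8/CD133 indices are count ratios (equal to density
    ratios over one slide area); a zero denominator leaves the index NaN and
    the dichotomizer later assigns it to the favorable group.
    """
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue_area must be positive")
    n_cd8 = int(phenotyped["is_cd8"].sum())
    n_cd133 = int(phenotyped["is_cd133"].sum())
    buds = [c for c in clusters if c.is_budding]
    n_tb = len(buds)

    cd8_pts = phenotyped.loc[phenotyped.is_cd8, ["x", "y"]].to_numpy()
    bud_pts = np.array([p for c in buds for p in c.member_centroids], dtype=float).reshape(-1, 2)
    csc_pts = phenotyped.loc[phenotyped.is_cd133, ["x", "y"]].to_numpy()

    def _ratio(ref):
        if len(cd8_pts) == 0 or len(ref) == 0:
            return float("nan")
        return spatial.adjacent_ratio(cd8_pts, ref, radius=adjacency_radius, denominator=ratio_denominator)

    return PatientFeatures(
        patient_id=patient_id,
        cd8_density=n_cd8 / tissue_area_mm2,
        cd133_density=n_cd133 / tissue_area_mm2,
        tb_density=n_tb / tissue_area_mm2,
        cd8_tb_index=n_cd8 / n_tb if n_tb else float("nan"),
        cd8_cd133_index=n_cd8 / n_cd133 if n_cd133 else float("nan"),
        tb_adjacent_cd8_ratio=_ratio(bud_pts),
        csc_adjacent_cd8_ratio=_ratio(csc_pts),
        tnm_stage=int(tnm_stage),
    )


def features_frame(features: Sequence[PatientFeatures]) -> pd.DataFrame:
    return pd.DataFrame([f.as_dict() for f in features])


def _lower_median(values: np.ndarray) -> float:
    """Lower-middle order statistic: for even n the smaller of the two
    central values, so the inclusive '<= cutoff' group always contains the
    median patient."""
    v = np.sort(values)
    return float(v[(len(v) - 1) // 2])


def median_cutoffs(cohort: pd.DataFrame, features: Sequence[str] = FEATURE_NAMES[:-1]) -> CutoffSet:
    """Per-feature cohort medians (undefined values excluded)."""
    cuts = {}
    for f in features:
        vals = cohort[f].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(f"fewer than 2 defined values for feature {f!r}")
        cuts[f] = _lower_median(vals)
    return CutoffSet(cutoffs=cuts, provenance="cohort-median")


def dichotomize(cohort: pd.DataFrame, cutoffs: CutoffSet) -> pd.DataFrame:
    """Label each patient low/high per feature: low iff value <= cutoff.

    Undefined (NaN) values take the documented favorable-group rule.
    Returns a copy with one ``{feature}_group`` column per cutoff.
    """
    out = cohort.copy()
    for f, cut in cutoffs.cutoffs.items():
        if f not in cohort.columns:
            raise ValueError(f"feature {f!r} missing from cohort table")
        vals = cohort[f].to_numpy(dtype=float)
        grp = np.where(vals <= cut, "low", "high")
        grp = np.where(np.isfinite(vals), grp, UNDEFINED_GROUP)
        out[f"{f}_group"] = grp
    return out
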