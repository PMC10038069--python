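"""Synthetic tissue, image and cohort generators with known ground truth.

The tissue generator emulates the statistical structure of a pancreatic
ductal adenocarcinoma (PDAC) microenvironment as the downstream analysis
assumes it: CK19+ tumor cells placed by a Thomas cluster process split into
large ducts/nests (>= 6 nuclei) and small buds (1-5 nuclei), CD133+ cancer
stem cells (CSCs) enriched inside buds, and CD8+ T cells placed by complete
spatial randomness (CSR) optionally thinned (repulsion) or boosted
(attraction) near bud/CSC centers.  Marker intensities are drawn from
log-normal classes straddling the phenotyping thresholds so classification
error rates can be dialed from zero upward via the class separation.

The cohort generator draws correlated per-patient features on the scales of
the real cohorts (density medians 309.2 / 131.6 / 336.1 per mm^2, index
medians 3.73 / 3.325, adjacency-ratio medians 0.21 / 0.19) and survival
times from a Weibull proportional-hazards model whose linear predictor is
built from the eight prognostic factors used by the nomogram.

All generators are deterministic given their seed: one master seed is split
into fixed named streams so adding a feature never reshuffles existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CHANNELS = ("dapi", "opal520", "opal570", "opal690")
MARKER_CHANNELS = {"cd8": "opal520", "cd133": "opal570", "ck19": "opal690"}
COMPARTMENTS = ("nucleus", "cytoplasm", "membrane")

# Default per-compartment positivity thresholds (normalized intensity), the
# published values the intensity classes straddle.
DEFAULT_THRESHOLDS = {
    "cd8": {"nucleus": 0.344, "cytoplasm": 0.025, "membrane": 0.025},
    "cd133": {"nucleus": 0.524, "cytoplasm": 0.045, "membrane": 0.045},
    "ck19": {"nucleus": 0.624, "cytoplasm": 0.025, "membrane": 0.025},
}

_STREAMS = ("nests", "buds", "csc", "cd8", "areas", "intensity", "noise", "cohort")


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal intensity classes per marker and compartment.

    For each (marker, compartment) the negative and positive classes are
    log-normal with a common log-scale sigma and log-means placed
    ``separation_sd/2`` standard deviations below/above the log threshold.
    Draws are truncated at 3 SD (intensities occupy a bounded biological
    range), so at separation >= 6 SD the classes never cross the threshold
    and phenotyping against truth is error-free.
    """

    separation_sd: float = 6.0
    log_sigma: float = 0.25
    thresholds: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_THRESHOLDS
    )

    def sample(
        self,
        marker: str,
        compartment: str,
        positive: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        thr = self.thresholds[marker][compartment]
        half = 0.5 * self.separation_sd
        center = np.where(positive, half, -half)
        z = rng.uniform(size=positive.shape)
        # inverse-CDF truncated standard normal on [-3, 3]
        from scipy.stats import norm

        lo, hi = norm.cdf(-3.0), norm.cdf(3.0)
        t = norm.ppf(lo + z * (hi - lo))
        vals = np.exp(np.log(thr) + self.log_sigma * (center + t))
        return np.clip(vals, 0.0, 1.0)


@dataclass(frozen=True)
class TissueSimParams:
    """Parameters of the synthetic tissue point process.

    Defaults reproduce slide-level marginals close to the published cohort
    medians: ~310 CD8+ cells/mm^2, ~330 buds/mm^2 and ~130 CD133+ cells/mm^2
    on a 1 mm^2 window.
    """

    window_width: float = 1000.0  # um
    window_height: float = 1000.0  # um
    pixel_size: float = 0.5  # um / px
    nest_rate: float = 8.0  # parent nests per mm^2
    nest_size_mean: float = 20.0  # expected cells per nest (>= 6 enforced)
    nest_sigma: float = 30.0  # offspring dispersion, um
    bud_rate: float = 330.0  # parent buds per mm^2
    bud_size_range: tuple[int, int] = (1, 5)
    bud_sigma: float = 6.0  # offspring dispersion, um
    csc_fraction_in_buds: float = 0.12
    csc_fraction_elsewhere: float = 0.02
    cd8_intensity: float = 310.0  # cells per mm^2
    cd8_interaction: float = 0.0  # log-intensity modifier near bud/CSC centers
    interaction_radius: float = 20.0  # um
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    nucleus_radius_mean: float = 4.0  # um
    nucleus_radius_sd: float = 0.4  # um
    noise_sd: float = 0.0  # raster Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nest_rate, self.bud_rate, self.cd8_intensity) < 0:
            raise ValueError("rates must be non-negative")
        lo, hi = self.bud_size_range
        if not (1 <= lo <= hi <= 5):
            raise ValueError("bud_size_range must lie within [1, 5]")
        for p in (self.csc_fraction_in_buds, self.csc_fraction_elsewhere):
            if not 0.0 <= p <= 1.0:
                raise ValueError("CSC fractions must be probabilities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def area_mm2(self) -> float:
        return self.window_width * self.window_height / 1e6


@dataclass(frozen=True)
class SyntheticTruth:
    """Immutable ground truth emitted alongside every synthetic realization."""

    true_cells: pd.DataFrame  # cell_id, x, y, area, is_cd8/is_cd133/is_ck19
    true_clusters: tuple[tuple[frozenset, bool], ...]  # (member ids, is_budding)
    true_patient_features: Mapping[str, float]
    generator_params: TissueSimParams

    def __post_init__(self) -> None:
        seen: set = set()
        for members, _ in self.true_clusters:
            if seen & members:
                raise ValueError("a true cell belongs to more than one cluster")
            seen |= members


def _truncated_poisson_ge(rng: np.random.Generator, mean: float, floor: int, n: int) -> np.ndarray:
    """Poisson shifted so every draw is >= floor, preserving the mean."""
    excess = max(mean - floor, 0.0)
    return floor + rng.poisson(excess, size=n)


def simulate_cell_table(params: TissueSimParams) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a phenotyped-cell-like table with continuous intensities.

    Returns a DataFrame (cell_id, x, y, nucleus_area, per channel x
    compartment intensity columns) plus the :class:`SyntheticTruth` that
    produced it.  Tumor cells come from the Thomas cluster process; CD8+
    T cells from (optionally interacting) CSR.
    """
    rng = _rng_streams(params.seed)
    W, H = params.window_width, params.window_height
    area = params.area_mm2

    if params.nest_rate > 0 and params.nest_rate * area < 1.0:
        raise ValueError(
            f"window of {area:.4f} mm^2 too small to host one nest at "
            f"nest_rate={params.nest_rate}/mm^2; enlarge the window or set nest_rate=0"
        )

    xs, ys, labels, parent_ids, is_bud_parent = [], [], [], [], []

    def _scatter(rg, n_parents, sizes, sigma, tag):
        px = rg.uniform(0, W, n_parents)
        py = rg.uniform(0, H, n_parents)
        for k in range(n_parents):
            n_off = int(sizes[k])
            ox = np.clip(px[k] + rg.normal(0, sigma, n_off), 0, W)
            oy = np.clip(py[k] + rg.normal(0, sigma, n_off), 0, H)
            xs.append(ox)
            ys.append(oy)
            parent_ids.append(np.full(n_off, len(parent_seen)))
            parent_seen.append(tag)

    parent_seen: list[str] = []
    rg = rng["nests"]
    n_nests = rg.poisson(params.nest_rate * area)
    nest_sizes = _truncated_poisson_ge(rg, params.nest_size_mean, 6, n_nests)
    _scatter(rg, n_nests, nest_sizes, params.nest_sigma, "nest")

    rg = rng["buds"]
    n_buds = rg.poisson(params.bud_rate * area)
    lo, hi = params.bud_size_range
    bud_sizes = rg.integers(lo, hi + 1, size=n_buds)
    _scatter(rg, n_buds, bud_sizes, params.bud_sigma, "bud")

    if xs:
        tx = np.concatenate(xs)
        ty = np.concatenate(ys)
        tparent = np.concatenate(parent_ids)
    else:
        tx = ty = np.empty(0)
        tparent = np.empty(0, dtype=int)
    n_tumor = tx.size
    in_bud = np.array([parent_seen[p] == "bud" for p in tparent], dtype=bool) if n_tumor else np.empty(0, bool)

    p_csc = np.where(in_bud, params.csc_fraction_in_buds, params.csc_fraction_elsewhere)
    is_csc = rng["csc"].uniform(size=n_tumor) < p_csc

    # CD8: thinning of a dominating CSR process gives intensity
    # lambda0 * exp(gamma) within interaction_radius of bud/CSC centers and
    # lambda0 outside; gamma = 0 reduces to exact CSR.
    rg = rng["cd8"]
    gamma = params.cd8_interaction
    lam_max = params.cd8_intensity * max(1.0, np.exp(gamma))
    n_cand = rg.poisson(lam_max * area)
    cx = rg.uniform(0, W, n_cand)
    cy = rg.uniform(0, H, n_cand)
    centers_mask = in_bud | is_csc
    centers = np.column_stack([tx[centers_mask], ty[centers_mask]]) if centers_mask.any() else None
    if centers is not None and n_cand:
        d, _ = cKDTree(centers).query(np.column_stack([cx, cy]))
        near = d <= params.interaction_radius
    else:
        near = np.zeros(n_cand, dtype=bool)
    lam = params.cd8_intensity * np.where(near, np.exp(gamma), 1.0)
    keep = rg.uniform(size=n_cand) < lam / lam_max
    cx, cy = cx[keep], cy[keep]
    n_cd8 = cx.size

    n = n_tumor + n_cd8
    cell_id = np.arange(n)
    x = np.concatenate([tx, cx])
    y = np.concatenate([ty, cy])
    is_ck19 = np.concatenate([np.ones(n_tumor, bool), np.zeros(n_cd8, bool)])
    is_cd133 = np.concatenate([is_csc, np.zeros(n_cd8, bool)])
    is_cd8 = np.concatenate([np.zeros(n_tumor, bool), np.ones(n_cd8, bool)])

    radii = np.clip(
        rng["areas"].normal(params.nucleus_radius_mean, params.nucleus_radius_sd, n),
        0.5 * params.nucleus_radius_mean,
        None,
    )
    areas = np.pi * radii**2

    table = pd.DataFrame(
        {"cell_id": cell_id, "x": x, "y": y, "nucleus_area": areas}
    )
    truth_flags = {"cd8": is_cd8, "cd133": is_cd133, "ck19": is_ck19}
    irng = rng["intensity"]
    for marker, channel in MARKER_CHANNELS.items():
        for comp in COMPARTMENTS:
            table[f"{channel}_{comp}"] = params.intensity_model.sample(
                marker, comp, truth_flags[marker], irng
            )

    truth_cells = pd.DataFrame(
        {
            "cell_id": cell_id,
            "x": x,
            "y": y,
            "area": areas,
            "is_cd8": is_cd8,
            "is_cd133": is_cd133,
            "is_ck19": is_ck19,
        }
    )
    clusters = []
    for pid in range(len(parent_seen)):
        members = frozenset(cell_id[:n_tumor][tparent == pid].tolist())
        if members:
            clusters.append((members, parent_seen[pid] == "bud" and len(members) <= 5))
    truth = SyntheticTruth(
        true_cells=truth_cells,
        true_clusters=tuple(clusters),
        true_patient_features=_true_features(truth_cells, clusters, area, params),
        generator_params=params,
    )
    return table, truth


def _true_features(cells: pd.DataFrame, clusters, area_mm2: float, params: TissueSimParams) -> dict:
    n_cd8 = int(cells["is_cd8"].sum())
    n_cd133 = int(cells["is_cd133"].sum())
    n_tb = sum(1 for _, b in clusters if b)
    feats = {
        "cd8_density": n_cd8 / area_mm2,
        "cd133_density": n_cd133 / area_mm2,
        "tb_density": n_tb / area_mm2,
        "cd8_tb_index": n_cd8 / n_tb if n_tb else float("nan"),
        "cd8_cd133_index": n_cd8 / n_cd133 if n_cd133 else float("nan"),
    }
    # adjacency of CD8 to bud members / CSCs, same 20-um rule as the analysis
    q = cells.loc[cells.is_cd8, ["x", "y"]].to_numpy()
    bud_ids = set().union(*[m for m, b in clusters if b]) if n_tb else set()
    bud_pts = cells.loc[cells.cell_id.isin(bud_ids), ["x", "y"]].to_numpy()
    csc_pts = cells.loc[cells.is_cd133, ["x", "y"]].to_numpy()
    for key, ref in (("tb_adjacent_cd8_ratio", bud_pts), ("csc_adjacent_cd8_ratio", csc_pts)):
        if len(q) and len(ref):
            d, _ = cKDTree(ref).query(q)
            feats[key] = float(np.mean(d <= 20.0))
        else:
            feats[key] = float("nan")
    return feats


def render_multiplex(cells: pd.DataFrame, truth_cells: pd.DataFrame, params: TissueSimParams) -> np.ndarray:
    """Rasterize a cell table into a (4, H, W) float image.

    Nuclei are rendered as flat disks (DAPI amplitude 0.9) at the cell's
    true radius, with the marker channels flat over the matching compartment
    geometry: nucleus disk, 0.5-um membrane ring, 2-um cytoplasm ring.  Flat
    profiles keep the rendered footprint and the segmented mask coincident,
    so measured compartment means track the drawn intensities.  Gaussian
    raster noise of ``noise_sd`` is added last.
    """
    from scipy import ndimage as ndi

    ps = params.pixel_size
    if params.nucleus_radius_mean / ps < 1.0:
        raise ValueError("pixel_size too coarse: mean nucleus radius is below one pixel")
    H = int(round(params.window_height / ps))
    W = int(round(params.window_width / ps))
    img = np.zeros((4, H, W), dtype=np.float64)
    chan_index = {c: i for i, c in enumerate(CHANNELS)}
    n = len(cells)
    if n:
        # per-pixel ownership: overlapping disks resolved by nearest center,
        # mirroring the nearest-nucleus rule the measurement stage applies
        owner = np.zeros((H, W), dtype=np.int64)
        dmin = np.full((H, W), np.inf)
        radii = np.sqrt(truth_cells["area"].to_numpy(dtype=float) / np.pi)
        cxs = cells["x"].to_numpy(dtype=float)
        cys = cells["y"].to_numpy(dtype=float)
        for i in range(n):
            r = radii[i]
            cx, cy = cxs[i] / ps, cys[i] / ps
            ext = int(np.ceil(r / ps)) + 2
            x0, x1 = max(0, int(cx) - ext), min(W, int(cx) + ext + 1)
            y0, y1 = max(0, int(cy) - ext), min(H, int(cy) + ext + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d = np.hypot((xx + 0.5) - cx, (yy + 0.5) - cy) * ps
            closer = (d <= r) & (d < dmin[y0:y1, x0:x1])
            owner[y0:y1, x0:x1][closer] = i + 1
            dmin[y0:y1, x0:x1][closer] = d[closer]

        img[chan_index["dapi"]] = np.where(owner > 0, 0.9, 0.0)
        bg = owner == 0
        dist_px, (iy, ix) = ndi.distance_transform_edt(bg, return_indices=True)
        ring_owner = owner[iy, ix]
        dist_um = dist_px * ps
        # one-pixel guard band: the innermost ring shell keeps membrane values
        # so mask-edge jitter after smoothing stays membrane-classified
        inner = bg & (dist_um <= 0.5 + ps)
        outer = bg & (dist_um > 0.5 + ps) & (dist_um <= 2.5 + ps)
        nuc_core = (owner > 0) & (dmin <= np.maximum(
            np.take(np.concatenate([[0.0], radii]), owner) - ps, 0.0
        ))
        nuc_edge = (owner > 0) & ~nuc_core
        for channel in CHANNELS[1:]:
            nuc = np.concatenate([[0.0], cells[f"{channel}_nucleus"].to_numpy(dtype=float)])
            mem = np.concatenate([[0.0], cells[f"{channel}_membrane"].to_numpy(dtype=float)])
            cyt = np.concatenate([[0.0], cells[f"{channel}_cytoplasm"].to_numpy(dtype=float)])
            plane = np.zeros((H, W))
            plane[nuc_core] = nuc[owner[nuc_core]]
            plane[nuc_edge] = mem[owner[nuc_edge]]
            plane[inner] = mem[ring_owner[inner]]
            plane[outer] = cyt[ring_owner[outer]]
            img[chan_index[channel]] = plane

    if params.noise_sd > 0:
        noise_rng = _rng_streams(params.seed)["noise"]
        img = img + noise_rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def simulate_multiplex_image(params: TissueSimParams) -> tuple[np.ndarray, SyntheticTruth]:
    """Simulate a tissue realization and rasterize it to a 4-channel image."""
    cells, truth = simulate_cell_table(params)
    return render_multiplex(cells, truth.true_cells, params), truth


def write_ome_tiff(path, image: np.ndarray, pixel_size_um: float) -> None:
    """Write a multichannel raster with physical pixel-size metadata."""
    import tifffile

    tifffile.imwrite(
        path,
        image.astype(np.float32),
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": pixel_size_um,
            "PhysicalSizeXUnit": "um",
            "PhysicalSizeY": pixel_size_um,
            "PhysicalSizeYUnit": "um",
        },
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

FACTORS = (
    "cd8_density",
    "cd133_density",
    "tb_density",
    "cd8_tb_index",
    "cd8_cd133_index",
    "tb_adjacent_cd8_ratio",
    "csc_adjacent_cd8_ratio",
    "tnm_stage",
)

# Log-hazard coefficients reproducing the published direction of effect:
# abundant CD8 and high anti-/pro-tumor indices protect, stemness/budding and
# stage harm.
PUBLISHED_SIGN_EFFECTS: dict[str, float] = {
    "cd8_density": -0.35,
    "cd133_density": 0.35,
    "tb_density": 0.35,
    "cd8_tb_index": -0.5,
    "cd8_cd133_index": -0.5,
    "tb_adjacent_cd8_ratio": -0.25,
    "csc_adjacent_cd8_ratio": -0.25,
    "tnm_stage": 0.4,
}

# Observable scales anchored at the published cohort medians.
_FEATURE_MEDIANS = {
    "cd8_density": 309.2,
    "cd133_density": 131.6,
    "tb_density": 336.1,
    "cd8_tb_index": 3.73,
    "cd8_cd133_index": 3.325,
    "tb_adjacent_cd8_ratio": 0.21,
    "csc_adjacent_cd8_ratio": 0.19,
}
_LOG_SD = {
    "cd8_density": 0.5,
    "cd133_density": 0.5,
    "tb_density": 0.5,
    "cd8_tb_index": 0.6,
    "cd8_cd133_index": 0.6,
}
_LOGIT_SD = 0.8


def default_feature_correlation() -> np.ndarray:
    """Block-sign correlation: the five CD8-favorable factors move together
    and against the three adverse factors (CD133, TB, stage), mirroring the
    reported negative CD8-vs-TB/CSC and positive TB-vs-CSC relationships."""
    signs = np.array([+1, -1, -1, +1, +1, +1, +1, -1], dtype=float)
    return 0.7 * np.eye(8) + 0.3 * np.outer(signs, signs)


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the synthetic survival cohort (times in months)."""

    n_patients: int = 160
    effect_vector: Mapping[str, float] = field(default_factory=lambda: dict(PUBLISHED_SIGN_EFFECTS))
    baseline_shape: float = 1.3
    baseline_scale: float = 25.0  # months
    censor_window: float = 60.0  # months
    feature_correlation: np.ndarray = field(default_factory=default_feature_correlation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline shape and scale must be positive")
        if self.censor_window <= 0:
            raise ValueError("censor_window must be positive")
        missing = set(FACTORS) - set(self.effect_vector)
        if missing:
            raise ValueError(f"effect_vector missing factors: {sorted(missing)}")


_TNM_CUTS = (-0.4307272992954576, 0.4307272992954576)  # standard-normal terciles


def _features_from_latent(z: np.ndarray) -> pd.DataFrame:
    cols = {}
    for j, f in enumerate(FACTORS[:5]):
        cols[f] = _FEATURE_MEDIANS[f] * np.exp(_LOG_SD[f] * z[:, j])
    for j, f in ((5, "tb_adjacent_cd8_ratio"), (6, "csc_adjacent_cd8_ratio")):
        m = _FEATURE_MEDIANS[f]
        logit = np.log(m / (1 - m)) + _LOGIT_SD * z[:, j]
        cols[f] = 1.0 / (1.0 + np.exp(-logit))
    zt = z[:, 7]
    cols["tnm_stage"] = 1 + (zt > _TNM_CUTS[0]).astype(int) + (zt > _TNM_CUTS[1]).astype(int)
    return pd.DataFrame(cols)


def design_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Invert the observable feature scales back to the generator's
    standardized covariates (the scale on which effects act): log ratios for
    densities/indices, logits for adjacency ratios, centered stage."""
    out = {}
    for f in FACTORS[:5]:
        out[f] = np.log(features[f] / _FEATURE_MEDIANS[f]) / _LOG_SD[f]
    for f in ("tb_adjacent_cd8_ratio", "csc_adjacent_cd8_ratio"):
        m = _FEATURE_MEDIANS[f]
        v = np.clip(features[f], 1e-9, 1 - 1e-9)
        out[f] = (np.log(v / (1 - v)) - np.log(m / (1 - m))) / _LOGIT_SD
    out["tnm_stage"] = features["tnm_stage"].astype(float) - 2.0
    return pd.DataFrame(out, index=features.index)


def simulate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a correlated-feature cohort and Weibull proportional-hazards
    survival times.

    Returns ``(features, records)``: features holds patient_id, the eight
    observable factors and a ``true_lp`` ground-truth column (excluded from
    any model fitting); records holds patient_id, time (months) and event.
    """
    corr = np.asarray(params.feature_correlation, dtype=float)
    if corr.shape != (8, 8):
        raise ValueError("feature_correlation must be 8x8")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"feature_correlation is not positive definite:\n{corr}"
        ) from exc

    rng = _rng_streams(params.seed)["cohort"]
    n = params.n_patients
    z = rng.standard_normal((n, 8)) @ chol.T
    feats = _features_from_latent(z)

    design = design_matrix(feats)
    beta = np.array([params.effect_vector[f] for f in FACTORS])
    lp = design.to_numpy() @ beta

    shape, scale = params.baseline_shape, params.baseline_scale
    u = rng.uniform(size=n)
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    if np.isfinite(params.censor_window):
        c = rng.uniform(0.0, params.censor_window, size=n)
        c = np.where(c == 0.0, params.censor_window, c)  # censor on (0, window]
    else:
        c = np.full(n, np.inf)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)

    feats.insert(0, "patient_id", np.arange(n))
    feats["true_lp"] = lp
    records = pd.DataFrame({"patient_id": np.arange(n), "time": time, "event": event})
    return feats, records
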