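"""Spatial statistics of CD8+ T cells around tumor buds and CSCs.

Three views of the same question — how close do cytotoxic T cells get to
their targets:

* :func:`distance_profile` counts CD8+ cells in 20-um distance classes
  (0-20, ..., 80-100 um) of their nearest bud/CSC nuclear center;
* :func:`adjacent_ratio` is the fraction of CD8+ cells within 20 um of a
  reference center, the radius of plausible direct cell-cell contact;
* :func:`cross_L` is the cross-type Ripley statistic
  L(r) = sqrt(K(r)/pi), which equals r when the query pattern is completely
  spatially random (CSR) relative to the references.

Distances are Euclidean in um; bins are half-open [lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_BIN_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
DEFAULT_ADJACENCY_RADIUS = 20.0  # um


@dataclass(frozen=True)
class DistanceProfile:
    bin_edges: tuple
    counts: tuple  # query cells per class, by nearest-reference distance
    densities: tuple  # counts / annulus area (per um^2)
    n_query: int
    n_within: int

    def __post_init__(self) -> None:
        if sum(self.counts) != self.n_within or self.n_within > self.n_query:
            raise ValueError("profile counts are inconsistent")


@dataclass(frozen=True)
class CrossLResult:
    radii: tuple
    L_values: tuple
    envelope_low: tuple | None
    envelope_high: tuple | None
    edge_correction: str


def _as_points(a, name: str) -> np.ndarray:
    pts = np.asarray(a, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"{name} must be an (n, 2) array of um coordinates")
    return pts


def nearest_reference_distance(query_points, reference_points) -> np.ndarray:
    """Distance from each query point to its nearest reference point."""
    q = _as_points(query_points, "query_points")
    r = _as_points(reference_points, "reference_points")
    if len(r) == 0:
        raise ValueError(
            "empty reference set: no buds/CSCs on this slide — distance "
            "classes are undefined rather than zero"
        )
    d, _ = cKDTree(r).query(q)
    return np.atleast_1d(d)


def distance_profile(query_points, reference_points, bin_edges=DEFAULT_BIN_EDGES) -> DistanceProfile:
    """Distance-class counts of query cells around the reference pattern."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges[0] != 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing and start at 0")
    q = _as_points(query_points, "query_points")
    d = nearest_reference_distance(q, reference_points) if len(q) else np.empty(0)
    # half-open [lo, hi): a cell exactly at an inner edge joins the upper class
    idx = np.digitize(d, edges, right=False)
    counts = tuple(int(np.sum(idx == k)) for k in range(1, len(edges)))
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    densities = tuple(c / a for c, a in zip(counts, areas))
    return DistanceProfile(
        bin_edges=tuple(edges),
        counts=counts,
        densities=densities,
        n_query=len(q),
        n_within=int(sum(counts)),
    )


def adjacent_ratio(
    query_points,
    reference_points,
    radius: float = DEFAULT_ADJACENCY_RADIUS,
    denominator: str = "all",
) -> float:
    """Fraction of query cells whose nearest reference lies within ``radius``.

    ``denominator="all"`` (default) divides by every query cell in the
    region, making the published 0.21 / 0.19 cutoffs slide-level fractions;
    ``"within100"`` restricts the denominator to cells within 100 um.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    q = _as_points(query_points, "query_points")
    if len(q) == 0:
        raise ValueError("adjacency ratio undefined for an empty query set")
    d = nearest_reference_distance(q, reference_points)
    if denominator == "all":
        denom = len(q)
    elif denominator == "within100":
        denom = int(np.sum(d <= 100.0))
        if denom == 0:
            raise ValueError("no query cells within 100 um; ratio undefined")
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return float(np.sum(d <= radius)) / denom


def cross_K(
    query_points,
    reference_points,
    radii,
    window: tuple[float, float, float, float],
    edge_correction: str = "border",
) -> np.ndarray:
    """Cross-type Ripley K from reference to query points.

    ``window`` is (xmin, xmax, ymin, ymax) in um.  Border correction keeps,
    at each radius r, only reference points at least r from the boundary
    (reduced-sample estimator); ``none`` uses all references and is unbiased
    only on guard-banded windows.
    """
    q = _as_points(query_points, "query_points")
    r_pts = _as_points(reference_points, "reference_points")
    if len(q) < 2 or len(r_pts) < 2:
        raise ValueError("cross_K needs at least 2 points in each pattern")
    xmin, xmax, ymin, ymax = window
    area = (xmax - xmin) * (ymax - ymin)
    if area <= 0:
        raise ValueError("window must have positive area")
    radii = np.asarray(radii, dtype=float)
    tree = cKDTree(q)
    lam_q = len(q) / area
    border = np.minimum.reduce(
        [r_pts[:, 0] - xmin, xmax - r_pts[:, 0], r_pts[:, 1] - ymin, ymax - r_pts[:, 1]]
    )
    K = np.empty(radii.shape)
    for i, r in enumerate(radii):
        if r == 0:
            K[i] = 0.0
            continue
        counts = tree.query_ball_point(r_pts, r, return_length=True)
        if edge_correction == "none":
            K[i] = counts.mean() / lam_q
        elif edge_correction == "border":
            valid = border >= r
            if not valid.any():
                raise ValueError(f"no reference point is {r} um from the boundary")
            K[i] = counts[valid].mean() / lam_q
        else:
            raise ValueError(f"unknown edge correction {edge_correction!r}")
    return K


def cross_L(
    query_points,
    reference_points,
    radii,
    window: tuple[float, float, float, float],
    edge_correction: str = "border",
    n_envelope: int = 0,
    envelope_quantiles: tuple[float, float] = (0.025, 0.975),
    rng: np.random.Generator | None = None,
) -> CrossLResult:
    """L(r) = sqrt(K(r)/pi); under CSR of the query pattern, L(r) = r.

    With ``n_envelope`` > 0, query points are re-randomized uniformly over
    the window ``n_envelope`` times and pointwise quantile envelopes of the
    simulated L-curves are attached.
    """
    radii = np.asarray(radii, dtype=float)
    K = cross_K(query_points, reference_points, radii, window, edge_correction)
    L = np.sqrt(K / np.pi)
    env_lo = env_hi = None
    if n_envelope > 0:
        if rng is None:
            rng = np.random.default_rng()
        xmin, xmax, ymin, ymax = window
        n_q = len(_as_points(query_points, "query_points"))
        sims = np.empty((n_envelope, radii.size))
        for s in range(n_envelope):
            qs = np.column_stack(
                [rng.uniform(xmin, xmax, n_q), rng.uniform(ymin, ymax, n_q)]
            )
            sims[s] = np.sqrt(
                cross_K(qs, reference_points, radii, window, edge_correction) / np.pi
            )
        env_lo = tuple(np.quantile(sims, envelope_quantiles[0], axis=0))
        env_hi = tuple(np.quantile(sims, envelope_quantiles[1], axis=0))
    return CrossLResult(
        radii=tuple(radii),
        L_values=tuple(L),
        envelope_low=env_lo,
        envelope_high=env_hi,
        edge_correction=edge_correction,
    )
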