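"""Tumor-budding detection: CK19+ connected components of 1-5 nuclei.

A tumor bud is a single CK19+ cell or a cluster of up to five CK19+ nuclei;
components of six or more nuclei are scored as ducts/nests.  Cells are
connected when their nuclear centroids lie within ``contact_distance``
(default 20 um, about two nuclear diameters); when label masks are available
a mask-adjacency mode connects touching nuclei instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

BUDDING_MAX_SIZE = 5  # nuclei; >= 6 is a duct/nest
DEFAULT_CONTACT_DISTANCE = 20.0  # um


@dataclass(frozen=True)
class TumorCluster:
    cluster_id: int
    member_ids: frozenset
    size: int
    is_budding: bool
    member_centroids: tuple  # ((x, y) um, ...)

    def __post_init__(self) -> None:
        if self.size != len(self.member_ids) or self.size < 1:
            raise ValueError("cluster size must equal member count and be >= 1")
        if self.is_budding != (self.size <= BUDDING_MAX_SIZE):
            raise ValueError("is_budding inconsistent with the 1-5 nucleus rule")


def cluster_tumor_cells(
    ck19_cells: pd.DataFrame,
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
    label_mask: np.ndarray | None = None,
) -> list[TumorCluster]:
    """Group CK19+ cells into connected components.

    ``ck19_cells`` must contain only CK19+ cells (columns cell_id, x, y and,
    if present, a truthy ``is_ck19``).  Components are emitted ordered by
    their smallest member id and flagged ``is_budding`` when size <= 5.
    With ``label_mask`` supplied, cells are connected when their nuclear
    masks touch (8-connectivity) instead of by centroid distance.
    """
    if contact_distance <= 0:
        raise ValueError("contact_distance must be positive")
    if "is_ck19" in ck19_cells.columns and not ck19_cells["is_ck19"].all():
        bad = ck19_cells.loc[~ck19_cells["is_ck19"], "cell_id"].iloc[0]
        raise ValueError(f"non-CK19 cell {bad} passed to cluster_tumor_cells")
    n = len(ck19_cells)
    if n == 0:
        return []

    ids = ck19_cells["cell_id"].to_numpy()
    pts = ck19_cells[["x", "y"]].to_numpy(dtype=float)

    if label_mask is not None:
        pairs = _touching_pairs(label_mask, ids)
    else:
        pairs = list(cKDTree(pts).query_pairs(contact_distance))
    if pairs:
        rows, cols = np.array(pairs, dtype=int).T
    else:
        rows = cols = np.empty(0, dtype=int)
    graph = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    n_comp, assign = connected_components(graph, directed=False)

    clusters = []
    for comp in range(n_comp):
        idx = np.flatnonzero(assign == comp)
        members = frozenset(ids[idx].tolist())
        clusters.append(
            (
                min(members),
                TumorCluster(
                    cluster_id=-1,
                    member_ids=members,
                    size=len(members),
                    is_budding=len(members) <= BUDDING_MAX_SIZE,
                    member_centroids=tuple(map(tuple, pts[idx])),
                ),
            )
        )
    clusters.sort(key=lambda t: t[0])
    return [
        TumorCluster(
            cluster_id=k,
            member_ids=c.member_ids,
            size=c.size,
            is_budding=c.is_budding,
            member_centroids=c.member_centroids,
        )
        for k, (_, c) in enumerate(clusters)
    ]


def _touching_pairs(label_mask: np.ndarray, ids: np.ndarray) -> list[tuple[int, int]]:
    """Index pairs of nuclei whose masks touch under 8-connectivity."""
    pos = {int(cid): i for i, cid in enumerate(ids)}
    pairs = set()
    lab = np.asarray(label_mask)
    for shift in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = lab[max(0, -shift[0]) : lab.shape[0] - max(0, shift[0]),
                max(0, -shift[1]) : lab.shape[1] - max(0, shift[1])]
        b = lab[max(0, shift[0]) :, max(0, shift[1]) :] if min(shift) >= 0 else None
        b = lab[
            max(0, shift[0]) : lab.shape[0] + min(0, shift[0]),
            max(0, shift[1]) : lab.shape[1] + min(0, shift[1]),
        ]
        m = (a > 0) & (b > 0) & (a != b)
        for u, v in zip(a[m].ravel(), b[m].ravel()):
            if int(u) in pos and int(v) in pos:
                pairs.add((min(pos[int(u)], pos[int(v)]), max(pos[int(u)], pos[int(v)])))
    return sorted(pairs)


def budding_summary(clusters: list[TumorCluster], tissue_area_mm2: float) -> tuple[int, float, int]:
    """(bud count, bud density per mm^2, nest count) over the analyzed region."""
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue_area must be positive (mm^2)")
    tb = sum(1 for c in clusters if c.is_budding)
    nests = len(clusters) - tb
    return tb, tb / tissue_area_mm2, nests


def clusters_to_frame(clusters: list[TumorCluster]) -> pd.DataFrame:
    """Tabular cluster export (one row per component)."""
    rows = [
        {
            "cluster_id": c.cluster_id,
            "size": c.size,
            "is_budding": c.is_budding,
            "centroid_x": float(np.mean([p[0] for p in c.member_centroids])),
            "centroid_y": float(np.mean([p[1] for p in c.member_centroids])),
        }
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "size", "is_budding", "centroid_x", "centroid_y"])
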