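"""Marker positivity calls from per-compartment intensities.

A cell is called positive for a marker when any compartment's mean intensity
reaches that compartment's threshold (OR rule; the membrane and cytoplasm
thresholds are an order of magnitude below the nuclear ones, so each alone is
treated as sufficient evidence).  ``rule`` switches to AND or nucleus-only
behavior.  Comparison is inclusive: a value exactly at the threshold is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .synthgen import COMPARTMENTS


@dataclass(frozen=True)
class MarkerThresholds:
    channel: str
    nucleus: float
    cytoplasm: float
    membrane: float

    def __post_init__(self) -> None:
        for v in (self.nucleus, self.cytoplasm, self.membrane):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")

    def threshold(self, compartment: str) -> float:
        return getattr(self, compartment)


@dataclass(frozen=True)
class MarkerPanel:
    """Marker -> channel/threshold mapping; defaults are the published panel."""

    markers: Mapping[str, MarkerThresholds] = field(
        default_factory=lambda: {
            "cd8": MarkerThresholds("opal520", 0.344, 0.025, 0.025),
            "cd133": MarkerThresholds("opal570", 0.524, 0.045, 0.045),
            "ck19": MarkerThresholds("opal690", 0.624, 0.025, 0.025),
        }
    )

    def __post_init__(self) -> None:
        channels = [m.channel for m in self.markers.values()]
        if len(set(channels)) != len(channels):
            raise ValueError("marker channels must be unique")


DEFAULT_PANEL = MarkerPanel()


def classify_marker(cell: Mapping[str, float], thresholds: MarkerThresholds, rule: str = "or") -> bool:
    """Positivity call for a single cell and marker.

    ``cell`` is any mapping exposing ``{channel}_{compartment}`` intensities
    (a DataFrame row works).  Missing or non-finite compartment values raise,
    never silently return negative.
    """
    hits = []
    for comp in COMPARTMENTS:
        key = f"{thresholds.channel}_{comp}"
        if key not in cell or cell[key] is None or not np.isfinite(cell[key]):
            raise ValueError(f"missing intensity for compartment {key!r}")
        hits.append(cell[key] >= thresholds.threshold(comp))
    if rule == "or":
        return any(hits)
    if rule == "and":
        return all(hits)
    if rule == "nucleus":
        return hits[0]
    raise ValueError(f"unknown combination rule {rule!r}")


def phenotype_cells(
    cells: pd.DataFrame,
    panel: MarkerPanel = DEFAULT_PANEL,
    rule: str = "or",
    ck19_priority: bool = False,
) -> pd.DataFrame:
    """Vectorized marker classification; appends one boolean column per marker.

    Markers are called independently, so a cell can carry several flags; with
    ``ck19_priority`` a CK19+ call suppresses the CD8 flag (exclusivity mode
    for users who want disjoint tallies).  Row order is preserved.
    """
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell id {dup}")
    out = cells.copy()
    for name, thr in panel.markers.items():
        comp_hits = []
        for comp in COMPARTMENTS:
            key = f"{thr.channel}_{comp}"
            if key not in cells.columns:
                raise ValueError(f"cell table lacks measured column {key!r}")
            col = cells[key].to_numpy(dtype=float)
            if not np.all(np.isfinite(col)):
                raise ValueError(f"non-finite intensity in column {key!r}")
            comp_hits.append(col >= thr.threshold(comp))
        stacked = np.vstack(comp_hits)
        if rule == "or":
            flags = stacked.any(axis=0)
        elif rule == "and":
            flags = stacked.all(axis=0)
        elif rule == "nucleus":
            flags = stacked[0]
        else:
            raise ValueError(f"unknown combination rule {rule!r}")
        out[f"is_{name}"] = flags
    if ck19_priority and {"is_ck19", "is_cd8"} <= set(out.columns):
        out.loc[out["is_ck19"], "is_cd8"] = False
    return out
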