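"""Simulate one multiplexed-IF field with known ground truth.

Generates the default study conditions (~310 CD8+ cells/mm^2, ~330 buds/mm^2,
CSCs enriched in buds) on a 1 mm^2 window, writes a truth summary to
results/, and the full cell/truth tables plus the 4-channel OME-TIFF raster
to scratch/ (they are regenerated deterministically from the seed).
"""

import json
from pathlib import Path

from immunobud.synthgen import (
    TissueSimParams,
    simulate_cell_table,
    render_multiplex,
    write_ome_tiff,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    params = TissueSimParams(seed=1)
    table, truth = simulate_cell_table(params)
    image = render_multiplex(table, truth.true_cells, params)

    table.to_csv(SCRATCH / "slide_cells.csv", index=False)
    truth.true_cells.to_csv(SCRATCH / "slide_truth_cells.csv", index=False)
    (RESULTS / "slide_truth.json").write_text(
        json.dumps(
            {
                "true_patient_features": truth.true_patient_features,
                "n_true_clusters": len(truth.true_clusters),
                "n_true_buds": sum(1 for _, b in truth.true_clusters if b),
            },
            indent=2,
        )
    )
    write_ome_tiff(SCRATCH / "slide.ome.tif", image, params.pixel_size)

    print(f"simulated {len(table)} cells on {params.area_mm2:.2f} mm^2")
    print(
        f"truth: {int(truth.true_cells.is_cd8.sum())} CD8+, "
        f"{int(truth.true_cells.is_cd133.sum())} CD133+, "
        f"{int(truth.true_cells.is_ck19.sum())} CK19+ cells, "
        f"{sum(1 for _, b in truth.true_clusters if b)} buds"
    )
    print(f"wrote {SCRATCH/'slide_cells.csv'} and {SCRATCH/'slide.ome.tif'}")


if __name__ == "__main__":
    main()
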