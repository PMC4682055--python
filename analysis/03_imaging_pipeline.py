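#!/usr/bin/env python
"""Imaging quantification demo on rendered ground-truth tissue.

Renders a sheared synthetic epithelium into a label mask plus an intensity
channel whose boundary brightness follows 1 + b cos 2(theta - 45 deg) (the
polarized junctional myosin pattern), then runs the extraction pipeline on
the images alone and compares the recovered statistics with the generator's
ground truth: region adjacency, per-boundary angles, left/right aggregate
intensity, and the planar-cell-chirality fraction.

Writes: results/imaging_per_boundary.csv, results/imaging_summary.csv,
        results/synthetic_labels.tif, results/synthetic_intensity.tif
"""

from pathlib import Path

import numpy as np
import pandas as pd

from chiralsheet.imaging import boundary_intensity, extract_boundaries
from chiralsheet.quantify import boundary_angles, pcc_fraction
from chiralsheet.synthetic import (
    CANONICAL_FRAME,
    RenderSpec,
    SyntheticMeshSpec,
    make_chiral_mesh,
    render_labeled_tissue,
    write_rendered_tiffs,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    mesh, expected_rf = make_chiral_mesh(
        SyntheticMeshSpec(rows=6, cols=6, shear_bias=0.3, jitter=0.12, seed=4)
    )
    spec = RenderSpec(pixels_per_unit=30, intensity_bias=0.5, noise_sd=2.0,
                      background=100.0, seed=4)
    labels, intensity, truth = render_labeled_tissue(mesh, spec)
    write_rendered_tiffs(labels, intensity,
                         RESULTS / "synthetic_labels.tif",
                         RESULTS / "synthetic_intensity.tif")

    seg = extract_boundaries(labels)
    res = boundary_intensity(seg, intensity, CANONICAL_FRAME)
    res.per_boundary.to_csv(RESULTS / "imaging_per_boundary.csv", index=False)

    recovered_rf = pcc_fraction(boundary_angles(seg, CANONICAL_FRAME)).right_fraction
    n_pairs_true = len(truth)
    n_pairs_found = sum(1 for b in seg.boundaries)
    summary = pd.DataFrame([{
        "boundaries_true": n_pairs_true,
        "boundaries_recovered": n_pairs_found,
        "left_mean_intensity_ratio": res.left_mean,
        "right_mean_intensity_ratio": res.right_mean,
        "peak_bin_centre_deg": float(
            res.bin_edges[int(np.nanargmax(res.binned_mean_ratio))] + 15.0
        ),
        "pcc_right_fraction_truth": expected_rf,
        "pcc_right_fraction_recovered": recovered_rf,
    }])
    summary.to_csv(RESULTS / "imaging_summary.csv", index=False)

    print(f"boundaries: {n_pairs_found} recovered / {n_pairs_true} interior junctions")
    print(f"normalised intensity: right {res.right_mean:.3f} vs left {res.left_mean:.3f}"
          f" (peak bin centred at {summary.peak_bin_centre_deg[0]:+.0f} deg)")
    print(f"PCC right fraction: recovered {recovered_rf:.3f} vs truth {expected_rf:.3f}")
    print(f"wrote {RESULTS / 'imaging_summary.csv'}")


if __name__ == "__main__":
    main()
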