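#!/usr/bin/env python
"""Fixed-cell N/C ratio quantification on synthetic two-channel images.

Generates an image of cells with prescribed BMAL1 and CLOCK N/C ratios,
runs the segmentation / 3-px-ring / ratio pipeline, and compares measured
against prescribed ratios.  With noise off the recovery is exact; the run
below adds mild noise to show realistic behavior.
"""

from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from clocksync.imaging import cytoplasm_ring, measure_nc, nc_summary, segment_nuclei
from clocksync.synth import ImagingScenario, gen_fixed_cell_image

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    scenario = ImagingScenario(
        n_cells=24, shape=(800, 800),
        nc_ratio={"bmal1": (0.5, 3.0), "clock": (0.5, 3.0)},
        noise_sd=2.0, seed=14,
    )
    img, truth = gen_fixed_cell_image(scenario)
    labels = segment_nuclei(img)
    rings = cytoplasm_ring(labels, dilation_px=3)
    table = measure_nc(img, labels, rings, ["bmal1", "clock"])
    table.to_csv(OUT / "nc_measurements.csv", index=False)
    truth.to_csv(OUT / "nc_truth.csv", index=False)

    ids = np.unique(labels[labels > 0])
    cents = np.asarray(ndi.center_of_mass(np.ones_like(labels), labels, ids))
    tc = truth[["row", "col"]].to_numpy()
    errs = []
    for cid, cent in zip(ids, cents):
        k = int(np.argmin(np.linalg.norm(tc - cent, axis=1)))
        for ch in ("bmal1", "clock"):
            meas = table[(table.cell_id == cid) & (table.channel == ch)]
            errs.append(abs(meas["nc_ratio"].iloc[0]
                            - truth[f"true_nc_ratio_{ch}"].iloc[k]))
    print(f"{labels.max()} cells segmented of {scenario.n_cells}; "
          f"median |ratio error| {np.median(errs):.4f} (noise sd "
          f"{scenario.noise_sd})")
    summ = nc_summary(table, "bmal1", "clock")
    print(f"BMAL1 vs CLOCK ratio correlation r = {summ['r']:+.3f} "
          f"over {summ['n_cells']} cells (independent by construction)")
    print(f"wrote {OUT / 'nc_measurements.csv'}")


if __name__ == "__main__":
    main()
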