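#!/usr/bin/env python
"""Quantify per-cell mRNA signal in a synthetic thick-tissue mFISH volume.

Renders a 3-channel volume (PVALB / SST / VIP probes) containing ten
segmented cells — half expressing in the PVALB channel, half in the SST
channel — plus lipofuscin granules bright in every channel.  Runs the
background-threshold → lipofuscin-mask → per-cell quantification pipeline
and checks expression is assigned to the correct channel and does not vary
with imaging depth.

Writes results/mfish_expression.csv and results/mfish_depth_profile.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from stpkit import (
    Blob,
    SyntheticVolumeSpec,
    background_threshold,
    depth_profile,
    lipofuscin_mask,
    quantify_cell,
    simulate_mfish_volume,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 33
CHANNELS = ("PVALB-546", "SST-647", "VIP-488")


def main() -> None:
    rng = np.random.default_rng(SEED)
    shape = (20, 128, 128)
    cells, spots, cell_channel = [], [], []
    for i in range(10):
        center = (rng.uniform(4, 16), rng.uniform(12, 116), rng.uniform(12, 116))
        mask = np.zeros(shape, bool)
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        mask |= ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                 + (xx - center[2]) ** 2) <= 5.0**2
        cells.append(mask)
        ch = 0 if i % 2 == 0 else 1  # PVALB vs SST expressors
        cell_channel.append(ch)
        spots.append(Blob(center, 4.0, 220.0, channel=ch))
    lipo = [Blob((rng.uniform(3, 17), rng.uniform(8, 120), rng.uniform(8, 120)),
                 rng.uniform(1.5, 3.0), 500.0) for _ in range(8)]
    spec = SyntheticVolumeSpec(shape=shape, n_channels=3,
                               lipofuscin_blobs=lipo, spots=spots,
                               cell_masks=cells)
    stack, truth = simulate_mfish_volume(spec, seed=SEED)

    non_cell = ~np.any(cells, axis=0)
    models = [background_threshold(stack[c], non_cell) for c in range(3)]
    thr = np.array([m.threshold for m in models])
    print("background thresholds:",
          ", ".join(f"{n} = {t:.1f}" for n, t in zip(CHANNELS, thr)))

    mask = lipofuscin_mask(stack, thr)
    print(f"lipofuscin mask: {mask.sum()} voxels "
          f"({100 * mask.sum() / mask.size:.2f}% of volume)")

    expr = [quantify_cell(stack, m, mask, thr, cell_id=f"cell{i:02d}")
            for i, m in enumerate(cells)]
    rows = []
    correct = 0
    for ce, ch in zip(expr, cell_channel):
        row = dict(cell_id=ce.cell_id, volume=ce.cell_volume,
                   masked_voxels=ce.masked_voxels, true_channel=CHANNELS[ch])
        row.update({f"expr_{n}": e for n, e in zip(CHANNELS, ce.expression)})
        rows.append(row)
        correct += int(np.argmax(ce.expression) == ch)
    pd.DataFrame(rows).to_csv(RESULTS / "mfish_expression.csv", index=False)
    print(f"dominant channel matches the expressed probe in {correct}/10 cells")

    df, reg = depth_profile(expr, channel=0)
    df.to_csv(RESULTS / "mfish_depth_profile.csv", index=False)
    if reg is not None:
        print(f"expression vs depth: slope {reg.slope:+.3f}/plane, "
              f"p = {reg.p_value:.3f}"
              + (" — no depth attenuation" if reg.p_value > 0.05 else ""))


if __name__ == "__main__":
    sys.exit(main())
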