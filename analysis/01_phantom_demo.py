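#!/usr/bin/env python
"""Generate one synthetic CE-CMR stack and verify exact scar recovery.

Builds the default phantom (annular myocardium, 90-degree subendocardial
scar wedge with core plateau and border rim, bright blood pool), writes the
stack/contours/truth to results/phantom_demo/, runs the FWHM pipeline on
the noiseless image, and reports recovered vs true zone percentages — they
must agree exactly because zone labels are decided at voxel centers.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from scarchar.io_formats import ShortAxisStack, write_contours, write_stack
from scarchar.phantom import PhantomSpec, generate_phantom
from scarchar.scar import analyze_stack

OUT = Path(__file__).resolve().parents[1] / "results" / "phantom_demo"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec(seed=42)
    stack, truth = generate_phantom(spec)

    write_stack(stack, OUT / "stack.nii.gz")
    write_contours(truth.contours, OUT / "contours.json")
    labels = (truth.myocardium_mask.astype(np.uint8)
              + truth.border_mask.astype(np.uint8)
              + 2 * truth.core_mask.astype(np.uint8))
    write_stack(
        ShortAxisStack(labels, stack.pixel_spacing_mm,
                       stack.slice_thickness_mm, stack.slice_gap_mm),
        OUT / "truth_labels.nii.gz",
    )
    (OUT / "spec.json").write_text(json.dumps(dataclasses.asdict(spec), indent=1))

    smap, fr, myo = analyze_stack(stack, truth.contours)
    rows = [{
        "quantity": name, "truth": t, "recovered": r,
    } for name, t, r in [
        ("core_pct", truth.true_core_pct, fr.core_pct),
        ("peri_pct", truth.true_peri_pct, fr.peri_pct),
        ("total_pct", truth.true_total_pct, fr.total_pct),
    ]]
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "recovery.csv", index=False)

    print(f"phantom: {spec.n_slices} slices, {spec.grid_size}^2 px, "
          f"myocardium {int(myo.sum())} voxels, max SI {smap.max_si:.1f} "
          f"(thresholds {smap.peri_si:.1f}/{smap.core_si:.1f})")
    print(table.to_string(index=False))
    exact = all(abs(r['truth'] - r['recovered']) == 0 for r in rows)
    print(f"noiseless recovery exact: {exact}")


if __name__ == "__main__":
    main()
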