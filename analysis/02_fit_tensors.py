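#!/usr/bin/env python
"""Fit DTI and multi-tensor models to one example subject.

Reads the first control subject written by 01_simulate_phantom.py,
fits both representations over the ribbon, and reports how many
compartments the model selection kept per voxel — on this phantom
(crossing radial + tangential populations everywhere) two tensors
should dominate.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cortexdiff.io_core import ImageVolume, read_scheme, read_volume, write_volume
from cortexdiff.pipeline import fit_slice, fits_to_stack

ROOT = Path(__file__).resolve().parents[1] / "results"
STUDY = ROOT / "study"


def main() -> None:
    labels = read_volume(STUDY / "mask.nii.gz")
    scheme = read_scheme(STUDY / "dwi.bval", STUDY / "dwi.bvec")
    dwi = read_volume(STUDY / "group_a" / "sub-01_dwi.nii.gz")
    fa_map, md_map, fits = fit_slice(dwi.data, labels, scheme)
    out = ROOT / "fits"
    out.mkdir(parents=True, exist_ok=True)
    write_volume(fa_map, out / "fa.nii.gz")
    write_volume(md_map, out / "md.nii.gz")
    stack, nsel = fits_to_stack(fits)
    write_volume(ImageVolume(stack.astype(np.float32), labels.voxel_size,
                             labels.affine), out / "mt.nii.gz")
    write_volume(ImageVolume(nsel, labels.voxel_size, labels.affine),
                 out / "nsel.nii.gz")
    ribbon = np.asarray(labels.data) > 0
    counts = np.bincount(nsel[ribbon], minlength=4)[1:]
    pd.DataFrame({"n_tensors": [1, 2, 3], "voxels": counts}).to_csv(
        out / "n_selected_counts.csv", index=False
    )
    print(f"DTI FA over ribbon: median {np.nanmedian(fa_map.data):.3f} "
          "(single tensor blurs the crossing, hence well below the "
          "generative FA of either population)")
    print(f"compartments kept per voxel: 1->{counts[0]}, 2->{counts[1]}, "
          f"3->{counts[2]}")


if __name__ == "__main__":
    main()
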