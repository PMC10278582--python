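#!/usr/bin/env python
"""Structure-tensor quantification of synthetic myelin-like texture.

Emulates the histology arm of the pipeline: two synthetic micrographs
— one with coherent fiber texture, one with the same texture
orientation-scrambled (the disorganized-myeloarchitecture analogue) —
are quantified with a 15 um Gaussian-window structure tensor, and
their mean local coherency is compared.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from cortexdiff.histostruct import mean_coherency, structure_tensor

ROOT = Path(__file__).resolve().parents[1] / "results"
PIXEL_UM = 1.5  # emulated micrograph pitch
SIGMA_UM = 15.0


def fiber_texture(rng, shape=(256, 256), coherent=True):
    """Band-filtered noise: oriented (coherent) or isotropic (scrambled)."""
    img = rng.normal(size=shape)
    if coherent:
        # smooth strongly along one axis -> fiber-like streaks
        return ndimage.gaussian_filter(img, sigma=(8.0, 1.0))
    return ndimage.gaussian_filter(img, sigma=(2.9, 2.9))


def main() -> None:
    rng = np.random.default_rng(0)
    out = ROOT / "histo"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, coherent in (("organized", True), ("disorganized", False)):
        img = fiber_texture(rng, coherent=coherent)
        maps = structure_tensor(img, SIGMA_UM, PIXEL_UM)
        rows.append(dict(
            texture=label,
            mean_coherency=round(mean_coherency(maps), 4),
            mean_energy=round(float(maps.energy.mean()), 4),
        ))
    df = pd.DataFrame(rows)
    df.to_csv(out / "coherency_summary.csv", index=False)
    print(df.to_string(index=False))
    print("\ncoherent fiber texture shows markedly higher local coherency "
          "— the contrast the histology analysis uses to detect "
          "disorganized myeloarchitecture.")


if __name__ == "__main__":
    main()
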