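"""3D foci counting and colocalization on synthetic nuclei.

Generates nuclei with planted foci, segments them from the DAPI-like
channel, counts foci with the 10-voxel minimum size filter, and
evaluates colocalization (Pearson/Spearman/Manders) of a partially
co-located second channel against its right-angle rotation null.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import numpy as np
import pandas as pd

from rdpa import (
    VolumePair,
    coloc_coefficients,
    count_foci,
    region_mean_intensity,
    rotation_null,
    segment_nuclei,
)
from rdpa.simulate import ImageConfig, generate_image_stack

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for cell in range(8):
        planted = int(rng.integers(2, 15))
        nucleus = generate_image_stack(
            ImageConfig(n_foci=planted, coloc_fraction=0.5),
            seed=int(rng.integers(2**31)),
        )
        labels = segment_nuclei(nucleus.dapi, sigma=2.0)
        mask = labels == 1
        count, _ = count_foci(nucleus.target, mask)
        pair = VolumePair(nucleus.target, nucleus.second, mask)
        real = coloc_coefficients(pair, manders_thresholds="otsu")
        null = rotation_null(pair, 90)
        rows.append(
            {
                "cell": cell,
                "planted_foci": planted,
                "counted_foci": count,
                "pearson": real.pearson,
                "spearman": real.spearman,
                "manders_m1": real.manders_m1,
                "manders_m2": real.manders_m2,
                "null_pearson": null.pearson,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "foci_quantification.tsv", sep="\t", index=False)
    exact = (table.planted_foci == table.counted_foci).mean()
    print("per-cell foci counts and colocalization:")
    print(table.round(3).to_string(index=False))
    print(
        f"\nexact count recovery: {100 * exact:.0f}% of cells"
        f"\nmean Pearson {table.pearson.mean():.3f} vs rotation null "
        f"{table.null_pearson.mean():.3f} (50% of foci co-located by design)"
    )

    # region intensity quantification on one nucleus
    nucleus = generate_image_stack(ImageConfig(n_foci=6), seed=SEED)
    _, label_vol = count_foci(nucleus.target, nucleus.mask)
    speckles = label_vol > 0
    nucleoplasm = nucleus.mask & ~speckles
    reference = float(nucleus.target[nucleoplasm].mean())
    out = region_mean_intensity(
        nucleus.target, {"Sp": speckles, "Np": nucleoplasm}, reference
    )
    pd.DataFrame([out]).to_csv(ROOT / "region_intensity.tsv", sep="\t", index=False)
    print(
        f"\nregion intensities normalized to nucleoplasm: "
        f"Sp {out['Sp']:.2f}, Np {out['Np']:.2f}"
    )


if __name__ == "__main__":
    main()
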