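"""Count phospho-ATM foci per nucleus and stratify by baseline hypoxia.

Generates a phantom with 80 nuclei, half CCI-103F positive, foci counts drawn
Poisson with a higher mean in the treated (reoxygenated) stratum, then
segments nuclei, counts foci by LoG blob detection, and reports the percent
of cells with >5 foci per stratum.
"""

from reoxquant import (
    FociPhantomParams,
    aggregate_foci,
    count_foci,
    generate_foci_phantom,
    score_cells,
    segment_nuclei,
)
from reoxquant.phantoms import FociCountDistribution

params = FociPhantomParams(
    n_nuclei=80,
    image_height_px=340,
    image_width_px=340,
    fraction_cci_positive=0.5,
    foci_count_distribution=FociCountDistribution(
        mean=4.0, mean_cci_positive=6.0, mean_cci_negative=3.0
    ),
    seed=5,
)
image, truth = generate_foci_phantom(params)

labels = segment_nuclei(image.channels["nuclei"])
counts = [
    count_foci(image.channels["phospho_atm"], labels == lab)
    for lab in range(1, labels.max() + 1)
]
cells = score_cells(labels, counts, truth.true_cci_mask, region_id=1, field_id=1)
report = aggregate_foci(cells, min_cells_per_field=50, min_fields_per_region=1)

print(f"segmented nuclei : {labels.max()} (ground truth {params.n_nuclei})")
for status, row in report.per_stratum.items():
    print(
        f"CCI-103F {status:8s}: n={row['n_cells']:.0f}  any foci {row['pct_any_foci']:.1f}%"
        f"  >5 foci {row['pct_high_foci']:.1f}%"
    )
print(
    "\nCells hypoxic at baseline (CCI-positive) carry the higher foci burden"
    "\nhere by construction, mimicking reoxygenation-induced oxidative stress."
)
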