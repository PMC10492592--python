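"""Differentiating sound from demineralized enamel with ROI t-scores.

Generates a synthetic set of co-linear / cross-circular image pairs for seven
teeth (two spots per side, 28 data points) where the acidified side's
illumination core is 40% dimmer, runs the five-metric battery, and builds the
(co-linear, cross-circular) polarimetric map.
"""

import numpy as np

from polarpath import (
    RegionSpec,
    SyntheticToothConfig,
    generate_synthetic_tooth_set,
    polarimetric_map,
    roi_metric_battery,
)
from polarpath.toothstats import METRIC_NAMES, battery_summary

config = SyntheticToothConfig(seed=2023)
image_set = generate_synthetic_tooth_set(config)
print(
    f"{config.n_samples} samples x 2 sides x {config.spots_per_side} spots "
    f"= {len(image_set.spots())} data points per channel"
)

families = roi_metric_battery(image_set)
summary = battery_summary(families)
print(summary[["metric", "t_score", "p_value"]].to_string(index=False))
print(
    "  -> interior-region metrics separate the classes more strongly than\n"
    "     full-image sums (the demineralization contrast concentrates near\n"
    "     the illumination spot); pooling both interior metrics doubles the\n"
    "     sample size and gives the largest t"
)

pmap = polarimetric_map(image_set, region=RegionSpec("disc", diameter_mm=3.0))
print(
    f"polarimetric-map separability (best threshold on the principal axis): "
    f"{100 * pmap.separability_accuracy:.0f}% of 28 spots"
)
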