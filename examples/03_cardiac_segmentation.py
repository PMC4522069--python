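"""Cardiac short-axis pipeline: simulate, fit, segment, flag.

Generates a midventricular slice whose segment 3 carries a 30% pixel-wise
T2 spread, fits the T2 map, partitions the myocardium into the 6 AHA
sectors, and applies the homogeneity rule (pixel SD > 20% of segment
mean).
"""

import numpy as np

import t2mapping as t2
from t2mapping.segmentation import aha_segments, annulus_mask, segment_stats
from t2mapping.stats import flag_inhomogeneous, inhomogeneity_proportion

schedule = t2.build_schedule("MESE")
geo = t2.CardiacGeometry(per_segment_sd_inflation=[0, 0, 0.3, 0, 0, 0])
stack, truth, contours = t2.make_cardiac_sax(geo, schedule, sigma=0.5, seed=21)

mask = annulus_mask(contours, stack.shape)
print(f"myocardial annulus: {mask.sum()} pixels")

maps = t2.fit_map(stack, mask, schedule, method="MLE", sigma=0.5)
labels = aha_segments(mask, geo.center, geo.rv_insertion_angle, geo.slice_level)
stats = segment_stats(maps.t2_map, labels)
flagged = flag_inhomogeneous(stats[stats.segment_id != 0])
print(flagged[["segment_id", "n_pixels", "mean_t2_ms", "sd_t2_ms", "inhomogeneous"]]
      .to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print(f"\nglobal myocardial T2: "
      f"{stats.loc[stats.segment_id == 0, 'mean_t2_ms'].item():.2f} ms "
      f"(generator truth 53.8 ms)")
print(f"inhomogeneous proportion: {inhomogeneity_proportion(flagged):.3f} "
      f"(segment 3 was generated with a 30% pixel T2 spread)")
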