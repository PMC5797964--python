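"""The aMTOC sorting statistic: scattered vs pole-sorted scenes.

During meiosis I, aMTOCs relocate from the spindle body to its poles. The
per-oocyte statistic is the sample SD of the length-normalized distances
of all aMTOCs to their nearest pole: high while aMTOCs are scattered, low
once they are sorted.
"""

import numpy as np

import oospindle as oo
from oospindle import morphometry


def truth_sorting_sd(truth):
    a, b = np.asarray(truth.spindle_pole_a), np.asarray(truth.spindle_pole_b)
    records = []
    for c in truth.mtoc_centers:
        d = min(np.linalg.norm(np.asarray(c) - a), np.linalg.norm(np.asarray(c) - b))
        p = d / truth.spindle_length
        records.append(morphometry.MTOCRecord(c, 1.0, d, p, 0.0))
    return oo.sorting_sd(records)


for label, dist in (("scattered (pre-sorting)", "scattered"),
                    ("pole-sorted", "sorted")):
    sds = []
    for seed in range(10):
        truth = oo.generate_scene(
            oo.SceneParams(n_mtocs=20, axial_distribution=dist), seed=seed
        )
        sds.append(truth_sorting_sd(truth))
    print(f"{label:25s} sorting SD = {np.mean(sds):.3f} ± {np.std(sds):.3f} "
          f"(10 oocytes)")
# Scattered oocytes sit near the SD of a uniform [0, 0.5] sample (~0.14);
# sorted oocytes drop by an order of magnitude, mirroring how the statistic
# separates early and late meiosis-I time points.
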