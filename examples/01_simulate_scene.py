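"""Generate one synthetic oocyte scene and inspect its ground truth.

The generator draws a bipolar spindle inside an oocyte and scatters aMTOC
blobs along the pole axis, then renders bright-field, microtubule, and
aMTOC channels with PSF blur and camera noise. Everything is reproducible
from the seed.
"""

import numpy as np

import oospindle as oo

params = oo.SceneParams(n_mtocs=8, axial_distribution="scattered")
truth = oo.generate_scene(params, seed=7)
bright_field, microtubule, mtoc = oo.render_volumes(truth)

print(f"volume shape (z,y,x): {truth.shape}, voxel size {truth.voxel_size} µm")
print(f"spindle poles: {np.round(truth.spindle_pole_a, 2)} "
      f"to {np.round(truth.spindle_pole_b, 2)} µm")
print(f"true spindle length: {truth.spindle_length:.1f} µm")
print(f"aMTOCs placed: {len(truth.mtoc_centers)}; axial fractions "
      f"{np.round(truth.mtoc_axial_fractions, 3)}")
print(f"microtubule channel intensity range: "
      f"{microtubule.data.min():.0f}-{microtubule.data.max():.0f} a.u.")
# The axial fractions are each blob's intended distance to its nearest pole
# as a fraction of spindle length: 0 = at a pole, 0.5 = spindle equator.
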