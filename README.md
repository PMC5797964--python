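# oospindle

3D quantification of meiotic spindle morphogenesis in mouse oocytes.

Oocytes build their meiosis-I spindle without centrioles: dozens of
acentriolar microtubule-organizing centres (aMTOCs) are progressively
**sorted** toward the two spindle poles and **clustered** into compact pole
structures while the microtubule mass transitions from a ball to a bipolar
spindle. `oospindle` is a tested, reusable implementation of the image
analysis this biology requires, for cell biologists quantifying
three-channel spinning-disk z-stacks (bright-field, a microtubule reporter
such as GFP-EB3 or SiR-Tubulin, and an aMTOC marker such as mCherry-Plk4):

- **Segmentation** — oocyte boundary (variance filter + triangle
  threshold), spindle body (3D Gaussian + Kapur maximum-entropy
  threshold), aMTOC spots (difference of Gaussians + maximum-entropy
  threshold), all on 256-bin histograms with 26-connected 3D labeling.
- **Morphometry** — spindle poles as the extremities of the 3D Feret
  diameter, so spindle length `L = |p_a − p_b|`; central and pole widths
  from thin slabs along the pole axis; per-aMTOC minimum pole distance
  `d_i`, normalized position `x_i = d_i / L`, and signed border distance
  to the spindle surface.
- **Sorting/clustering statistics** — per oocyte, the sample SD of the
  normalized positions, `SD(x_1..x_n)` (high when aMTOCs are scattered
  along the hemi-spindle, low once they sit at the poles), plus the aMTOC
  count and total volume.
- **Photometry & FRAP** — background-subtracted totals inside a fixed
  circle with group expression ratios, and single-exponential recovery
  fitting `F(t) = A(1 − e^{−kt})`, `t_half = ln 2 / k`, on traces
  normalized to pre-bleach = 1 / first post-bleach = 0.
- **Synthetic scenes** — a generator that renders oocyte stacks with
  known ground truth (poles, aMTOC positions, PSF, Poisson + read noise),
  so every stage is testable without microscope data.

## Worked example

```python
import oospindle as oo

params = oo.SceneParams(n_mtocs=6, min_mtoc_separation=5.0, gaussian_noise_sd=10.0)
truth = oo.generate_scene(params, seed=3)
bf, mt, spot = oo.render_volumes(truth)
result = oo.analyze_channels(
    {"bright_field": bf, "microtubule": mt, "mtoc": spot}, oo.PipelineConfig()
)
print(result.summary)
```

prints (values from `examples/02_segment_and_measure.py`):

```
true spindle length 32.0 µm, measured 32.0 µm
central width 19.3 µm, pole width 8.1 µm
aMTOCs: 6 detected of 6 placed, total volume 170.9 µm³
  aMTOC 0: 35.75 µm³, normalized position 0.189, border distance -3.83 µm
  ...
```

i.e. the chain recovered the generated 32 µm pole-to-pole length, found
all six aMTOC foci, and placed each on the hemi-spindle axis (0 = at a
pole, 0.5 = equator); negative border distances mean the foci lie inside
the spindle body. The `examples/` directory has one short script per
capability (scene simulation, segmentation + morphometry, the sorting
statistic, FRAP fitting, expression ratios).

A thin CLI wraps the same library for batch work:

```bash
oospindle simulate --n-scenes 3 --seed 0 --out scenes/
oospindle analyze scenes/ --out results/ --qc
oospindle frap trace.csv
oospindle report results/
```

`analyze` writes `mtocs.csv` (one row per aMTOC), `oocytes.csv` (one row
per stack), label TIFFs, a manifest of per-file failures, and metadata
carrying the hash of the configuration actually used; re-runs are
byte-identical.

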