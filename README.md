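# isletpol

Automated quantification of insulin polarisation in pancreatic β cells.

β cells inside islets of Langerhans are polarised: they orientate toward the
islet capillaries, and insulin is enriched at the face of the cell that
contacts the capillary basement membrane (marked by laminin). Measuring this
by hand — drawing a line-scan across each cell from its vascular to its
avascular face — is slow and samples only a few dozen cells per islet.
`isletpol` implements the automated alternative as a tested, reusable
pipeline for multi-channel confocal planes (insulin / laminin / nuclei,
8-bit grey, one PNG per channel per z-plane):

1. **Semantic segmentation** — a compact U-Net (pure NumPy, CPU) maps
   channel planes to a per-pixel β-cell probability, thresholded at 0.5;
   externally predicted masks are accepted equally. Training utilities
   include ×8 random affine augmentation (rotation, shear, shift, flips) and
   K-fold cross-validation by image with pixel confusion-matrix metrics
   (accuracy, precision, recall, F1, BCE loss, mean stopping epoch).
2. **Instance segmentation** — marker-controlled watershed on the
   Gaussian-smoothed Euclidean distance transform of the mask; instances of
   area ≤ 490 px are filtered out.
3. **Face detection** — for each cell, a 10-px boundary region
   (dilation − mask) is scanned with a 9×9 window over the laminin channel;
   the window-mean argmax marks the vascular face, the argmin the avascular
   face.
4. **Line-scan quantification** — Bresenham lines from each face point to
   the cell centroid; at every in-cell line coordinate the mean insulin over
   a 10×10 window ∩ cell is computed and the maximum retained:

   `I_face = max_{p ∈ line ∩ cell} mean{ insulin(q) : q ∈ W_10(p) ∩ cell }`

5. **Statistics** — per-cell vascular/avascular pairs are compared with a
   paired two-tailed Student's t test (t = mean(d)·√n / sd(d), df = n−1) and
   reported as mean ± SEM (SD also shown). One CSV row per cell instance per
   plane.

Because real annotated islet stacks are large and not bundled here, the
package ships a **synthetic islet generator** with known ground truth: a
connected tortuous capillary network (laminin-bright), irregular close-packed
cells grown against the capillaries, and per-cell insulin enriched toward the
capillary contact by a programmed ratio *r* (intensity
`base·(1 + (r−1)·g(p))` with `g` falling linearly from 1 at the contact to 0
at the farthest cell pixel), plus granule speckle and Gaussian noise. Every
stage of the pipeline is validated against this ground truth; see
`docs/methods.md` for what that does and does not demonstrate about real
tissue.

## Worked example

Run the full pipeline (simulate → ground-truth masks → watershed instances →
polarity → statistics → 3-D volume) on three synthetic planes:

```sh
isletpol run --out demo_out --seed 1
cat demo_out/report.txt
```

```
n = 94 cell instances (0 dropped)
laminin vascular: 181.28 +/- 0.05 SEM (SD 0.51)
laminin avascular: 1.44 +/- 0.01 SEM (SD 0.13)
laminin paired t(93) = 3368.537, p = 2.5e-238
insulin vascular: 138.23 +/- 1.88 SEM (SD 18.23)
insulin avascular: 133.96 +/- 1.86 SEM (SD 17.99)
insulin paired t(93) = 4.394, p = 2.95e-05
```

Reading this: 94 cell instances survived the 490-px area filter across the
three planes. The laminin contrast (181 vs 1.4) confirms the face detector is
separating capillary-contacting from capillary-free boundary stretches, and
the paired insulin excess at the vascular face (138.2 vs 134.0,
p ≈ 3×10⁻⁵) recovers the programmed polarisation — the cells were simulated
with insulin enriched toward their capillary contact. `demo_out/` also holds
the per-cell CSV (`records.csv`), instance label maps, a JSON report, a
scaled multi-page TIFF volume of the masks and a `manifest.json` recording
seeds and per-stage counts; rerunning with the same seed reproduces the CSV
byte for byte.

Individual stages are available as subcommands (`simulate`, `augment`,
`train`, `predict`, `instances`, `polarity`, `stats`, `volume`) and as plain
library calls (`isletpol.polarity.analyse_islet`, …).

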