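# bordercell

Quantification of collective cell migration in small clusters, built
around the *Drosophila* border-cell system: a group of ~6–8 cells that
migrates through the egg chamber while balancing two antagonistic
F-actin structures — finger-like **protrusions** that pull the group
forward and a peripheral supracellular actomyosin **cable** that holds
it together.  The package turns fluorescence time-lapses of such
clusters into the standard read-outs of this field:

* **Subcellular region decomposition.** From a background-subtracted
  frame and a handful of user-clicked landmarks, the cluster is split
  into main body, labelled protrusions, the peripheral cable (with its
  *broken sections*) and inner cell–cell contacts.
* **Morphometrics and group classification.** Protrusion-area fraction
  *f* = A<sub>prot</sub>/(A<sub>body</sub>+A<sub>prot</sub>), cable
  discontinuity *d* = L<sub>broken</sub>/L<sub>rim</sub>, protrusion
  count, total area, migration speed, and relative F-actin intensity per
  region.  Groups are classified **tight** (*f* < 10 %, *d* ≤ 8 %),
  **loose** (*f* > 25 %, *d* ≥ 25 %) or **balanced** (10 % ≤ *f* ≤ 25 %,
  8 % < *d* < 25 %); contradictory combinations stay *unclassified*.
* **PIV actin-flow analysis.** Network displacements between frames are
  estimated by windowed zero-normalized cross-correlation (source window
  1.4 µm², search window 2.4 µm², coefficient cutoff c₀ = 0.5),
  interpolated over the cell outline with a truncated Gaussian kernel
  (6 µm, σ 1.2 µm), smoothed in time (20 s kernel, σ 10 s), and reduced
  to divergence maps (∇·V; strong sinks mark converging actin that loads
  myosin), retrograde/anterograde labels (sign of the cosine to the cell
  motion), per-region occurrence rates and rose histograms.
* **Synthetic ground truth.** Because such imaging data are rarely
  public, a first-class generator renders cluster movies with exactly
  known regions, flows (translation / retrograde / centripetal / radial
  sink), drift, photobleaching and noise.  Every downstream stage is
  tested against this truth, and brute-force oracles check the numerics.

Intended users: cell-migration labs quantifying cluster morphology and
cortical flows, and method developers who need a fully ground-truthed
test bed for segmentation or PIV code.

## Worked example

`examples/02_segment_and_classify.py` generates a "balanced" cluster
movie (two protrusions, 15 % cable gap, 0.5 µm/min drift, speckle and
noise), recovers the morphometrics from the pixels and compares them to
the generator's truth:

```
                             recovered     truth
protrusion area fraction        0.1451    0.1500
cable discontinuity             0.1370    0.1481
protrusion count                     2         2
speed (um/min)                   0.497     0.500
category                      balanced  balanced

relative F-actin intensity (region mean / group mean):
  contacts     1.122
  cables       1.552
  protrusions  1.260
```

Both classification axes come back within ~0.01 of truth and the group
is classified balanced.  The relative intensities read out the rendered
contrast: the cable is the brightest compartment, as in a LifeAct image.

`examples/03_actin_flow_piv.py` pushes a rendered sink flow
(v(r) = −k·r, k = 0.5 min⁻¹) through the full PIV pipeline:

```
flow fields estimated         : 3 frame pairs
mean in-mask flow speed       : 2.95 um/min
mean interior divergence      : -0.911 / min
analytic divergence (-2k)     : -1.000 / min
negative-divergence fraction  : 1.00  (sinks dominate)
```

The measured mean interior divergence lands within ~9 % of the analytic
−2k despite integer-pixel displacement quantization.

The other examples cover movie generation (`01`) and photobleaching
correction (`04`).  A thin CLI wraps the same library calls:

```bash
bordercell synth --out fixtures/        # write the canonical fixtures
bordercell quantify movie.tif landmarks.json --out metrics.csv
bordercell piv movie.tif --out-dir flow/
bordercell run --config run.yaml        # full pipeline + hash manifest
```

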