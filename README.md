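# angioarch

Quantification of how hundred-micron-scale substrate architecture controls
the position and orientation of self-assembled microcapillary-like
structures in endothelial/osteoblast co-cultures.

When HDMECs (human dermal microvascular endothelial cells) and human
osteoblasts are co-cultured on patterned bioceramic surfaces, the
endothelial cells self-assemble into CD31-positive, vessel-like tubular
structures. On substrates carrying periodic semicircular grooves
(concavities) or ridges (convexities) with feature widths of 330/660 µm
and depths of 150–585 µm, these structures form preferentially inside
grooves (or between convexities) and align with the groove axis. This
package implements the confocal image-analysis pipeline that turns a
CD31 Z-stack of such a sample into two summary statistics:

- **DOA — degree of alignment.** From the background-subtracted maximum
  intensity projection, a Fourier orientation histogram
  w(θ), θ ∈ [−90°, 90°), is computed (Hann apodization, power spectrum,
  orientations accumulated over a physical-frequency annulus with radial
  whitening). With the groove axis at 0°,

      DOA = w(0°) / w(90°)

  DOA = 1 means random alignment; the study's patterned substrates reach
  DOA ≥ 2.5.

- **DOC — degree of containment.** The projection is auto-contrasted,
  converted to 8-bit, binarized with Phansalkar local thresholding
  (radius 5 px), and cleaned of particles below 400 µm². With grooves
  vertical, the mask's vertically averaged signal profile v(x) is
  compared against the groove intervals G detected from the stack's
  depth profile:

      DOC = ( Σ_{x∈G} v(x) / |G| ) / ( Σ_{x∉G} v(x) / |Gᶜ| )

  DOC = 1 means a uniform distribution of structures; deep narrow
  grooves in the study exceed 2.

The groove intervals come from a re-implementation of the GrooveJ
detection (depth profiles along 300-µm-wide lines across the stack; the
published parameter set 300 µm / 0.4 / 100 µm / 0.5 / 0.35 / 0.01 is the
default). Because the study's raw images are not deposited, the package
includes a first-class synthetic generator — parametric substrate
geometries with analytic depth profiles and ground-truth groove
intervals, plus confocal-like Z-stacks of tortuous, branched,
vessel-like structures with controllable alignment (`alignment_kappa`)
and containment (`containment_prob`) — so every stage is testable
against known ground truth.

## Worked example

Analyse a synthetic sample on the "small deep" architecture (330 µm
grooves, 300 µm deep, 630 µm periodicity) with strongly aligned,
strongly contained structures:

```python
from angioarch import PipelineConfig, run_pipeline, FRAME_HALF

cfg = PipelineConfig(design="small_deep", alignment_kappa=16.0,
                     containment_prob=0.95, image_size_px=FRAME_HALF,
                     seed=1)
report = run_pipeline(cfg)
print("DOA =", round(report.doa.doa, 3))
print("DOC =", round(report.doc.doc, 3))
print("grooves:", report.grooves.n_grooves)
```

prints

```
DOA = 3.327
DOC = 54.461
grooves: 5
```

DOA ≈ 3.3 says the orientation histogram holds 3.3× more signal along
the groove axis than perpendicular to it (strong alignment); DOC ≈ 54
says essentially all segmented CD31 signal sits inside the five detected
groove intervals (near-total containment; with some signal between
grooves this value drops toward the study's ≥ 2 range). A flat control
(`design="flat"`, `alignment_kappa=0`, `containment_prob=0`) gives
DOA ≈ 1 and an undefined DOC (no grooves to contain anything).

The same pipeline is scriptable from a shell:

```
angioarch simulate --design small_deep --seed 1 --out stack.tif
angioarch run-all --stack stack.tif --design small_deep --out report/
angioarch simulate-study --seed 1 --out study.csv   # 7 designs x 3 replicates
angioarch compare study.csv --stat DOA              # Kruskal-Wallis + Dunn
```

Group tables are compared exactly as in the study: per-architecture mean
± SEM, a Kruskal-Wallis omnibus test (exact permutation null for the
small n = 3 groups) and Dunn's pairwise post-hoc z-tests flagged at
P < 0.05 and P < 0.005.

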