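# golgiatlas

Quantitative 3D colocalization analysis and sub-Golgi "atlas" mapping for
dual-color fluorescence volumes.

## The problem

Golgi glycosyltransferases are not distributed uniformly across the stack:
each enzyme occupies a characteristic position along the cis→trans axis,
and those positions differ by fractions of a micrometre — at or below the
axial resolution of confocal microscopy. Direct segmentation of cisternae
is therefore not an option; instead, relative positions can be inferred
statistically by co-expressing pairs of labeled enzymes and measuring how
strongly their 3D voxel intensities correlate. Enzymes in the same
sub-compartment colocalize almost as well as a dual-labeled single enzyme;
enzymes one or two cisternae apart correlate measurably less.

`golgiatlas` implements that measurement machinery end to end:

- **Costes automatic thresholding** — fit the orthogonal (total least
  squares) regression of channel B on channel A, then lower the candidate
  threshold `t_a` (with `t_b` slaved to the regression line) from the top
  intensity down until the Pearson correlation of the *below*-threshold
  voxels first reaches ≤ 0. Voxels above threshold are signal.
- **Thresholded voxel Pearson r** over the signal set — the scalar degree
  of colocalization per cell.
- **nMDP colormapping** after Otsu or maximum-entropy (Kapur)
  segmentation:
  `nMDP(x) = (A(x) − ā)(B(x) − b̄) / ((A_max − ā)(B_max − b̄))`
  over the foreground, with `Icorr` = fraction of foreground voxels with
  nMDP > 0 and `Inega-corr = 1 − Icorr`.
- **Group statistics** — per-pair mean ± SEM over cells, Dunnett
  many-to-one comparisons against a control pair, unpaired pooled t-tests.
- **The atlas** — enzyme–enzyme dissimilarity `d = 1 − r̄`, embedded in 3D
  by metric MDS (SMACOF, seeded multi-restart), projected to 2D by PCA:
  a map in which nearby points are enzymes with similar sub-Golgi
  distributions.
- **A ground-truthed simulator** — seeded dual-channel Golgi-ribbon
  volumes (ministacks along a curved polyline, jittered local cis→trans
  axes, anisotropic Gaussian PSF, Poisson shot + Gaussian read noise) in
  which the axial offset between the two labels is known exactly, so every
  stage of the pipeline can be validated against ground truth.

## Worked example

Run the whole pipeline on a small synthetic three-enzyme panel
(cisA at 0 µm, medB at 0.25 µm, transC at 0.6 µm along the stack axis):

```bash
golgiatlas demo out/
```

which writes `truth.csv`, `coloc.csv`, `stats.csv`, `distances.csv`,
`embedding.csv`, `atlas.png` and a `config.json` echo into `out/`.
With the default configuration, `stats.csv` contains:

```
pair,n_cells,mean_r,sem_r,is_control,p_adjusted,stars,method
cisA~cisA,3,0.8143603046203548,0.003386280863676718,True,,,
cisA~medB,3,0.7140426079107195,0.009519470474085976,False,0.00041354066250254284,***,dunnett
cisA~transC,3,0.3138113534849561,0.022892614425984552,False,0.0,****,dunnett
medB~medB,3,0.8271798776642809,0.014890746987465198,False,0.9156645530064613,ns,dunnett
medB~transC,3,0.6177880949106563,0.007537046512554959,False,1.7991437351039252e-07,****,dunnett
transC~transC,3,0.8097565467111055,0.004700735911676159,False,0.9989311541851593,ns,dunnett
```

Reading it: the three dual-label controls (`cisA~cisA`, `medB~medB`,
`transC~transC`) all sit near r ≈ 0.81–0.83 — the noise ceiling of the
measurement under the demo's reduced grid. The 0.25-µm pair drops to
r ≈ 0.71, the 0.35-µm pair to r ≈ 0.62, and the 0.6-µm pair to r ≈ 0.31,
each significantly below the control (Dunnett-adjusted p and significance
stars in the last columns). `distances.csv` holds the corresponding
`d = 1 − r̄` matrix and `atlas.png` the 2D atlas, in which the three
enzymes line up in their true cis→trans order.

The individual stages are available as subcommands (`simulate`, `coloc`,
`stats`, `atlas`) and as plain library functions (`costes_thresholds`,
`thresholded_pearson`, `nmdp_map`, `make_atlas`, ...) operating on
OME-TIFF z-stacks with voxel-size metadata.

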