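# vvoqc — voxel volume overlap motion QC for fMRI

Head motion summaries in common use — total displacement (TD, motion
relative to the first volume) and scan-to-scan displacement (STS,
motion relative to the preceding volume) — are measured in
millimetres and ignore the voxel grid. Yet the damage a movement does
at the level of a single voxel depends entirely on voxel size: a 1 mm
shift leaves 18/27 mm³ (66.6 %) of a 3 mm isotropic voxel overlapping
its previous position, 50 % of a 2 mm voxel, and 0 % of a 1 mm voxel.
Millimetre thresholds therefore cannot be compared across studies
acquired at different resolutions.

`vvoqc` computes **voxel volume overlap (VVO)** metrics that fold
voxel size in directly. For each timepoint the voxel cuboid is pushed
through the rigid-body transform estimated by realignment and the
*exact* volume still overlapping the unmoved reference cuboid is
computed geometrically:

- the reference voxel is the intersection of six half-spaces;
- the moved voxel is clipped against the six cutting planes in turn
  (3-D Sutherland–Hodgman clipping with linear interpolation at the
  plane crossings);
- the convex remnant's volume is obtained by tetrahedral
  decomposition of its vertex hull and expressed in percent of
  dx·dy·dz.

This yields, per volume *t* with transforms `T_t`:

- `TD_VVO(t) = 100 · |voxel ∩ (T_t T_1⁻¹) voxel| / |voxel|` — drift,
- `STS_VVO(t) = 100 · |voxel ∩ (T_t T_{t-1}⁻¹) voxel| / |voxel|` — spikes,

evaluated at six representative voxels 65 mm from the origin (the
average adult cortical distance) along ±x, ±y, ±z and summarized by
their median. The non-overlapping volume is further split into
in-plane and through-plane (out-of-plane) parts per acquisition plane
— out-of-plane motion is disproportionately harmful through
spin-history effects.

The two scales are linked by the constrained calibration line
`STS_VVO = 100 − a·STS` (zero motion must give 100 % overlap), fitted
through the origin on datapoints with STS in 0–1.5 mm; with the
reference slope `a = 43.2422`, STS thresholds 0.25/0.5/1.0/1.5 mm map
to STS_VVO ≈ 90/80/55/35 %, the default quality cutoffs
(very high / high / potentially acceptable / questionable). A
censoring (scrubbing) regressor flags volumes below a chosen overlap
threshold.

The only required input is the realignment parameter file — SPM
`rp_*.txt`, FSL `.par` or a BIDS confounds TSV — plus voxel
dimensions (given directly or read from a NIfTI header). No image
data is touched.

## Worked example

```sh
# a synthetic 60-volume session with drift and motion spikes
vvo simulate --kind random --n-volumes 60 --seed 7 --out rp_demo.txt
vvo compute --rp rp_demo.txt --voxel 3 3 3 --threshold 55 --out qc/
```

prints

```
n_volumes: 60
voxel: (3.0, 3.0, 3.0) mm (acquired), plane axial
median TD_VVO over time:  71.3267 %
median STS_VVO over time: 92.8626 %
censored volumes (<55.0% sts_vvo): 0 (0.00 %)
reports written to qc
```

Read: over the session the typical voxel still shares 71.3 % of its
volume with its starting position (slow drift has moved the head
about a voxel-quarter), scan-to-scan overlap stays high (92.9 %), and
no volume dropped below the 55 % "potentially acceptable" floor; when
volumes are flagged, `qc/censor_regressors.txt` holds one
spike-regressor column per flagged volume, ready for a GLM design
matrix.
`qc/vvo_report.csv` has one row per volume with TD/STS (mm), the six
per-location overlaps, their medians, the out-of-plane percentage and
the quality label; `qc/vvo_report.json` adds the metadata and summary.

Other entry points:

```sh
vvo sweep --rp rp_demo.txt --out sweep.tsv        # overlap vs voxel size (4 … 0.5 mm)
vvo calibrate --a 43.2422 --out lookup.tsv        # STS -> STS_VVO lookup table
vvo calibrate sess1.txt sess2.txt --out lookup.tsv  # fit the slope from sessions
```

Everything is also available as a library (`vvoqc.overlap_fraction`,
`vvoqc.compute_vvo`, `vvoqc.fit_constrained`, …); see the docstrings
and `docs/methods.md`.

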