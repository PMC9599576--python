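# wirespec

Chemometrics for SERS (surface-enhanced Raman scattering) line scans
acquired at 1 µm steps along a single nanowire probe inserted into 2D
(monolayer) or 3D (spheroid) cell-culture models.

Two analysis stages:

1. **Model discrimination** (`wirespec.model_discrimination`) — PCA of the
   labeled 2D/3D spectra, 95% confidence ellipses in (PC1, PC2) score
   space, a loading-quadrant rule that reads model-characteristic bands
   off the loadings (PC1 > 0 ∧ PC2 < 0 → 2D, PC1 < 0 ∧ PC2 > 0 → 3D),
   and KNN validation (K = 11) using the root-mean-square distance
   between score pairs on a stratified 80/20 split.
2. **Region mapping** (`wirespec.region_clustering`) — K-means++ over the
   full 717–1827 cm⁻¹ spectra with the cluster count selected by the
   silhouette coefficient, Random-Forest importance ranking per
   wavenumber, boxcar smoothing, selection of the two most important
   bands (the nucleic-acid marker near 782 cm⁻¹ and the amide I protein
   marker near 1655 cm⁻¹ on default synthetic data), two-band
   re-clustering into protein-rich / nucleic-acid-rich calls, and a
   normalized per-spectrum intensity (1 at the cluster center).

Since no raw spectra are publicly deposited, `wirespec.synthetic_data`
generates line scans with the statistical structure the analysis
expects: Lorentzian band mixtures per cellular region (nucleus /
cytoplasm / ECM), model-specific band sets for the 2D/3D pair,
multiplicative hot-spot variability (default CV 0.042), polynomial
baseline and Gaussian noise — all seeded and reproducible, with ground
truth recorded for scoring.

## CLI

```bash
# synthetic line scan (default layout: ECM | cytoplasm/nucleus alternation | ECM)
wirespec simulate --seed 1 --out out/sim

# labeled 2D/3D pair
wirespec simulate --mode model-pair --n-2d 270 --n-3d 200 --seed 1 --out out/pair

# stage 1: PCA + ellipses + key bands + KNN
wirespec discriminate out/pair/model_2d.csv out/pair/model_3d.csv --seed 1 --out out/disc

# stage 2: RF-guided two-band K-means++ region mapping
wirespec map-regions out/sim/line_scan.csv --seed 1 --out out/map

# band-area RSD of a scan
wirespec metrics out/sim/line_scan.csv --center 782 --halfwidth 6
```

Pipeline settings can be overridden with `--config cfg.yaml` (keys match
`wirespec.spatial_pipeline.PipelineConfig` / `GeneratorConfig` fields);
every default used is echoed into the JSON run reports.

Spectra are exchanged as plain CSV (metadata columns `position_um`,
`model_label`, `truth_region` followed by one column per wavenumber;
lossless round trip) and a minimal JCAMP-DX reader is included for
single- and multi-block files.

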