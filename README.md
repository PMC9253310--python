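# hgparcel

Individual-level parcellation of Heschl's gyrus (HG) from structural-
connectivity fingerprints, with downstream structural/functional
profiling and seed-based functional gradient mapping. Because the real
imaging data are access-restricted, the package ships a first-class
synthetic-cohort generator that emulates the statistical structure the
pipeline consumes, so every stage is testable offline.

## What it does

- **`hgparcel.synthetic`** — multi-subject synthetic cohorts: a
  lattice-embedded seed region with three planted subregions ordered
  along an anatomical axis (HG2 medial-posterior-superior, HG1 central,
  HG3 lateral-anterior-inferior), multinomial streamline-count
  fingerprints over 42 target ROIs (10,000 streamlines per seed unit),
  1400-timepoint time series with a planted medial-to-lateral
  connectivity gradient, and subregion-ordered myelin/thickness maps.
- **`hgparcel.fingerprints`** — seed-region dilation constrained to
  specific neighboring regions (default 2.1 mm into STG/insula),
  endpoint-table → fingerprint-matrix construction, row-proportion and
  log1p normalization.
- **`hgparcel.parcellation`** — K-means (k-means++, best-of-restarts)
  over K = 2..10, elbow selection via the Kneedle rule on the inertia
  profile (per-subject or group-level), canonical relabeling to
  HG1/HG2/HG3 along the anatomical axis.
- **`hgparcel.profiles`** — per-subregion structural-connectivity
  profiles, soft-thresholded functional connectivity
  (((r + 1) / 2) ** beta, beta = 6), morphometry summaries, paired
  t-tests per subregion pair, and Benjamini–Hochberg FDR correction
  within each measure family.
- **`hgparcel.gradients`** — z-normalization, SVD compression of the
  outside-seed time series into singular-value-weighted components,
  cosine-similarity affinity over seed vertices, PCA gradients,
  group-reference construction, orthogonal Procrustes alignment, and
  subregion stratification of the first gradient.
- **`hgparcel.workbench`** — configuration, the end-to-end pipeline,
  and plain-text report generation.

## CLI

```sh
# write a synthetic cohort to disk (tables + YAML sidecar)
hgparcel simulate --n-subjects 20 --seed 0 --out-dir out/sim

# single-subject file-based steps
hgparcel fingerprint --endpoints endpoints.tsv --coords coords.tsv \
    --radius-mm 2.1 --allowed-regions STG,IN --out fp.tsv
hgparcel parcellate --fingerprint fp.tsv --coords coords.tsv --out labels.tsv

# configured pipeline stages (simulate -> parcellate [-> profile -> gradient])
hgparcel run --seed 0 --out-dir out/run
hgparcel profile --config run.yaml --out-dir out/profiles
hgparcel gradient --config run.yaml --out-dir out/gradients
```

`run.yaml` mirrors `hgparcel.workbench.RunConfig`; any omitted field
keeps its default. A run directory contains per-subject coordinate,
fingerprint, label and morphometry tables, the inertia profiles, the
statistics table, aligned first gradients, `summary.json`, and a
human-readable `report.txt`.

## Notes

- All randomness flows from a single master seed through
  `numpy.random.SeedSequence` spawning; identical configs reproduce
  cohorts bit for bit.
- The generator is an emulation of the statistics the method assumes
  (clusterable fingerprints, a smooth connectivity gradient), not a
  model of BOLD physiology or fiber geometry.
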