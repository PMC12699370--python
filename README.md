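# cytocurv

Quantitative image-analysis pipelines for studying how cortical proteins
partition between flat and curved membranes:

- **Boundary curvature localization** — segment a cell from two-channel
  fluorescence images, extract a sub-pixel outline, estimate signed and
  smoothed |κ| along it, sample per-channel boundary intensity, classify
  actin- vs spectrin-enriched stretches and compare their curvature
  distributions (including the fraction of samples below a configurable
  |κ| cutoff, default 0.2 µm⁻¹).
- **Deformability cytometry** — per-cell deformation index DI = H/W from
  cross-flow junction video frames (H along the outflow axis, W along the
  inflow axis, at the frame of maximum deformation per transit),
  aggregated into DI-vs-flow-rate curves.
- **Densitometry** — background-subtracted band/spot integration for gels
  and lipid strips, dilution-corrected sedimentation binding ratio
  B / (B + d·U), and blank-subtracted max-normalized spot intensities.
- **Assay design** — closed-form calculators for spherical supported
  lipid bilayer (SSLB) experiments: sphere curvature κ = 2/diameter and
  equal-total-surface-area mass scaling across bead sizes.
- **Synthetic generators** — seeded, ground-truth-annotated phantoms for
  every stage: two-channel cells with a programmable curvature-dependent
  channel response, transit videos with programmed peak DI, gel lanes and
  strip spots with programmed intensities.

## Command line

One executable with subcommands (exit codes: 0 ok, 1 data error,
2 config error):

```bash
# equal-surface-area design table (mass and curvature per bead diameter)
cytocurv design --diameters 1000,100,50,30

# seeded synthetic data (TIFFs + ground-truth CSV/JSON side files)
cytocurv simulate phantom --out out/phantom --seed 1
cytocurv simulate video  --config video.yaml --out out/video --seed 1
cytocurv simulate gel    --config gel.yaml   --out out/gel   --seed 1
cytocurv simulate strip  --config strip.yaml --out out/strip --seed 1

# analyses (YAML configs; unknown keys rejected; pixel size never guessed)
cytocurv curvature --config curvature.yaml --out out/curv
cytocurv deform    --config deform.yaml    --out out/di
cytocurv densito   --config densito.yaml   --out out/gelq
```

Minimal curvature config:

```yaml
pixel_size_um: 0.1
images:
  spectrin: out/phantom/spectrin.tif
  actin: out/phantom/actin.tif
params:
  presmooth_window_um: 3.0
```

Every run writes a `provenance.json` (config hash, seed, versions)
alongside its CSV/JSON outputs.

## Conventions

- Contours are closed, counterclockwise (interior on the left), uniformly
  resampled in arc length, in micrometres (image convention x right,
  y down, pixel centres at integer coordinates).
- Signed curvature is positive where the osculating-circle centre lies on
  the interior side, so a convex cell outline is uniformly positive and
  invaginations are negative; region classification uses smoothed |κ|
  only, so results do not depend on this sign choice.
- Sphere curvature for bead assays is 1/radius = 2/diameter.
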