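# memclust

Quantitative image analysis of plasma-membrane protein condensation and
its physiological consequences, built around the readouts used to show
that the defence hormone salicylic acid condenses the PIN2 auxin
transporter into membrane "hyperclusters" in *Arabidopsis* roots:

- **Cluster statistics** — segmentation of membrane signal into islands,
  areas classified as tiny (< 0.2 µm²), small (0.2–0.6), medium (0.6–1)
  or long (> 1 µm²), size-class frequency tables, nearest-neighbour
  spacing, and object/pixel colocalisation.
- **Clustering index** — per-cell coefficient of variation of
  membrane-pixel intensities; condensation packs the same fluorescence
  into fewer, brighter pixels, so CV = σ/µ rises.
- **Outside confidence** — percentage of treated intensity values beyond
  the mock sample's empirical 2.5–97.5 percentile interval; ≈ 5% under
  the null by construction, and rising with condensation.
- **Single-particle tracking** — spot detection, greedy nearest-
  neighbour linking, intensity classes (low < 5×10³, medium 5–15×10³,
  high > 15×10³ AU), time-averaged MSD and the short-lag fit
  MSD(Δt) = 4DΔt + 4σ², whose slope/4 is the 2-D diffusion coefficient
  and whose intercept is the static localization-noise term.
- **FRAP** — normalization to the pre-bleach plateau and the
  single-exponential recovery fit I(t) = I₀ + (I∞ − I₀)(1 − e^(−kt)),
  partitioning molecules into mobile and stable fractions (summing to 1
  by construction).
- **Kymograph lifetimes** — residence times of endocytic puncta as
  supra-threshold run lengths × frame interval, with censoring of runs
  touching the movie edges.
- **Root asymmetry & gravitropism** — sided intensity profiles,
  lower/upper ratios and treatment fold changes, deviated-tip-angle
  summaries, pooled-variance t-tests and dose–response tables.

Because the original microscopy is not deposited, the package ships a
first-class synthetic-data module (`memclust.synthetic`) whose seeded
generators plant known ground truth for every readout: cluster fields
with controlled area distributions, Brownian/immobile trajectory
mixtures, single-exponential FRAP curves, kymographs with exponential
lifetimes, and two-sided root fields with an imposed fold difference.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/03_single_particle_diffusion.py` simulates 200
particles (half free at D = 0.05 µm²/s, half immobile; 6 s movies at
0.1 s interval, 0.02 µm localization noise) and prints:

```
free    : D = 0.0502 µm²/s, intercept = 0.00169 µm² (r² = 1.000)
immobile: D = 0.0000 µm²/s, intercept = 0.00158 µm² (r² = 0.000)
true D_free = 0.05 µm²/s; localization offset 4σ² = 0.00160 µm²
```

The free population recovers the planted diffusion coefficient from the
MSD slope; the immobile one collapses to D ≈ 0, leaving only the
localization offset 4σ² in the intercept. The other examples print the
size-class table and clustering index of a hyperclustered field, the 5%
null baseline of the outside-confidence statistic, mobile/stable FRAP
fractions for a control vs a stabilised membrane, and puncta lifetimes
plus the lower/upper root ratio.

A `memclust` command-line interface wraps the same library for shell
use (`memclust simulate|clusters|spt|frap|lifetime|asym|run`), driven
either by flags or a YAML pipeline config; every run writes a manifest
with the config snapshot, seed and input checksums so deterministic
stages reproduce bit-identically.

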