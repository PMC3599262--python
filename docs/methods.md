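# Methods

## Problem and model

An imaging flow cytometer captures, for every cell passing the flow cell,
a brightfield image, one or more fluorescence images and a side-scatter
image of that single cell (one "event"). Probe molecules (here: labeled or
light-diffracting nanoparticles) associated with a cell are either adsorbed
on the plasma membrane or internalized in the cytoplasm; total cell
fluorescence cannot distinguish the two. The package's model of the
distinction is purely geometric: pixels deeper than a fixed physical depth
*d* from the cell boundary are "inside", the remaining rim of the cell mask
is the "membrane shell". This assumes (i) the brightfield mask traces the
plasma membrane closely enough, (ii) the erosion depth exceeds the apparent
thickness of the membrane-bound signal (set by optical blur and particle
size), and (iii) a single 2-D section represents the cell — true for
imaging-flow data with a wide depth of focus, not for thin confocal slices.

## Masks

- **Whole-cell mask.** Otsu threshold, by default on the absolute deviation
  of the brightfield from its median (so cells darker *or* brighter than the
  background are found; `brightfield_polarity` can force a direction), then
  hole filling and the largest connected component. Blank images yield an
  empty mask with `no_cell_found` set rather than an exception. Objects
  smaller than `min_cell_area_um2` (default 50 µm², an image-domain analog
  of scatter-based debris gating) are flagged `below_area_gate`; cells
  touching the image border are flagged, not dropped — downstream code
  decides.
- **Internal mask.** A pixel of the whole mask survives erosion iff its
  Euclidean distance to the nearest background pixel is at least
  `erosion_px = round(erosion_depth_um / pixel_size_um)` (ties to even).
  Defaults 3.0 µm and 0.5 µm/px give 6 px. The test for `dist ≥ erosion_px`
  uses exact integer squared distances recovered from the distance
  transform's nearest-background indices, so the operation is
  pixel-for-pixel identical to a brute-force minimum-distance check and free
  of floating-point boundary ambiguity. EDT thresholding was chosen over
  iterated structuring-element erosion because it is isotropic in physical
  units; a 6-step 4- or 8-connected erosion would carve a diamond or square
  metric instead.

## Internalization Score

With I_in and I_out the channel sums over the internal mask and the shell
(I_total = I_in + I_out by construction, so the partition identity is
exact),

    IS = log10((I_in + ε)/(I_out + ε)).

The log in/out ratio is the only simple statistic consistent with the
score's documented behavior — zero for an equal split, negative when
surface signal dominates — whereas a raw inside/total ratio is confined to
[0, 1] and cannot go negative; that ratio is still emitted as
`ratio_in_total`. ε (default 1 intensity unit, configurable, recorded in
output metadata) regularizes empty compartments and bounds the score by
±log10((I_total+ε)/ε). ε is in intensity units: rescaling a channel by c
while rescaling ε by c leaves IS unchanged.

Background handling is `none` by default (raw instrument-style sums);
`median_outside` subtracts the median intensity outside the whole-cell mask
and clips at zero. Saturated pixels are only counted
(`saturation_fraction`), never corrected.

## Population statistics

- **MFI**: median of per-cell intensities for classic flow-cytometry tables,
  mean for imaging-derived internal intensities; the statistic used is
  always recorded. Values are sorted before the median so results are
  independent of input order. Warnings are raised below 500 cells (imaging)
  or 10,000 (classic FCM).
- **Trypan-Blue quench**: internalized% = 100·r with r = MFI_withTB /
  MFI_withoutTB, capped at 100 with a flag. TB is assumed to remove only
  extracellular signal; incomplete quenching is modeled by an efficiency
  q ∈ (0, 1]: internalized% = 100·(r − (1 − q))/q, default q = 1.
- **Inhibition**: 100·(1 − (MFI_cond − bg)/(MFI_ref − bg)), background
  default 0, clipped to [0, 100] with a flag. Both quench and inhibition
  are invariant under common rescaling of all MFIs.
- **ANOVA + Bonferroni**: one-way ANOVA, then the classic Bonferroni t-test
  — pairwise t statistics using the pooled within-group mean square with
  N − k degrees of freedom, p_adj = min(1, p·m) over all m = k(k−1)/2
  pairs. Zero-variance input is reported as p = 1 with a `degenerate` flag
  instead of NaN.

## Colocalization

Plain pixel-wise Pearson correlation (JACoP-style, no Costes threshold or
randomization) of two channels over a mask — whole-cell by default,
internal or full-frame on request. A channel that is constant within the
mask makes r undefined and raises an error; silently returning 0 would
masquerade as "no relationship". Batch results are mean ± sample (n−1) SD
over per-image coefficients, with undefined events excluded and counted.

## Synthetic event generator

Each event is one round cell: a uniform disk of radius `cell_radius_um`
(default 8 µm) offset from the brightfield background (100) by
`cell_brightfield_contrast` (default −30, cell darker). The true interior
is the disk eroded by `membrane_width_um` (default 3 µm) with the same
exact-EDT erosion the analysis uses, so generator truth and mask oracle
agree by construction. A probe budget (`probe_total_intensity`, default
10,000) is split: fraction `internal_fraction` strictly interior, the rest
in the shell — either diffuse (uniform per compartment) or as `n_spots`
Gaussian puncta (σ = 1 px, centers uniform in the compartment, each
compartment renormalized so the split is exact despite Gaussian tails).
Noiseless channels therefore conserve the budget and match the requested
split to floating-point rounding. Optional channels: side scatter (same
spatial recipe, own amplitude) and a marker for colocalization, rendered
either coincident with the probe or independently placed.

Noise: none, Poisson (per-pixel counts) or Gaussian with sd defaulting to
1% of the noiseless channel peak, clipped at zero. Uniform background
(default 2 units/px) is added to fluorescence and scatter channels.
Defaults — 64×64 px at 0.5 µm/px, one cell per event centered in frame —
emulate per-event imaging-flow acquisition.

What the generator does **not** emulate: optical PSF/defocus, the
partial-volume effects of a 4 µm depth of focus, irregular cell shapes,
multi-cell doublets, spectral overlap, camera fixed-pattern noise. Passing
tests therefore validate the arithmetic and geometry of the pipeline, not
segmentation robustness on hard real-world brightfield images.

Cohorts derive per-event seeds from one master seed (an event's images do
not depend on cohort size), and per-field relative-s.d. jitter perturbs
specs multiplicatively; draws violating spec invariants are redrawn up to
10 times, then error.

## Numerical and design choices

- Erosion depth in pixels rounds half-to-even (documented, deterministic).
- `I_total` is defined as `I_in + I_out` so the partition identity is exact
  rather than subject to summation-order rounding.
- Identical per-image Pearson coefficients report an SD of exactly 0.
- The pipeline writes a manifest with package version, per-stage counts and
  a configuration hash (SHA-256 of the canonical JSON, excluding the output
  directory, which does not affect the computation); every CSV carries the
  hash in a leading `#` comment line. Reruns with the same configuration
  and inputs are byte-identical.
- Proprietary instrument container formats (.rif/.cif) are rejected;
  events travel as multi-page TIFF with channel names and pixel size in a
  JSON image description, configuration pixel size winning over metadata
  (logged).
- Validation sizes: the test suite uses cohorts of 20–200 events at
  64×64 px, 100 random masks up to 64×64 for the erosion oracle, and 2000
  simulations for the ANOVA type-I-error check — sizes at which the checked
  tolerances (±0.05 fraction recovery, 3.5–6.5% rejection band) are
  well-resolved while the suite stays fast.

## Known limitations

- The erosion depth is a single global constant; cells much smaller than
  2·d lose their interior entirely (flagged `internal_mask_empty`).
- The brightfield segmenter is a global-threshold method for one cell per
  frame; crowded scenes need watershed or learned segmentation, which are
  out of scope.
- IS depends on ε at very low signal; compare scores only at a fixed ε.
- The quench model attributes the full MFI drop to surface signal; dye
  uptake by compromised cells would bias internalized% downward.
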