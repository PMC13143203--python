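# Methods

## Segmentation model

Each channel of a confocal z-stack is treated as an independent 3D intensity
field containing bright, roughly spherical nuclei over a dark background.
Because clustered nuclei cannot be reliably separated into instances,
segmentation produces a single voxel mask per channel and proliferation is
reported as a volume ratio (EdU⁺ voxels / DAPI⁺ voxels), not a cell-count
ratio. This is unbiased for the label fraction exactly when labeled and
unlabeled nuclei have the same volume distribution and both channels segment
each nucleus with the same effective boundary — see *Bias of the voxel-ratio
estimator* below for when that fails.

The chain per channel, in voxel units throughout:

| stage | operation | parameters (default) |
|---|---|---|
| 1 | min–max normalization to [0, 1] | — |
| 2 | 3D median filter | window 3, mirror padding |
| 3 | truncated separable Gaussian | kernel 5×5×5, σ = 0.5 voxels, mirror padding |
| 4 | grayscale erosion → marker | discrete ball, radius 3 voxels (123 offsets) |
| 5 | reconstruction by dilation under the filtered volume | connectivity 26 (6/18 selectable) |
| 6 | Otsu level on a fixed 256-bin histogram of [0, 1] | tie-break: mean of maximizing cuts |
| 7 | binarize `v > f·t*` (strict) | f = 0.5 nuclear, 0.2 proliferation |

### Numerical choices

* **Normalization degenerate rule.** A constant (blank) channel maps to all
  zeros instead of raising, so a negative-control channel flows through the
  pipeline and produces an empty mask (Otsu level 0, strict threshold).
* **Padding.** Both filters use mirror (symmetric) padding; zero padding
  would create dark rims that drag the histogram threshold down. Erosion
  ignores out-of-bounds voxels (+∞ padding), the standard convention for
  flat erosion on finite domains; borders are therefore not darkened.
  Erosion computes in float64 (exact for integer intensities up to 2⁵³) and
  casts back to the input dtype.
* **Gaussian σ.** The filter size (5×5×5) is fixed by the pipeline
  definition; σ is not, and defaults to 0.5 voxels — the conventional
  default for a gaussian-filter call of this kind — and is recorded in every
  quantification record for provenance.
* **Otsu histogramming.** Values in [0, 1] are assigned to 256 equal-width
  bins; the level is the lower edge of the upper class's first bin. When
  several cuts tie for maximal between-class variance (e.g. a perfectly
  bimodal volume at 0 and 1), the mean of the tying cut positions is
  returned, which is deterministic and matches the behavior of the classic
  fixed-bin implementations of the method.
* **Threshold source.** The Otsu level is computed on the reconstructed
  volume by default (the last processing product before segmentation); a
  `threshold_source="filtered"` switch thresholds the pre-erosion filtered
  volume instead, since the processing order admits either reading. The
  choice is recorded in the segmentation result.
* **Marker/mask roles are fixed:** the marker is always the eroded filtered
  volume and the reconstruction mask the filtered volume; this ordering is
  part of the pipeline definition and not configurable.

No claim of numerical parity with any particular prior implementation on
its own data is made: padding modes and Gaussian σ are documented contracts
of this package, chosen as above.

## Scores

* **Two-bottle preference** = 100 · V_tastant / (V_tastant + V_water) over
  the 48 h test (volumes summed across the side-switched halves); 50 is the
  no-preference line. Clamped to [0, 100] against floating-point overshoot.
* **Lick ratio** = mean licks across eligible tastant trials at one
  concentration / mean licks across eligible water trials, pooling trials
  over the two testing days (a per-day-ratio-then-average variant is behind
  a non-default flag). First-block exclusion defaults on for the sweet
  tastant panel only, where the water-deprived state drives maximal licking
  in block 1 regardless of solution; the thirst metric (first-block total
  licks averaged over the two days) quantifies that motivational state.
* **ΔΔCt**: per sample, ΔCt = Ct(target) − Ct(housekeeping); ΔΔCt = ΔCt −
  arithmetic mean of control-group ΔCt; fold = 2^(−ΔΔCt). Control folds have
  unit geometric mean by construction. Replicate collapsing (well-level vs
  sample-level) is left to the caller: the table carries one Ct per
  (sample, gene).
* **Mouse-level summaries** average counting units (taste bud profiles,
  organoids) within mouse first; condition summaries are mean ± s.e.m. over
  mouse means with the sample (n−1) standard deviation, because the mouse is
  the experimental unit. Single-mouse conditions report s.e.m. as NaN.
* **Marker-count categories** {0, 1–9, ≥10} return fractions that sum to 1
  exactly (the last bin is the complement of the first two).

## Synthetic data

`simulate_organoid_stack` renders equal-radius hard spheres (unambiguous
ground-truth volume) at uniform foreground intensity over a low background,
packed by rejection sampling with pairwise center distance ≥ 2r, then
applies a Gaussian blur (the optical PSF in voxel units) and additive
Gaussian noise with sd = (foreground − background)/SNR, quantized to uint16.
The EdU channel renders a random subset of round(n·edu_fraction) nuclei
identically. Every generator is a pure function of its parameters and seed,
and the ground-truth manifest serializes to JSON.

Defaults: shape (34, 384, 384) — a thin slab holding one organoid plane —
60 nuclei of radius 13 voxels, EdU fraction 0.3, SNR 20, blur σ = 0.3,
background 2% of signal. The geometry corresponds to ~10 µm nuclei sampled
at ~0.4 µm/voxel, i.e. well-resolved confocal imaging.

### Bias of the voxel-ratio estimator

The two channels are thresholded at different fractions of their Otsu level
(0.2 vs 0.5), so around every labeled nucleus the EdU mask extends further
down the blurred edge profile than the DAPI mask does — about Δr ≈ 0.6
voxels further at these settings. The measured ratio is inflated by roughly
(1 + Δr/R)³ ≈ 1 + 3Δr/R for nucleus radius R. Recovering a label fraction
of 0.3 to within ±0.05 therefore requires R ≳ 12 voxels; the default
radius 13 gives a measured ratio ≈ 0.345 for a true fraction of 0.300,
stable across seeds. With poorly resolved nuclei (R ≲ 9) the same pipeline
overshoots the tolerance (ratio ≈ 0.36), which is a property of the method,
not of the simulation: the factor asymmetry buys sensitivity to dim EdU
nuclei at the cost of a resolution-dependent halo bias.

### What the generator does not model

Anisotropic voxels (real stacks have ~2 µm optical sections against
sub-micron pixels; the pipeline operates in voxel units either way), a
realistic PSF (single isotropic Gaussian instead), intensity variation
between nuclei, organoid lumen/shell geometry, photobleaching, and
autofluorescence. Passing recovery tests on this generator therefore shows
the chain is implemented correctly and is volumetrically calibrated for
well-resolved data; it does not certify accuracy on anisotropic or
low-contrast acquisitions, where the field practice of visually
inspecting each segmentation against the raw stack remains necessary. In
particular, a channel containing only noise (no labeled structure at all)
is stretched to full range by normalization and segmented into a large
spurious mask — such channels must be caught by inspection; only a truly
constant (blank) channel degenerates safely to an empty mask.

`simulate_lick_session` draws Poisson lick counts per 5 s presentation with
one mean per bottle, each block presenting every bottle once in random
order; `simulate_ct_table` shifts the treated group's target Ct by −log2FC
(one PCR cycle per doubling) around fixed baselines with Gaussian Ct noise.

## Problem sizes used in the test suite

Oracle-equivalence checks run each image primitive against naive
brute-force implementations on 100 random volumes up to 8×8×8 (half
integer-valued, compared exactly; half float, at 1e−9). End-to-end recovery
runs the full default simulation (60 nuclei, 10 seeds, ~5M voxels per
stack), the package's chosen desk-scale reference condition; it completes
in a few minutes on one CPU, with grayscale reconstruction the dominant
cost. Unit fixtures use 3–20 nuclei in 48–128-pixel fields.

## Known limitations

* No nucleus instance separation — by design; the output is voxel volume.
* The EdU/DAPI ratio can exceed 1 on pathological inputs (e.g. EdU noise
  segmented against a tiny DAPI mask); records preserve whatever the masks
  give and leave QC to the caller.
* Dimension-order inference for plain TIFF without axis metadata assumes
  (z, c, y, x) for 4D payloads; use the explicit `axes=` override for files
  that deviate.
* `PolygonROI` accepts only simple polygons; self-intersecting freehand
  outlines are rejected rather than repaired.
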