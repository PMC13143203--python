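# organoquant

Volumetric quantification of proliferation in lingual organoids, plus the
behavioral and qPCR scores used to phenotype taste function in mice.

## The problem

Lingual (taste) organoids are imaged as multichannel confocal z-stacks: a
DAPI channel marking all nuclei and an EdU channel marking nuclei that were
in S phase during a labeling pulse. Nuclei in an organoid are tightly
clustered and cannot all be separated into instances, so proliferation is
quantified **volumetrically**: each channel is segmented independently into
signal and background, and the readout per organoid is

```
ratio = |EdU-positive voxels| / |DAPI-positive voxels|
```

i.e. the total EdU⁺ nuclear volume as a fraction of total nuclear volume.

The per-channel segmentation chain is:

1. **Normalize** the channel to [0, 1] against its own extrema.
2. **Denoise** with a 3×3×3 median filter, then a 5×5×5 Gaussian
   (σ = 0.5 voxels), both with mirror padding.
3. **Enhance contrast** by grayscale morphological reconstruction: erode the
   filtered volume with a discrete ball of radius 3 voxels to form the
   marker, then reconstruct the filtered volume from it by iterated
   conditional dilation (26-connected) to a fixed point. This levels small
   bright peaks while preserving nucleus-scale structure.
4. **Threshold** with a factor-scaled Otsu: compute the classic
   between-class-variance-maximizing level *t\** on a fixed 256-bin histogram
   of [0, 1], then binarize at `v > f·t*` with `f = 0.5` for DAPI and
   `f = 0.2` for EdU. The permissive EdU factor captures dim, partially
   labeled S-phase nuclei; the same factors are used for every stack.

The package also implements the surrounding quantitative procedures: taste
bud profile morphometry (maximum z-projection, polygon area in µm²),
marker-count categorization (0 / 1–9 / ≥10 cells per organoid), per-mouse
averaging with mean ± s.e.m. over mice, the 48 h two-bottle preference score
`100 · V_tastant / (V_tastant + V_water)`, the brief-access lickometer lick
ratio (mean licks to tastant / mean licks to water, first block excluded for
the sweet panel), and ΔΔCt relative qPCR quantification against *Rpl19*.

A synthetic-data module generates ground-truthed organoid stacks (packed
hard-sphere nuclei, optical blur, sensor noise), lickometer sessions
(Poisson licks), and Ct tables (known log2 fold changes), so every stage is
verifiable without any imaging data.

## Worked example

```python
from organoquant import (
    simulate_organoid_stack, segment_channel, ChannelParams, QuantRecord,
)

stack, truth = simulate_organoid_stack(
    shape=(24, 96, 96), n_nuclei=12, nucleus_radius=6.0,
    edu_fraction=0.25, snr=20.0, seed=7,
)
dapi = segment_channel(stack, "DAPI", ChannelParams.nuclear())
edu = segment_channel(stack, "EdU", ChannelParams.proliferation())
rec = QuantRecord.from_masks("demo", edu.mask, dapi.mask)
```

prints (via the fields of `dapi`, `edu` and `rec`):

```
true EdU fraction      : 0.250
DAPI otsu level        : 0.3965 -> threshold 0.1982
EdU  otsu level        : 0.4199 -> threshold 0.0840
DAPI+ voxels           : 11266
EdU+  voxels           : 3764
EdU+/DAPI+ voxel ratio : 0.3341
```

A quarter of the 12 equal-size nuclei are EdU-labeled, and the voxel ratio
estimates that fraction. The estimate (0.334) sits above the true 0.25
because the permissive EdU factor (0.2 vs 0.5) segments a slightly wider
halo around each labeled nucleus; the bias shrinks as nuclei become larger
relative to the optical blur (see `docs/methods.md`). At the default
simulation scale (radius-13 nuclei), the recovered ratio is within ±0.05 of
the true label fraction.

The same workflows are available from the shell:

```sh
organoquant simulate --kind stack --params '{"n_nuclei": 20}' --seed 1 --out sim
organoquant quantify-edu --input sim.ome.tif --out report.csv --save-masks masks/
organoquant score --kind ddct --input ct.csv --target-gene Lgr5 --out folds.csv
```

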