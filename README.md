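# fishpol

Quantification of mRNA polarity in single cells from FISH images.

Polarized, chemotaxing cells can localize specific transcripts toward
their rear. `fishpol` measures that asymmetry from 2D fluorescence
microscopy (maximum-intensity projections of single-molecule FISH
channels, plus a matching protein channel), for cells whose boundary is
too ill-defined for contour-based segmentation: instead of tracking the
outline precisely, it bisects each cell into an anterior and a
posterior region of interest about the nucleus and counts mRNA in each
half. It is aimed at cell-biology groups analysing transcript
localization in migrating cells (the motivating system is
*Dictyostelium discoideum* streaming toward an aggregation centre), and
ships a synthetic-scene generator with exact ground truth so the whole
pipeline is testable without any raw data.

## Method

**The mRNA unit.** Diffraction-limited FISH spots are detected as local
maxima, and isolated spots are fit to an isotropic Gaussian point-spread
function, I(r) = B + A·exp(−r²/2σ²). Both fit-parameter distributions
are thresholded from above until they are unimodal; the means of the
surviving distributions define the characteristic unit (amplitude A_u,
width σ_u) with integrated intensity

&nbsp;&nbsp;&nbsp;&nbsp;I_u = 2π · A_u · σ_u².

A unit is the smallest recurring spot, likely a small cluster of
transcripts rather than one molecule; all counts are denominated in
units, not molecules.

**Two count estimators per ROI.**

* *Linear:* integrated background-subtracted intensity inside the ROI,
  divided by I_u.
* *Simulated:* the image is rebuilt one unit PSF at a time — each
  placement near the current residual maximum, kept only if the sum of
  squared differences (SSD) to the original strictly decreases — and the
  stochastic rebuild is repeated to give a mean per-ROI placement count
  and an average reconstructed image. The rebuild stays reliable where
  punctae overlap and the linear readout merges into a blob.

**Geometry.** Each cell is cut by the line through the nucleus centroid
perpendicular to the nucleus→aggregation-centre direction; the half
toward the aggregation centre is the anterior. Cell polarization is the
eccentricity of the equivalent-inertia ellipse of the outline,
ε = √(1 − b²/a²) (0 = round/non-polarized, → 1 = elongated/polarized).

**Statistics.** Anterior vs posterior unit counts are compared by
t-test (Welch by default; a paired per-cell variant is available and is
the calibrated choice, since the two halves of one cell share its
total). Summaries use median-centred boxes: a 50% and a 99%
distribution-free (order-statistic) confidence region for the median,
with points beyond the 99% region flagged as outliers. The
protein channel is summarised by its posterior intensity fraction and
correlated (Pearson) with the mRNA posterior fraction, per cell and
across stream-position group means.

## Worked example

Run the full pipeline on a synthetic 12-cell stream cohort whose mRNA
posterior fraction rises from 0.5 (beginning of stream) to 0.7 (end),
with a protein channel that co-polarizes:

```python
from fishpol import RunConfig, run_pipeline

cfg = RunConfig(
    n_cells=12, master_seed=7, n_reps=5, scene={"n_spots": 40},
    protein_fraction_by_position={"beginning": 0.5, "middle": 0.6, "end": 0.7},
)
res = run_pipeline(cfg, "out/")
```

which simulates the cohort, calibrates the unit from ~185 isolated
spots pooled across the images, bisects every cell, runs both
estimators and prints/writes (records.csv, unit.json, stats.json):

```
unit: A_u=118.3  sigma_u=1.43 px  I_u=1510  (n=185)
beginning n= 4  posterior fraction=0.505  t=-0.19  p=0.857
middle    n= 4  posterior fraction=0.552  t=-2.52  p=0.0452
end       n= 4  posterior fraction=0.722  t=-5.88  p=0.0011
overall linear:    t=-3.72  p=0.00121  posterior fraction=0.593
overall simulated: t=-4.74  p=0.000101  posterior fraction=0.619
pearson r (position means): 0.95   per cell: 0.76
```

The generator's true unit has A = 120 and σ = 1.5 px, so the
calibration is recovering the unit to a few percent under shot + read
noise. The estimated posterior fraction climbs along the stream as
designed, the anterior−posterior t statistic is negative (posterior
excess) and significant where the enrichment is strong, and the
mRNA–protein posterior fractions correlate strongly across position
means because the protein was made to track the transcript.

The same stages are available as a CLI:

```sh
fishpol simulate  --config scene.yaml --out sim/ --seed 5
fishpol calibrate --image sim/cell_0000_mrna.tif --mask sim/scenes.geojson --out unit.json
fishpol bisect    --rois sim/scenes.geojson --out halves.geojson
fishpol estimate  --image sim/cell_0000_mrna.tif --rois halves.geojson \
                  --unit unit.json --reps 10 --seed 7 --out counts.csv
fishpol stats     --records records.csv --by stream_position --out stats.json
fishpol run       --config config.yaml --out out/ --seed 7
```

## Scope

The package consumes 2D projections; 3D stacks, deconvolution,
automated segmentation from phase contrast, and decomposition of units
into single transcripts are out of scope. See `docs/methods.md` for the
model, parameter defaults, numerical choices and known limitations.
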