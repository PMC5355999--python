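# aggsplit

Sizing and partitioning of red-blood-cell (RBC) aggregates in a T-junction
microchannel, from brightfield image stacks and PIV velocity fields.

At low shear, RBCs stack into rouleaux and clusters whose size distribution
shapes local blood viscosity. In a bifurcating microvessel-scale flow the
aggregates partition unevenly between the daughter branches: larger
aggregates concentrate near the flow centreline, so near-wall fluid —
which is what a low-flow daughter branch drains — is depleted of them.
`aggsplit` is an analysis pipeline for quantifying that phenomenon, with a
ground-truthed synthetic scene generator so every stage can be verified
without laboratory data. It is aimed at microfluidics and haemorheology
groups doing image-based aggregate quantification.

## What it computes

* **Aggregate detection** — calibrated gradient edge detection: local
  intensity gradients from the four opposite-neighbour pairs of a 3x3
  window (dS = 1.30 um horizontal/vertical, 1.61 um diagonal at
  0.65 um/px), normalized by the local mean intensity, optionally
  corrected for locally blurred regions via a coefficient-of-variation
  reference map, thresholded at a value calibrated so the mean structure
  area in a non-aggregating reference equals the characteristic RBC area
  A_c = 15 um^2, with components below 0.2 A_c discarded as noise.
  Output: per-structure areas A (um^2), normalized sizes A* = A/A_c, and
  normalized centroids.
* **Size statistics** — left-truncated exponential fits of A* by weighted
  least squares on the log empirical survival, reported as MV[LB, UB]
  (bounds replaced by primed truncation values where truncated) with
  percentile-bootstrap intervals; per-frame means, SD over frames, pooled
  SD; spatial distributions; wall-margin locations x*_A* (mean of the 5%
  near-wall tail); haematocrit profiles from light transmission
  (H = alpha(1 - I*) linear, H = a(1 - I*^b) non-linear with a = 0.685,
  b = 9.244); pseudo-shear U/D.
* **Flow split** — normalized-median validation of gridded velocity
  fields, flow ratios Q* = U_D/U_P, streamline tracing (RK4), and the
  flow-split location x*_fs by bisection of seed streamlines against an
  independent cumulative-flux oracle.
* **Partitioning** — the admitted-size rule: size A* enters the low-flow
  daughter iff its wall-margin location lies beyond x*_fs toward that
  daughter's wall; plus the end-to-end synthetic Q* sweep relating the
  daughter/parent mean-size ratio and the size-flow parameter
  F*_A* = Q* x A*_ratio to the flow ratio.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
scenes (full 1216 x 700 px frames, 100 um channel, seeds fixed in the
scripts); each writes tables under `results/`.

```
python analysis/01_generate_scenes.py
python analysis/02_detect_aggregates.py
python analysis/03_size_statistics.py
python analysis/04_flow_split.py
python analysis/05_partition_sweep.py
```

`02` calibrates the threshold on a dispersed-cell reference and detects
aggregates in a 50-frame aggregating stack whose true mean size is
A* = 1.99:

```
calibrated threshold 0.8401 (mean structure area 15.19 um^2, target 15.0)
detected 3735 structures (truth 4009); mean A* 1.930 vs true 1.986 (-2.9%)
```

`03` fits the size distribution (left-truncated at A* = 0.5; primed bound):

```
size distribution (k = 3683): mean A* = 1.91[0.50', 1.96] (rate 0.710)
restricted to A* > 3 (k = 618): mean A* = 4.70[3.00', 4.86]
ensemble over 50 frames: mean 1.928, SD over frames 0.165, pooled SD 1.560
```

A mean A* near 2 means the average detected structure is about twice the
projected area of a single RBC; the A* > 3 restriction isolates genuine
multi-cell aggregates. `05` runs the Q* sweep; its per-branch table shows
the partitioning signature — the low-flow branch at Q* = 0.1 receives a
*smaller* mean size than the parent (near-wall fluid is depleted of large
aggregates), while branches above Q* ~ 0.2 run 10-20% above it:

```
 qstar_right daughter  qstar_daughter  ratio     F
        0.10    right            0.10  0.849 0.085
        0.20    right            0.20  1.011 0.202
        0.35    right            0.35  1.111 0.389
        0.50    right            0.50  1.171 0.585
        0.50     left            0.50  1.135 0.567
```

with wall margins shrinking toward the centreline as size grows
(x*_A = 0.43 at A* = 1 down to ~0.27 at A* = 7), and admitted-size sets per
flow ratio (at Q* = 0.1 only A* <= 4 reach the low-flow branch; at
Q* = 0.5 every size does).

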