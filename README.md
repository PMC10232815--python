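# ectflow

Voxel current-flow modelling of electroconvulsive therapy (ECT) electrode
montages, built to answer one question: **how much of the body must a
volume-conductor model include before the predicted stimulation metrics stop
changing?**

MRI-guided forward models of ECT are limited to whatever axial coverage the
scan provides, so published models truncate the body at very different
levels. `ectflow` simulates the electric field induced by the two standard
clinical montages — right unilateral (**RUL**: one disc 2.5 cm right of the
vertex, one at the right frontotemporal position) and bilateral (**BL**:
both frontotemporal positions) — on a parametric head–neck–torso phantom,
truncates the model to five fields of view (upper head ⊃ whole brain, full
head, neck, torso, full body), and quantifies how the truncation changes
stimulation strength, laterality, and focality. It is a library for
researchers in computational neurostimulation / brain-stimulation dosimetry,
with a small CLI for batch runs.

## Model

Tissue is a passive volume conductor in the quasi-static regime, so the
potential obeys

```
∇·(σ ∇V) = 0
```

with isotropic conductivities σ per tissue (S/m): skin 0.465, skull 0.01,
CSF 1.65, grey matter 0.276, white matter 0.126, muscle/soft tissue 0.35,
gel 1.4, electrode metal 5.9·10⁷. Current `I` enters at the anode disc, the
cathode disc is grounded (V = 0), and all other exterior surfaces are
insulated. The equation is discretised by a cell-centred finite-volume
scheme on the voxel grid (face conductance = harmonic mean of the two
voxels' σ times face-area/spacing), the metal discs are treated as
equipotential terminals, and the resulting sparse SPD system is solved with
conjugate gradients under a smoothed-aggregation multigrid preconditioner.
The field is recovered as `E = −∇V`.

From `|E|` in the brain the package computes the standard dosimetry metrics:

- **stimulation strength** `E/E_th`, with neural activation threshold
  `E_th` = 25 V/m (ultra-brief pulse) or 21 V/m (brief pulse), and a
  *robust* threshold 1.4·`E_th`;
- the **99th-percentile peak** of `E/E_th` over the brain;
- the **relative error** of a truncated extent X against the full-body
  reference, `RE = (M_X − M_FB)/M_FB × 100 %`;
- the **laterality ratio** median right- / left-hemisphere `|E|`;
- **focality**: percent of brain volume with field at or above a threshold.

Because the field is linear in `I`, each geometry is solved once and the
100–900 mA amplitude range is obtained by scaling.

## Worked example

`examples/03_fov_experiment.py` runs the full design (2 montages × 5
extents, one solve each) on a small phantom and prints, at 100 mA with the
ultra-brief threshold:

```
montage        fov  p99_strength  re_pct  laterality
    RUL upper_head        1.5729  0.6201      1.4341
    RUL  full_head        1.5653  0.1313      1.4267
    RUL       neck        1.5633  0.0016      1.4274
    RUL      torso        1.5633  0.0000      1.4275
    RUL  full_body        1.5633  0.0000      1.4275
     BL upper_head        1.6024  1.8398      1.0000
     BL  full_head        1.5783  0.3099      1.0000
     BL       neck        1.5735  0.0037      1.0000
     BL      torso        1.5734  0.0000      1.0000
     BL  full_body        1.5734  0.0000      1.0000
```

Reading the numbers: the 99th-percentile stimulation strength falls
monotonically as more body is modelled (a truncated model overestimates the
brain field because injected current has nowhere to escape inferiorly); the
BL montage, whose electrodes sit low on the head, is hit hardest by the
upper-head truncation (RE 1.84 % vs 0.62 % for RUL on this phantom); BL's
laterality is exactly 1 by symmetry while RUL lateralises to the right
(≈1.43). On real MRI-derived anatomy the same orderings hold with much
larger BL errors; the absolute values depend on the anatomy.

The other examples build phantoms (`01`), solve and summarise a single
montage (`02`), and run the published-table desk checks (`04`).

A typical library session:

```python
from ectflow import (PhantomParams, build_phantom, truncate_fov, FOVLevel,
                     place_electrodes, solve_montage, ConductivityTable)

params = PhantomParams()                      # 2 mm adult-head defaults
vol = truncate_fov(build_phantom(params), FOVLevel.FULL_HEAD)
vol, montage = place_electrodes(vol, "RUL", current_mA=800.0, params=params)
solution, imbalance = solve_montage(vol, montage, ConductivityTable())
```

The CLI mirrors the library:
`ectflow build-phantom | solve | metrics | run-experiment | make-fixtures`.

## Output data dictionary

`run_experiment(config, output_dir=...)` writes:

| file | contents |
|---|---|
| `metrics_long.csv` / `.json` | one row per montage × extent × amplitude × threshold: `p99_strength`, `focality_pct`, `laterality`, `re_pct` |
| `p99_RUL.csv`, `p99_BL.csv` | p99 `E/E_th` grids, rows = amplitude (mA), columns = extent |
| `re_table.csv` | relative error (%) vs the full-body reference |
| `laterality_table.csv` | right/left median `|E|` ratio per montage × extent |
| `focality_curves.csv` | focality traces labelled `RUL_25`, `BL_25`, `BL_21` (brief-pulse BL), `..._35` (robust) |
| `manifest.json` | config hash, per-solve diagnostics (unknowns, iterations, residual, current imbalance), file list |

Label volumes are NIfTI-1 integer images with a JSON sidecar carrying the
truncation planes; field volumes are NIfTI-1 float.

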