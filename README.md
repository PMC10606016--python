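# bruisemap

Quantitative analysis of drop-impact fruit bruising from two complementary
observables:

1. **Array-pressure-sensor recordings** (40 × 40 grid, 1.9 mm pitch, 60 fps by
   default) of a free-falling hammer impact.  From the total force history the
   package reconstructs the hammer's per-frame velocity and displacement
   (`V_1 = sqrt(2 g h)`, impulse bookkeeping thereafter) and maps the absorbed
   impact energy `E(i, j)` onto every sensing point.
2. **Stained tissue-section micrographs** of the bruised region.  The
   sub-surface band of dead cells ("death zone") stains strongly, so it is
   segmented on the HSV saturation channel (threshold → opening/closing →
   largest connected component → hole filling), the peel surface is traced,
   and per-lateral-position depth and width profiles are measured — including
   the discontinuity convention (centre = midpoint of the two outermost run
   boundaries, width = summed run lengths).

The two profiles are registered at sensor pitch and correlated (Pearson r of
depth vs energy and width vs energy), with optional exclusion of sensing
points whose peak force never reached the tissue's biological yield force
(8.75 N), and summarised per drop height.

Because no raw experimental recordings are distributed, a first-class
synthetic-data module generates all inputs with exact ground truth: a
spring/damper contact simulator with a Hertzian footprint emits frame stacks
and fine-timestep work maps, a cell-mosaic renderer produces stained-section
images with programmed band geometry, and coupled samples tie band depth to
the energy profile with height-dependent noise.

## Layout

| module | role |
| --- | --- |
| `bruisemap.pressure_io` | read/write/calibrate/trim frame stacks |
| `bruisemap.energy_reconstruction` | kinematics, energy map, axial energy profile |
| `bruisemap.section_imaging` | saturation channel, death-zone segmentation, peel tracing |
| `bruisemap.damage_metrics` | column run-lengths, depth/width profiles, resampling |
| `bruisemap.correlation_analysis` | registration, Pearson r, yield masking, height summaries |
| `bruisemap.synthetic_data` | impact simulator, section renderer, coupled samples |
| `bruisemap.cli_pipeline` | single-sample/batch/study orchestration + CLI |

## CLI

```sh
# generate a synthetic coupled sample (frames.csv, section.tiff, truth.json)
bruisemap simulate --height 0.125 --seed 4 --out sample/

# reconstruct the energy map/profile from a frame stack
bruisemap energy sample/frames.csv --height 0.125 --out energy/

# segment a section image and measure the damage profile
bruisemap segment sample/section.tiff --out seg/

# full single-sample pipeline from a YAML config
bruisemap analyze --config run.yaml

# synthetic multi-height correlation study
bruisemap study --heights 50,125,200 --n-per-height 20 --seed 1 --out study/
```

All runs are deterministic under a fixed seed; re-running a study with the
same config produces byte-identical outputs.

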