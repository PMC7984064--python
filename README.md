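# pinclust

Quantification of plasma-membrane protein clustering in plant cells, for
microscopists studying polarly localized cargo such as the PIN auxin
transporters of the *Arabidopsis* root epidermis. The package implements
three complementary measurement pipelines plus seeded synthetic-data
generators that make every stage testable without original micrographs.

## What it computes

**Confocal cluster densities.** Membrane ROIs cut from a 3D stack
(default voxel size 0.089/0.089/0.313 µm, x/y/z) are reduced to
maximum-intensity projections. Clusters are detected *without any intensity
threshold*: a pixel is a cluster candidate if it is the strict maximum of
its 3×3 neighbourhood, and its size class is found by dilating square
windows — (2n+1) × (2n+1) pixels for radius *n* — until some pixel outranks
the peak. The largest passing radius gives the size class
`side_px = 2·n_max + 1`, converted to µm by the lateral pixel size
(5 px → 0.445 µm, 9 px → 0.801 µm). Calls with size classes from 5 to
9 px are retained, and the cluster density is the retained count divided by
the brightness-thresholded membrane area:

```
density = n_retained / area_membrane   [µm⁻²]
```

**Immunogold clustering statistics.** Gold-particle coordinates (nm) from
freeze-fracture replica labeling or thin-section immunogold images are
partitioned by single linkage: particles joined whenever a chain of
centre-to-centre distances ≤ 55 nm connects them. Groups of 1 / 2 / ≥3
particles are *scattered* / *doublets* / *clusters*; class fractions are
percentages of particles. Per polar domain — within 2 µm of the apical
edge, a 2-µm band on the midline, within 2 µm of the basal edge — the
package reports particle and cluster densities, class fractions, Feret
cluster diameters and the particles-per-cluster gradient along the
apical–basal axis.

**Polarity index.** The apical-to-lateral ratio of mean membrane ROI
intensities, per cell, aggregated as mean ± SD across cells.

**Statistics.** Two-sided Mann–Whitney U (exact null for small samples)
and t-tests, with mean ± SD summary tables and configurable significance
stars.

## Worked example

```python
import numpy as np
from pinclust.datatypes import MembraneROI
from pinclust.synthetic_data import single_face_stack_params, simulate_membrane_stack
from pinclust.confocal_cluster import quantify_roi

params = single_face_stack_params(cluster_density_per_um2=0.19, seed=1)
stack, truth = simulate_membrane_stack(params)
roi = MembraneROI(id="face", bounds_zyx=((0, 16), (0, 192), (0, 192)), projection_axis="z")
result, calls = quantify_roi(stack, roi, area_threshold=0.5, drop_low_contrast=True)
print(f"planted {truth.planted_counts[0] / truth.face_areas_um2[0]:.3f} /um2, "
      f"estimated {result.density_per_um2:.3f} /um2 "
      f"({result.n_retained} retained calls on {result.membrane_area_um2:.1f} um2)")
```

prints

```
planted 0.192 /um2, estimated 0.127 /um2 (37 retained calls on 291.9 um2)
```

i.e. a membrane sheet planted with 0.19 clusters/µm² is simulated, projected
and quantified; single-seed estimates scatter around the planted density
(this one is low; the 10-seed mean recovers it within ±30%, see the
recovery tests). The same round trip exists for point patterns:

```python
from pinclust.synthetic_data import polar_marker_field_params, simulate_particle_field
from pinclust.particle_analysis import link_particles, classify_particle_groups

particles, truth = simulate_particle_field(polar_marker_field_params(seed=1))
counts = classify_particle_groups(link_particles(particles))
print(f"clustered particles: truth {truth.class_fractions['cluster']:.1f}% "
      f"recovered {counts['fractions_percent']['cluster']:.1f}%")
```

prints `clustered particles: truth 53.9% recovered 52.4%`.

## Command line

One entry point with subcommands mirroring the stages:

```
pinclust simulate-stack   --config sim.yaml --out run/
pinclust simulate-particles --config field.yaml --out run/
pinclust confocal-quant   --stack run/stack.tif --min-side 5 --max-side 9 --out quant/
pinclust frl-quant        --particles p.csv --geometry g.json --dmax 55 --band 2.0 --out frl/
pinclust iem-quant        img1.csv img2.csv --dmax 55 --out iem/
pinclust polarity         --stack s.tif --rois rois.json --out pol/
pinclust report           --input values.csv --control ctrl --test mann-whitney --out rep/
pinclust run              --config pipeline.yaml
```

Every output directory receives a `provenance.json` with the config hash
and seed; identical config + seed reproduce identical tables.

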