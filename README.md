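# mrdistort

Quantitative analysis of implant-induced geometric image distortion in MR
volumes of a grid-of-spheres reference phantom.

MR imaging near active cardiac implants (loop recorders, pacemakers, ICDs)
suffers from susceptibility artifacts: besides the signal void, B0
inhomogeneity displaces, deforms, shrinks/enlarges and re-shades anatomical
structures. `mrdistort` measures these effects with a phantom built from a
7 × 7 × 7 cartesian grid of water-filled spheres (40.17 mm diameter,
40 mm pitch, five central spheres omitted for the device). Every sphere is
segmented by a competing reaction–diffusion front evolution and described
by its gravity center, volume `V`, mean gray value `GV`, and out-of-round
measure

    ORM = R_M / R_m − 1,

where `R_M` / `R_m` are the means of the upper / lower 5th percentile of
the center-to-surface radii. Comparing each sphere against its homologous
sphere in an implant-free reference scan gives the comparative metrics

    dCL = |c_d − c_r|        (center displacement, mm)
    dV  = (V_d − V_r) / V_r  (relative volume change)
    dORM = ORM_d − ORM_r     (roundness change)
    dGV = (GV_d − GV_r)/GV_r (relative gray-value change)

Repeat reference scans calibrate per-metric uncertainties (worst case over
balls and repeats); thresholds are twice the uncertainties, and the
**critical radius** `Rcr` of a metric is the largest isocenter distance of
an affected ball center plus the 20 mm nominal ball radius — the extent of
the region around the implant where that distortion quality exceeds
scan-to-scan noise.

A built-in phantom rasterizer and dipole-field artifact simulator
(displacement along the readout axis, signal void, gray-value gain, seeded
noise) make the entire pipeline testable with known ground truth and no
scanner. See `docs/methods.md` for the model details and numerical
choices.

## Worked example

Simulate a reference scan and an implant scan with a dipole artifact, run
the full pipeline, and read off the summary:

```python
import mrdistort as md

spec = md.default_spec()                      # 338 spheres, 40 mm pitch
ref = md.rasterize(spec, spacing=2.0)         # synthetic reference volume

model = md.ImplantFieldModel(moment=3e5, displacement_scale=1.0,
                             readout_axis="x", b0_axis="y")
dist, truth = md.apply_distortion(ref, model) # implant scan + ground truth

def segment(vol):
    seeds = md.seed_from_grid(spec, vol)
    return md.describe_scan(vol, md.evolve(vol, seeds))

ref_balls, dist_balls = segment(ref), segment(dist)
records = md.compare_scans(ref_balls, dist_balls)
print(md.summarize(dist_balls, records))
rcr = md.critical_radius(records, "dCL", threshold=2.0)
print(rcr.radius_mm, len(rcr.affected))
```

Output (values printed by this exact script):

```
{'V_min_mm3': 29896.0, 'V_max_mm3': 37952.0, 'ORM_min': 0.09237166622367443,
 'ORM_max': 0.7359779162806348, 'dCL_max_mm': 3.718222395598333,
 'dV_max': 0.16075360900415953, 'dORM_max': 0.6376063770587965,
 'dGV_max': 0.011385490607847293, 'n_disappeared': 0.0}
76.60314522461242 6
```

Reading: the simulated implant displaces sphere centers by up to ≈3.7 mm,
deflates/inflates ball volumes by up to ≈16 %, and strongly deforms the
nearest spheres (dORM up to 0.64). The 6 balls displaced beyond the 2 mm
threshold all lie within 76.6 mm of the isocenter (56.6 mm to the farthest
affected center + 20 mm nominal ball radius) — the artifact is confined to
the implant's neighbourhood.

The same pipeline runs from the shell:

```bash
mrdistort simulate --out scans --moment 3e5
mrdistort analyze --ref scans/reference.nii.gz --dist scans/implant.nii.gz --out report
```

`report/` then holds `per_ball.csv`, `summary.csv`, `rcr.json` and a 3D
displacement plot.

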