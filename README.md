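# dmdlitho

Planning, calibration, virtual printing and quality control for **maskless
photolithography on a DMD-equipped microscope** — the workflow in which a
digital micromirror device (DMD) projects binary UV masks through a
microscope objective to cure photosensitive resin, building micron-scale
structures (micropatterns, mold masters, microfluidic chips) for cell
biology without a cleanroom or physical photomasks.

The package is for labs running (or evaluating) such a setup. Everything
runs with **no hardware**: jobs execute against a simulated driver, and a
virtual printer turns exposure plans into dose and cure maps.

## What it computes

- **Optics & dosimetry** (`dmdlitho.optics`) — projected DMD pixel size
  (FOV width / DMD columns, scaled between objectives by magnification
  ratio), field of view, depth of focus Δz = nλ/NA², LED and
  ON-pixel-fraction power models, and the exposure-dose chain
  E = P·t, D = E/A with its exact inverse t(D).
- **Spin-coat calibration** (`dmdlitho.spincoat`) — film thickness
  h(RPM) = a/√RPM + h₀, fitted by closed-form least squares; inversion
  RPM(h); layer constants c = h·√RPM and the multilayer stacking-error
  statistic 100·|c₁−c₂|/mean(c₁, c₂).
- **Tiling** (`dmdlitho.tiling`) — decompose a physical-units design mask
  into abutting DMD frames with serpentine-ordered stage positions;
  exposure-time calibration series; fiducial alignment by normalised
  cross-correlation.
- **Virtual printer** (`dmdlitho.simulate`) — accumulate dose per substrate
  cell under configurable Gaussian PSF blur and stage jitter, threshold to
  a cured structure, and generate synthetic QC grid images with exact
  ground truth.
- **Grid QC** (`dmdlitho.qc`) — the automated stitching-quality analysis:
  upscale → Otsu binarise → skeletonise → probabilistic Hough →
  classify/group/merge line segments → orientation and pitch statistics
  (mean, SD) per axis in μm.
- **Jobs & CLI** (`dmdlitho.config`, `jobs`, `cli`) — YAML-configured jobs
  executed against a driver contract (simulated driver included), with a
  `litho` command line: `litho optics`, `litho spincoat fit|rpm`,
  `litho plan`, `litho simulate`, `litho qc grid`, `litho run`.

## Worked example

```python
from dmdlitho import optics, spincoat, default_instrument
from dmdlitho.simulate import synth_grid_image
from dmdlitho.qc import analyze_grid

inst = default_instrument()          # 600x800 DMD, 395 nm LED @ 2.96 mW
area = optics.fov_area_mm2(0.702, inst.dmd)
p = optics.led_power(0.46, inst.light_source)
e = optics.exposure_energy(p, 83.0)
print(f"power at 46% LED: {p:.2f} mW")
print(f"energy over 83 ms: {e:.3f} mJ")
print(f"field area:        {area:.3f} mm^2")
print(f"dose:              {optics.energy_dose(e, area):.3f} mJ/mm^2")

c1 = spincoat.layer_constant(43.93, 120)
c2 = spincoat.layer_constant(spincoat.split_stacked_depth(69.77, 2), 210)
print(f"stacking error:  {spincoat.multilayer_error(c1, c2):.2f} %")

img, truth = synth_grid_image(pitch_um=50, n_lines=10, line_width_um=5,
                              jitter_sd_um=1.0, noise_sd=5,
                              pixel_size_um=2.0, seed=7)
print(analyze_grid(img, 2.0, upscale_factor=4, expected_pitch_um=50, seed=0))
```

prints

```
power at 46% LED: 1.36 mW
energy over 83 ms: 0.113 mJ
field area:        0.237 mm^2
dose:              0.478 mJ/mm^2
stacking error:  4.93 %
axis        n_lines  orient_mean_deg  orient_sd_deg  pitch_mean_um  pitch_sd_um
horizontal  10       0.000            0.000          49.889         1.269
vertical    10       0.000            0.000          49.889         0.928
```

Reading: a 46% LED setting delivers 1.36 mW at the sample; over 83 ms that
is 0.113 mJ spread across the 0.237 mm² projected field, a dose of
0.478 mJ/mm² — around the 0.5 mJ/mm² that cures typical consumer resins.
The stacking error says two spin-coated layers measured at different spin
speeds agree with the h ∝ RPM^(−1/2) law to within 4.93%. The QC table
reports, for a synthetic grid printed with 1 μm stage jitter, the detected
line counts, their angular deviation from each axis, and the measured grid
pitch: the mean is within a detection pixel of the nominal 50 μm and the
pitch SD (≈1 μm here) quantifies stitching accuracy.

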