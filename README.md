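# scatterfiber

Nerve-fiber orientation analysis from azimuthal scattering profiles, with
cross-modality validation on synthetic phantoms.

## The problem

Light and X-rays scattered by brain tissue carry the local nerve-fiber
architecture. In **scattered light imaging (SLI)** a section is illuminated
from 24 azimuths (15° steps, fixed polar angle θ = 45°) and every image pixel
yields an azimuthal intensity profile *I*(φ); in **scanning small-angle X-ray
scattering (SAXS)** the myelin sheath produces a Debye–Scherrer ring at
q = 2π/d (d ≈ 17.5 nm), whose intensity around the ring is again a profile
*I*(φ); and a **diffusion-MRI fiber orientation distribution (FOD)**,
expanded in even-degree real spherical harmonics up to ℓmax = 8, can be
sampled on the section plane in 5° steps to the same form. In all three
cases the in-plane fiber orientations are encoded in the *peaks* of the
cyclic profile, and — for SLI — the out-of-plane inclination α in the
*distance* Δ between paired peaks.

`scatterfiber` implements this common analysis core and everything needed to
validate it end to end:

* **Peak analysis** — cyclic peak detection with relative prominence
  filtering (peaks with prominence ≤ 8 % of the profile amplitude
  max − min are discarded), full width at half prominence, sub-bin parabolic
  refinement, pairing of peaks lying 180° ± 35° apart, and the orientation
  φ = circular mid-position of each pair mod 180° (± 90° for FOD profiles,
  whose lobes lie along rather than perpendicular to the fiber). Up to three
  crossing orientations per pixel.
* **Peak distance and inclination** — Δ ∈ [0°, 180°] for one- or two-peak
  profiles, and a pluggable monotone calibration curve Δ(α) (stand-in
  Δ = 180°·cos α shipped as CSV) with its inverse α(Δ).
* **Profile extraction** — scatterometry pattern assembly, 1°-segment
  azimuthal integration about the intensity maximum, SAXS ring detection
  (d = 2π/q) and 5°-segment integration in a q-band with center-symmetry
  gap completion, and band-limited spherical-harmonic sampling.
* **Cross-modality comparison** — block upsampling of coarse onto fine
  grids, axial signed differences in [−90°, 90°), crossing-aware minimum
  pairing, per-class histograms/medians, multi-orientation prevalence, FA
  gating and axial dot products of 3D orientation vectors.
* **Synthetic phantoms** — ground-truth sections with up to three fiber
  populations (φ, α, weight) per pixel, rendered into SLI stacks, SAXS
  frames and FOD coefficients with seeded noise.

## Worked example

```python
from scatterfiber import RunConfig, run_full_validation

report = run_full_validation(RunConfig(seed=1))
print(report["classes"]["one_orientation"]["median_abs_deg"])
print(report["classes"]["two_orientations"]["median_abs_deg"])
print(report["scatter"]["per_region_medians"])
```

This simulates a 64×64 section containing a unidirectional in-plane bundle
(φ = 70°) and a 60° crossing (φ = 40°/100°) with 1 % Gaussian noise, renders
the 24-azimuth SLI stack, extracts profiles, runs the peak analysis, and
compares the recovered orientation map with the ground truth. With seed 1 it
prints

```
0.9649058435693121
0.9817608191439433
[{'region': 1, 'median_alpha_deg': 0.0, 'median_delta_deg': 179.8306414300665}]
```

i.e. the recovered in-plane orientations deviate from the ground truth by a
median of ≈ 1.0° in both the unidirectional and the crossing region (well
inside the ± 2.4° accuracy of the 15°-step acquisition), and the
unidirectional in-plane region shows the expected peak distance Δ ≈ 180°.

The same pipeline is available from the shell:

```bash
scatterfiber run --seed 1 --out report/
scatterfiber simulate --config phantom.yaml --out sim/ --seed 1
scatterfiber extract --modality sli --in sim/sli_stack.tif --out profiles.h5
scatterfiber peaks --profiles profiles.h5 --out maps/
scatterfiber incline --maps maps/ --out inclination.tif
scatterfiber compare --fine maps/ --coarse maps/ --out cmp/
```

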