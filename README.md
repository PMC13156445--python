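# wfmp2rage

Simulation and quantification for a **water/fat-selective, radially encoded
MP2RAGE** sequence: a single free-breathing 3D acquisition that yields
water-specific T1, fat-specific T1 and proton-density fat fraction (PDFF)
maps of the abdomen.

Quantitative T1 and PDFF are biomarkers for fatty liver disease, pancreatic
and bone-marrow pathology, but infiltrated fat confounds conventional T1
mapping. Alternating water- and fat-selective binomial excitations inside
an MP2RAGE readout separates the two proton pools at acquisition time; this
package implements everything downstream of the scanner (and a forward
simulator to stand in for it):

- **Binomial pulses** — hard-subpulse trains with binomial-coefficient
  amplitudes; rotation-matrix Bloch simulation of the excitation
  efficiency ε(Δf) and the small-tip closed form
  ε = |cos(πΔfτ)|ⁿ⁻¹ (water) / |sin(πΔfτ)|ⁿ⁻¹ (fat).
- **Protocol & trajectory** — sequence timing (TR_eff = 2·TR, inversion
  times referenced to the train centres) and the 3D golden-means radial
  spoke schedule with 90°-rotated fat spokes and block-wise undersampling.
- **Signal model & LUT** — closed-form periodic steady state of the
  longitudinal magnetization; UNI = Re(S1·S2*)/(|S1|²+|S2|²); train-mean
  (radial) UNI-vs-T1 look-up tables over 100–3500 ms, including per-voxel
  effective-flip tables from B0/B1 maps.
- **Quantification** — voxel-wise T1 decode, ordinary-least-squares
  component amplitudes S0 = (f1·s1 + f2·s2)/(f1²+f2²), and
  PDFF = 100·S0_fat/(S0_fat+S0_water).
- **Phantom simulator** — a 14-vial digital agar/fat phantom (Gd-doped
  fat-free vials, 10–90% mixtures, pure fat) with complex Gaussian noise
  and seeded reproducibility.
- **Reference fits & statistics** — STEAM inversion-recovery T1 and T2
  decay fits, spectroscopy PDFF with T2 back-extrapolation, ROI summaries,
  Bland–Altman limits of agreement and normalized-difference quantiles.

## Worked example

```python
import numpy as np
from wfmp2rage import *

pulse = make_binomial_pulse(6, "water")          # 1-5-10-10-5-1, 4 deg
print(f"pulse duration: {pulse.total_duration*1e3:.2f} ms")
print(f"eps(200 Hz) = {excitation_profile(pulse, np.array([200.0])).efficiency[0]:.3f}")
print(f"min eps over 112-Hz water band = {band_extremum_efficiency(pulse, 0, 112):.3f}")

params = ProtocolParams()                        # abdominal protocol defaults
print(f"TR_eff = {derive_timing(params).tr_eff} ms, scan = {scan_duration(params)/60:.0f} min")

spec = default_vial_phantom(seed=7, snr=50.0)    # 14-vial digital phantom
images, truth = simulate_component_images(spec, params)
maps = quantify(images, params, default_pulses())
m, sd, n = roi_stats(maps.pdff, spec.compartment_masks()["mix_40pct"])
print(f"40% vial: PDFF = {m:.1f} +/- {sd:.1f} % (n={n})")
```

prints

```
pulse duration: 5.81 ms
eps(200 Hz) = 0.238
min eps over 112-Hz water band = 0.902
TR_eff = 20.2 ms, scan = 12 min
40% vial: PDFF = 40.2 +/- 2.5 % (n=576)
```

The pulse keeps ≥ 90% excitation efficiency across a 112-Hz water band
while leaking only 0.6% at the α-olefinic fat line; at SNR 50 the 40%-fat
vial's ROI mean lands within 0.2 percentage points of truth (the per-voxel
SD reflects the noise level, not a bias). In the same run the vial's water
T1 comes back as 2295 ± 242 ms (truth 2300) and fat T1 as 286 ± 41 ms
(truth 280).

A CLI mirrors the library:

```bash
wfmp2rage pulse-profile --order 6 --target water --out profile.csv
wfmp2rage build-lut --encoding radial --out lut.csv
wfmp2rage simulate-phantom --seed 7 --snr 50 --outdir sim/
wfmp2rage fit --s1w sim/s1_water.nii.gz --s2w sim/s2_water.nii.gz \
              --s1f sim/s1_fat.nii.gz  --s2f sim/s2_fat.nii.gz --outdir maps/
```

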