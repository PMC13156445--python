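# Methods

`wfmp2rage` models a 3D radially encoded MP2RAGE sequence in which water and
fat are excited alternately by frequency-selective binomial pulses, and
implements the quantification that turns the resulting component-specific
GRE image pairs into water-specific T1, fat-specific T1, S0 amplitudes and a
proton-density fat fraction (PDFF). This note records the models, the
numerical choices, and what the synthetic phantom does and does not emulate.

## Binomial pulse model

A binomial pulse of order *n* is a train of *n* rectangular ("hard")
subpulses whose amplitudes follow the binomial row C(n−1, k), separated by a
fixed centre-to-centre spacing τ. Free precession between subpulses makes
the net excitation frequency selective: in-phase subpulses (water pulse)
excite on-resonance spins fully and null spins at Δf = 1/(2τ); alternating
the subpulse phase by 180° (fat pulse) swaps pass and stop bands. Defaults
follow the implemented protocol: n = 6, coefficients 1-5-10-10-5-1,
subpulse duration 60 μs, τ = 1.15 ms (total duration 5.81 ms), nominal flip
4°.

The excitation profile is computed by a relaxation-free rotation-matrix
Bloch simulation: each subpulse is one rotation about the effective-field
axis (B1 along ±x plus the off-resonance z-component) — exact for
constant-amplitude subpulses — with free precession during the remaining
gap of each spacing. Efficiency is defined as ε(Δf) = |M_xy(Δf)| / sin(α_nom)
with magnetization starting along +z. A zero-duration-subpulse
("instantaneous") variant and the small-tip closed form
ε = |cos(πΔfτ)|^{n−1} (water) / |sin(πΔfτ)|^{n−1} (fat) are provided; at 4°
the Bloch and small-tip profiles agree to < 0.01 absolute over ±600 Hz, and
the closed form serves as the analytic oracle in the tests.

With these defaults the water pulse keeps ε ≥ 90% over a 112-Hz band around
water, drops to 23.8% at 200 Hz, and leaks 0.61% at the α-olefinic line
(2.0 ppm ≈ 332.6 Hz from water at 123.2 Hz/ppm, water at 4.7 ppm). The
Hz-per-ppm scale and the named fat resonances are configurable through
`PpmConvention`.

## Protocol and timing

`ProtocolParams` holds the full acquisition parameter set (defaults: TR
10.1 ms, TE 3.45 ms, TI 668/2800 ms, MP2RAGE_TR 5 s, 64 echoes per
component per train, 4° flips, inversion efficiency 0.9, 9216 spokes per
component, 256³ matrix at 1.4 mm). Because water and fat excitations
alternate, each component sees TR_eff = 2·TR = 20.2 ms and an effective
train of 64 echoes (1292.8 ms per train).

The inversion times are referenced to the temporal centre of each GRE train
(the usual MP2RAGE convention; stated here explicitly because the choice is
otherwise open): the pre-train delay is TA = TI1 − train/2 = 21.6 ms, the
inter-train gap 839.2 ms, and the post-train delay TC = 1553.6 ms. Negative
delays raise `InfeasibleProtocolError`.

Spoke directions follow the 3D golden-means generator: spoke *i* has
z = 1 − 2·frac(i·0.46561…) and azimuth 2π·frac(i·0.68233…). Each fat spoke
reuses its paired water spoke's polar angle with the azimuth advanced by
+π/2; both trains of a block acquire identical directions, and block *n*
continues the sequence where block *n−1* stopped, so retrospective
undersampling is simply discarding trailing blocks.

## Steady-state signal model and look-up table

For one component, a full MP2RAGE_TR cycle acts on the longitudinal
magnetization as a composition of affine maps: inversion (m → −0.9·m,
modelled as instantaneous), exponential relaxation over the delays, and
per-echo excitation (×cos α) plus relaxation over TR_eff. The periodic
steady state is the unique fixed point of the composed map and is solved in
closed form; a brute-force multi-period integrator is kept in the test
suite as an independent oracle (agreement < 1e−6).

Each echo's signal factor is m·sin α sampled just before the excitation;
TE and T2* do not enter (they fold into S0). Radial encoding samples the
k-space centre on every spoke, so the image contrast corresponds to the
*mean* over the train's echoes; a Cartesian option takes the centre echo
instead. The UNI combination Re(S1·S2*)/(|S1|²+|S2|²) is tabulated against
T1 on a 100–3500 ms grid at 1 ms steps and restricted to its maximal
strictly monotone segment (the full grid, for the default protocol); T1 is
decoded by linear inverse interpolation, with out-of-range UNI mapping to
NaN. The train-mean (radial) table is displaced toward shorter T1 relative
to the centre-echo (Cartesian) table.

Effective-flip correction builds per-voxel tables at flip α_nom·B1·ε(Δf),
where Δf is the voxel B0 error plus the component's chemical-shift offset
(0 for water, −418.9 Hz for fat's methylene line). Tables are cached on a
quantized (B0, B1) grid of 5 Hz × 0.02 bins — the flip error introduced by
quantization is far below the decode resolution.

Decoding a UNI simulated at the 200-Hz effective flip with the nominal
(uncorrected) table misestimates a true T1 of 1000 ms by 31 ms under this
model (2.5–3% relative); the bias grows roughly quadratically with the
nominal flip, so its exact size is sensitive to the details of the train
recursion.
Decoding with the field-matched table recovers the truth to grid precision.

## Quantification

Per component: UNI → voxel-LUT T1 decode → OLS amplitude. The two
observations s1 = S0·f1(T1), s2 = S0·f2(T1) overdetermine the single
amplitude; the normal-equation solution is S0 = (f1 s1 + f2 s2)/(f1²+f2²).
GRE1 can be negative (acquired before the null crossing): with complex
inputs its sign is restored from the UNI numerator's sign, with magnitude
inputs from sign(f1(T1)). PDFF = 100·S0_fat/(S0_fat+S0_water) under the
equal-T2* assumption; negative amplitudes are clipped to zero before the
ratio and a zero denominator yields NaN (counts logged). No regularization
is added to the UNI combination.

Invariances: PDFF is unchanged by global intensity scaling of all four
inputs (receive field cancels), and T1 by a global complex phase.

## Synthetic phantom

`default_vial_phantom` mirrors a 14-vial agar/fat test object on a
64×64×16 grid at 2 mm (chosen so the full closed loop runs in seconds; the
protocol's 256³ is configurable): four fat-free agarose vials doped with
0, 0.02, 0.1, 0.3 mM Gd (water T1 from 1/T1 = 1/2.9 s + 3.5·[Gd] /s — a
nominal relaxivity assumption, so the truths are free parameters rather
than reproductions of any measured vial), nine mixtures with PDFF 10–90%
(T1_water 2300 ms, T1_fat 280 ms), one pure-fat vial, and a tap-water
background (T1 2900 ms).

The forward model is image-domain: per voxel and component the steady-state
factors are evaluated at the component T1 and local effective flips, scaled
by the component amplitude, plus complex Gaussian noise (σ given directly
or as peak-signal/SNR), generated from a stored seed (bit-reproducible).
It deliberately omits k-space effects: undersampling/streaking, gradient
imperfections, coil sensitivities, motion, cross-excitation of the
untargeted component, and T2* decay differences. Passing the closed-loop
tests therefore demonstrates the correctness of the signal model and
estimator chain, not robustness to reconstruction artefacts in real data.

Degenerate compartments behave as designed rather than as estimates: a
channel with zero amplitude carries only noise, its UNI is undefined
(noiseless) or random (noisy), and the corresponding T1/PDFF voxels are
NaN. Accuracy under noise is assessed on ROI means, as vials are evaluated
in practice: at SNR 50 the median |PDFF error| of mixture-vial ROI means
over 20 noise seeds is ≈ 0.4% (voxel-wise it is ≈ 2%).

## Spectroscopy reference fits

The STEAM reference models are fitted with bounded nonlinear least squares
(`scipy.optimize.curve_fit`): inversion recovery
y = M0·(1 − (1 − cos(eff·π))·e^(−TI/T1)) with eff = 0.9 (T1 initialised at
the abscissa of minimum |y|, bounds 10–10000 ms; a magnitude-mode fits |model|
for unsigned data), and monoexponential decay y = M0·e^(−TE/T2) (log-linear
initialisation, bounds 1–2000 ms). The spectroscopy fat fraction
back-extrapolates first-echo amplitudes to TE = 0 with fixed T2 values
(30 ms fat, 50 ms water) before the percent ratio. At amplitude SNR 100 on
the reference schedules (25 TIs 50–2450 ms; 7 TEs 20–110 ms) both fits show
< 1% bias and < 3% RMSE over 200 Monte-Carlo draws.

## Statistics

ROI summaries use the sample (n−1) SD. Bland–Altman limits are
mean ± 1.96·SD of the paired differences. The undersampling comparison
statistic is the voxel-wise normalized difference 100·(test−ref)/ref with
median and IQR over a foreground mask, quartiles by linear (type-7)
interpolation — the convention is stated because none is standard.

## Known limitations

- No k-space reconstruction: the spoke schedule is generated and subset,
  but images are simulated in the image domain, so undersampling quality
  can only be assessed by spoke counts, not artefact levels.
- Cross-excitation of the untargeted component is modelled nowhere (pulse
  leakage enters only through each component's own effective flip), so
  fat/water swaps at large B0 error are out of scope.
- The inversion is instantaneous with a fixed efficiency; T2 decay during
  the adiabatic pulse is ignored.
- Magnitude-only inputs cannot disambiguate the GRE1 polarity before the T1
  decode; complex (or signed) inputs are the supported path.
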