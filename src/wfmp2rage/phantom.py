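"""Digital vial phantom and image-domain forward simulator.

The default phantom mirrors a 14-vial agar/fat test object: four fat-free
agarose vials doped with increasing gadolinium concentrations (shortening the
water T1), nine agar/pork-fat mixtures with fat fractions from 10% to 90%,
and one pure-fat vial, all immersed in a tap-water background.  The forward
simulator produces the four component GRE volumes from the steady-state
signal model with voxel-wise effective flips and complex Gaussian noise,
returning the ground-truth maps alongside for closed-loop validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .protocol import ProtocolParams
from .pulses import BinomialPulse, PpmConvention, excitation_profile, make_binomial_pulse
from .quantify import ComponentImages, QuantMaps, component_b0_offset
from .signal_model import component_train_signals

__all__ = [
    "Compartment",
    "PhantomSpec",
    "gd_t1_ms",
    "default_vial_phantom",
    "simulate_component_images",
    "default_pulses",
]

#: Longitudinal relaxivity of a Gd-DOTA-like agent at 3 T, per mM per second.
GD_R1_PER_MM_S = 3.5
#: T1 of the undoped 1.5% agarose/PBS gel, ms.
AGAR_BASE_T1_MS = 2900.0


def gd_t1_ms(conc_mm: float, r1=GD_R1_PER_MM_S, base_t1_ms=AGAR_BASE_T1_MS) -> float:
    """Water T1 of a Gd-doped gel: 1/T1 = 1/T1_base + r1 * [Gd].

    The relaxivity and base T1 are assumptions (nominal agent/gel values);
    the phantom's T1 truths are free parameters of the simulation, not
    reproductions of any measured vial.
    """
    if conc_mm < 0:
        raise ValueError("concentration must be non-negative")
    r1_total = 1.0 / (base_t1_ms / 1000.0) + r1 * conc_mm  # 1/s
    return 1000.0 / r1_total


@dataclass(frozen=True)
class Compartment:
    """A cylindrical vial (full z extent) with its ground-truth tissue values."""

    name: str
    centre_xy: tuple[float, float]
    radius_vox: float
    t1_water_ms: float
    t1_fat_ms: float
    pdff_percent: float
    s0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pdff_percent <= 100.0:
            raise ValueError(f"{self.name}: pdff must be in [0, 100]")


@dataclass
class PhantomSpec:
    """Grid, compartments, field maps and noise model of a digital phantom."""

    shape: tuple[int, int, int] = (64, 64, 16)
    voxel_mm: float = 2.0
    compartments: list[Compartment] = field(default_factory=list)
    container_radius_vox: float | None = None
    b0_hz: np.ndarray | None = None
    b1_scale: np.ndarray | None = None
    noise_sigma: float | None = None
    snr: float | None = None
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        return aff

    def _circle_mask(self, centre_xy, radius) -> np.ndarray:
        nx, ny, nz = self.shape
        x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        in_plane = (x - centre_xy[0]) ** 2 + (y - centre_xy[1]) ** 2 <= radius**2
        return np.repeat(in_plane[:, :, None], nz, axis=2)

    def compartment_masks(self) -> dict[str, np.ndarray]:
        masks = {c.name: self._circle_mask(c.centre_xy, c.radius_vox) for c in self.compartments}
        union = np.zeros(self.shape, dtype=bool)
        for m in masks.values():
            if np.any(union & m):
                raise ValueError("compartment masks overlap")
            union |= m
        return masks

    def container_mask(self) -> np.ndarray:
        if self.container_radius_vox is None:
            return np.ones(self.shape, dtype=bool)
        centre = ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)
        return self._circle_mask(centre, self.container_radius_vox)

    def background_mask(self) -> np.ndarray:
        bg = self.container_mask()
        for m in self.compartment_masks().values():
            bg &= ~m
        return bg

    def validate(self) -> None:
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        for m in (self.b0_hz, self.b1_scale):
            if m is not None and np.shape(m) != self.shape:
                raise ValueError("field map shape must match the grid")
        self.compartment_masks()  # raises on overlap


def default_vial_phantom(
    shape: tuple[int, int, int] = (64, 64, 16),
    seed: int = 0,
    snr: float | None = None,
    noise_sigma: float | None = None,
) -> PhantomSpec:
    """The 14-vial agar/fat phantom on a fast test grid.

    One pure-fat vial at the centre, four fat-free Gd-doped vials (0, 0.02,
    0.1, 0.3 mM) on an inner ring, and nine agar/fat mixtures (PDFF 10-90%,
    step 10, fixed T1_water 2300 ms / T1_fat 280 ms) on an outer ring, in a
    tap-water container.
    """
    cx, cy = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    scale = shape[0] / 64.0
    comps: list[Compartment] = [
        Compartment(
            "pure_fat", (cx, cy), 3.5 * scale,
            t1_water_ms=math.nan, t1_fat_ms=280.0, pdff_percent=100.0,
        )
    ]
    for k, conc in enumerate([0.0, 0.02, 0.1, 0.3]):
        ang = 2.0 * math.pi * k / 4.0 + math.pi / 4.0
        comps.append(
            Compartment(
                f"gd_{conc:g}mM",
                (cx + 10.0 * scale * math.cos(ang), cy + 10.0 * scale * math.sin(ang)),
                3.5 * scale,
                t1_water_ms=gd_t1_ms(conc),
                t1_fat_ms=math.nan,
                pdff_percent=0.0,
            )
        )
    for k, pdff in enumerate(range(10, 100, 10)):
        ang = 2.0 * math.pi * k / 9.0
        comps.append(
            Compartment(
                f"mix_{pdff}pct",
                (cx + 20.0 * scale * math.cos(ang), cy + 20.0 * scale * math.sin(ang)),
                3.5 * scale,
                t1_water_ms=2300.0,
                t1_fat_ms=280.0,
                pdff_percent=float(pdff),
            )
        )
    return PhantomSpec(
        shape=shape,
        compartments=comps,
        container_radius_vox=28.0 * scale,
        seed=seed,
        snr=snr,
        noise_sigma=noise_sigma,
    )


def default_pulses() -> dict[str, BinomialPulse]:
    """The order-6 water- and fat-selective binomial pulses of the protocol."""
    return {
        "water": make_binomial_pulse(6, "water"),
        "fat": make_binomial_pulse(6, "fat"),
    }


#: Background (tap water) truth values.
_BACKGROUND_T1_WATER_MS = 2900.0


def simulate_component_images(
    spec: PhantomSpec,
    params: ProtocolParams,
    pulses: dict[str, BinomialPulse] | None = None,
    conv: PpmConvention | None = None,
) -> tuple[ComponentImages, QuantMaps]:
    """Forward-simulate the four component GRE volumes plus ground truth.

    Per voxel and component the steady-state train factors are evaluated at
    the component T1 and the local effective flips (B0/B1 fields through the
    pulse profile); the component amplitude splits the total S0 by the fat
    fraction.  Complex Gaussian noise of standard deviation ``noise_sigma``
    (or derived from ``snr`` relative to the strongest noiseless signal) is
    added per volume with the stored seed, making the output bit-reproducible.
    """
    spec.validate()
    pulses = pulses or default_pulses()
    conv = conv or PpmConvention()
    shape = spec.shape

    t1_w = np.full(shape, np.nan)
    t1_f = np.full(shape, np.nan)
    pdff = np.full(shape, np.nan)
    s0_tot = np.zeros(shape)

    bg = spec.background_mask()
    t1_w[bg] = _BACKGROUND_T1_WATER_MS
    pdff[bg] = 0.0
    s0_tot[bg] = 1.0

    masks = spec.compartment_masks()
    for comp in spec.compartments:
        m = masks[comp.name]
        t1_w[m] = comp.t1_water_ms
        t1_f[m] = comp.t1_fat_ms
        pdff[m] = comp.pdff_percent
        s0_tot[m] = comp.s0

    s0_w = np.where(np.isfinite(pdff), s0_tot * (1.0 - pdff / 100.0), 0.0)
    s0_f = np.where(np.isfinite(pdff), s0_tot * pdff / 100.0, 0.0)

    b0 = np.zeros(shape) if spec.b0_hz is None else np.asarray(spec.b0_hz, dtype=float)
    b1 = np.ones(shape) if spec.b1_scale is None else np.asarray(spec.b1_scale, dtype=float)

    volumes: dict[str, np.ndarray] = {}
    for name, t1_map_, s0_map_ in (("water", t1_w, s0_w), ("fat", t1_f, s0_f)):
        pulse = pulses[name]
        offs = np.asarray(component_b0_offset(name, b0, conv), dtype=float)
        uniq, inv = np.unique(np.round(offs, 6).ravel(), return_inverse=True)
        eps = excitation_profile(pulse, uniq).efficiency[inv].reshape(shape)
        flip1 = params.flip1_deg * b1 * eps
        flip2 = params.flip2_deg * b1 * eps

        s1 = np.zeros(shape)
        s2 = np.zeros(shape)
        ok = np.isfinite(t1_map_) & (s0_map_ > 0)
        if np.any(ok):
            fac = component_train_signals(params, t1_map_[ok], flip1[ok], flip2[ok])
            s1[ok] = s0_map_[ok] * fac.f1
            s2[ok] = s0_map_[ok] * fac.f2
        volumes[f"s1_{name}"] = s1
        volumes[f"s2_{name}"] = s2

    sigma = spec.noise_sigma
    if sigma is None and spec.snr is not None:
        peak = max(np.abs(v).max() for v in volumes.values())
        sigma = peak / spec.snr
    rng = np.random.default_rng(spec.seed)
    out: dict[str, np.ndarray] = {}
    for key in ("s1_water", "s2_water", "s1_fat", "s2_fat"):
        v = volumes[key].astype(complex)
        if sigma:
            v = v + sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
        out[key] = v

    # Truth T1 is only defined where the component actually contributes.
    truth = QuantMaps(
        t1_water=np.where(s0_w > 0, t1_w, np.nan),
        t1_fat=np.where(s0_f > 0, t1_f, np.nan),
        s0_water=s0_w,
        s0_fat=s0_f,
        pdff=pdff,
        affine=spec.affine,
        provenance={"phantom_seed": spec.seed, "noise_sigma": sigma},
    )
    images = ComponentImages(
        s1_water=out["s1_water"],
        s2_water=out["s2_water"],
        s1_fat=out["s1_fat"],
        s2_fat=out["s2_fat"],
        affine=spec.affine,
    )
    return images, truth
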