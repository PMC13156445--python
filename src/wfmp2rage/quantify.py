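"""Water/fat-specific T1, S0 and PDFF quantification from component GRE pairs.

Per component the pipeline is: UNI combination of the GRE1/GRE2 pair,
voxel-wise look-up-table decode of T1 (with effective-flip correction from B0
and B1 maps when available), then an ordinary-least-squares solve of the
overdetermined pair ``s1 = S0 f1(T1)``, ``s2 = S0 f2(T1)`` for the single
amplitude S0.  The proton-density fat fraction follows as
``100 * S0_fat / (S0_fat + S0_water)``: receive field and T2* weighting are
common to both amplitudes (equal-T2* assumption) and cancel in the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .protocol import ProtocolParams
from .pulses import BinomialPulse, PpmConvention, excitation_profile
from .signal_model import (
    LookUpTable,
    build_voxel_luts,
    component_train_signals,
    uni_combine,
)

__all__ = [
    "ComponentImages",
    "QuantMaps",
    "component_b0_offset",
    "t1_map",
    "s0_ols",
    "pdff_map",
    "quantify",
    "estimate_inversion_efficiency",
]

logger = logging.getLogger(__name__)


def component_b0_offset(
    target: str, b0_hz: float | np.ndarray = 0.0, conv: PpmConvention | None = None
):
    """Off-resonance seen by a component's spins on the carrier-referenced axis.

    Water sits at the carrier, so its offset is the local B0 error.  Fat
    (dominant methylene line, 1.3 ppm) resonates below water, at
    ``-(4.7 - 1.3) * hz_per_ppm`` Hz; both pulse profiles are symmetric in
    frequency so only the magnitude matters for the efficiency.
    """
    conv = conv or PpmConvention()
    if target == "water":
        return b0_hz
    if target == "fat":
        return b0_hz - conv.offset_hz(conv.resonances["methylene"])
    raise ValueError(f"unknown component {target!r}")


@dataclass(frozen=True)
class ComponentImages:
    """Water- and fat-specific GRE1/GRE2 volumes on one grid.

    Volumes may be complex (preferred; the UNI numerator sign disambiguates
    the GRE1 polarity) or signed real.  ``affine`` is the shared NIfTI
    affine.
    """

    s1_water: np.ndarray
    s2_water: np.ndarray
    s1_fat: np.ndarray
    s2_fat: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shapes = {v.shape for v in (self.s1_water, self.s2_water, self.s1_fat, self.s2_fat)}
        if len(shapes) != 1:
            raise ValueError(f"component volumes must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s1_water.shape

    def pair(self, component: str) -> tuple[np.ndarray, np.ndarray]:
        if component == "water":
            return self.s1_water, self.s2_water
        if component == "fat":
            return self.s1_fat, self.s2_fat
        raise ValueError(f"unknown component {component!r}")


@dataclass
class QuantMaps:
    """Output maps: component T1 (ms), S0 amplitudes (a.u.) and PDFF (%)."""

    t1_water: np.ndarray
    t1_fat: np.ndarray
    s0_water: np.ndarray
    s0_fat: np.ndarray
    pdff: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    provenance: dict = field(default_factory=dict)


def t1_map(uni_map: np.ndarray, lut_bank, b0_map=None, b1_map=None) -> np.ndarray:
    """Voxel-wise LUT decode of a UNI volume; NaN propagates.

    ``lut_bank`` may be a :class:`~wfmp2rage.signal_model.VoxelLutBank` or a
    single global :class:`~wfmp2rage.signal_model.LookUpTable`.
    """
    uni = np.asarray(uni_map, dtype=float)
    if isinstance(lut_bank, LookUpTable):
        if b0_map is not None or b1_map is not None:
            raise ValueError("field maps require a VoxelLutBank, not a single LUT")
        return lut_bank.decode(uni)
    for m in (b0_map, b1_map):
        if m is not None and np.shape(m) != uni.shape:
            raise ValueError("field map shape does not match the UNI map")
    return lut_bank.decode_map(uni, b0_map, b1_map)


def s0_ols(
    s1,
    s2,
    t1_ms,
    params: ProtocolParams,
    flip1_eff_deg=None,
    flip2_eff_deg=None,
    factors=None,
):
    """Least-squares amplitude of the pair s1 = S0 f1, s2 = S0 f2.

    The normal-equation solution of the 2-equation, 1-unknown system is
    ``S0 = (f1 s1 + f2 s2) / (f1^2 + f2^2)``.  GRE1 polarity is restored
    before the solve: from the UNI-numerator sign for complex inputs, from
    ``sign(f1(T1))`` for magnitude inputs.  Voxels with non-finite T1 or a
    vanishing denominator yield NaN.
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    t1 = np.asarray(t1_ms, dtype=float)
    scalar = t1.ndim == 0 and s1.ndim == 0
    s1, s2, t1 = np.atleast_1d(s1), np.atleast_1d(s2), np.atleast_1d(t1)

    if factors is not None:
        f1 = np.asarray(factors.f1, dtype=float)
        f2 = np.asarray(factors.f2, dtype=float)
    else:
        f1 = np.full(t1.shape, np.nan)
        f2 = np.full(t1.shape, np.nan)
        ok = np.isfinite(t1) & (t1 > 0)
        if np.any(ok):
            fac = component_train_signals(
                params,
                t1[ok],
                np.broadcast_to(np.asarray(
                    params.flip1_deg if flip1_eff_deg is None else flip1_eff_deg, float
                ), t1.shape)[ok],
                np.broadcast_to(np.asarray(
                    params.flip2_deg if flip2_eff_deg is None else flip2_eff_deg, float
                ), t1.shape)[ok],
            )
            f1[ok], f2[ok] = fac.f1, fac.f2

    if np.iscomplexobj(s1) or np.iscomplexobj(s2):
        sign1 = np.sign(np.real(s1 * np.conj(s2)))
        s1r = sign1 * np.abs(s1)
        s2r = np.abs(s2)
    else:
        s1r = np.sign(f1) * np.abs(np.asarray(s1, dtype=float))
        s2r = np.abs(np.asarray(s2, dtype=float))

    den = f1**2 + f2**2
    out = np.full(t1.shape, np.nan)
    good = np.isfinite(den) & (den > 0) & np.isfinite(s1r) & np.isfinite(s2r)
    out[good] = (f1[good] * s1r[good] + f2[good] * s2r[good]) / den[good]
    return float(out[0]) if scalar else out


def pdff_map(s0_fat, s0_water):
    """Proton-density fat fraction in percent: 100 * S0f / (S0f + S0w).

    Negative amplitudes (noise overshoot) are clipped to zero before the
    ratio; voxels where both amplitudes vanish or are non-finite return NaN.
    Clip and NaN counts are logged.
    """
    f = np.asarray(s0_fat, dtype=float)
    w = np.asarray(s0_water, dtype=float)
    if f.shape != w.shape:
        raise ValueError("s0_fat and s0_water shapes differ")
    n_clip = int(np.sum((f < 0) | (w < 0)))
    if n_clip:
        logger.info("pdff_map: clipped negative S0 in %d voxel(s)", n_clip)
    f = np.clip(f, 0.0, None)
    w = np.clip(w, 0.0, None)
    tot = f + w
    out = np.full(f.shape, np.nan)
    ok = np.isfinite(tot) & (tot > 0)
    out[ok] = 100.0 * f[ok] / tot[ok]
    n_nan = int(np.sum(~ok))
    if n_nan:
        logger.info("pdff_map: %d voxel(s) undefined (zero or non-finite total)", n_nan)
    return out


def quantify(
    images: ComponentImages,
    params: ProtocolParams,
    pulses: Mapping[str, BinomialPulse],
    b0_map: np.ndarray | None = None,
    b1_map: np.ndarray | None = None,
    conv: PpmConvention | None = None,
    b0_step_hz: float = 5.0,
    b1_step: float = 0.02,
) -> QuantMaps:
    """Full quantification: UNI, voxel-LUT T1 decode, OLS S0, PDFF.

    ``pulses`` maps ``"water"``/``"fat"`` to the selective excitation pulse
    of that component; each component's look-up tables are built at its own
    chemical-shift offset plus the voxel B0 error.  Missing field maps fall
    back to on-resonance / unit-transmit tables with a logged warning.
    """
    conv = conv or PpmConvention()
    if b0_map is None and b1_map is None:
        logger.warning("quantify: no B0/B1 maps given; using the global on-resonance LUT")
    shape = images.shape
    b0 = np.zeros(shape) if b0_map is None else np.asarray(b0_map, dtype=float)
    b1 = np.ones(shape) if b1_map is None else np.asarray(b1_map, dtype=float)
    if b0.shape != shape or b1.shape != shape:
        raise ValueError("field maps must match the image grid")

    t1_maps: dict[str, np.ndarray] = {}
    s0_maps: dict[str, np.ndarray] = {}
    for comp in ("water", "fat"):
        pulse = pulses[comp]
        s1, s2 = images.pair(comp)
        uni = uni_combine(s1, s2)
        bank = build_voxel_luts(
            params,
            pulse,
            b0_step_hz=b0_step_hz,
            b1_step=b1_step,
            component_offset_hz=float(component_b0_offset(comp, 0.0, conv)),
        )
        t1 = bank.decode_map(uni, b0, b1)

        # Effective flips per voxel for the amplitude solve (unquantized).
        offs = np.asarray(component_b0_offset(comp, b0, conv), dtype=float)
        uniq_offs, inv = np.unique(np.round(offs, 6).ravel(), return_inverse=True)
        eps_vals = excitation_profile(pulse, uniq_offs).efficiency
        eps_map = eps_vals[inv].reshape(shape)
        flip1 = params.flip1_deg * b1 * eps_map
        flip2 = params.flip2_deg * b1 * eps_map

        s0 = np.full(shape, np.nan).ravel()
        ok = np.isfinite(t1).ravel()
        if np.any(ok):
            fac = component_train_signals(
                params, t1.ravel()[ok], flip1.ravel()[ok], flip2.ravel()[ok]
            )
            s0[ok] = s0_ols(
                s1.ravel()[ok], s2.ravel()[ok], t1.ravel()[ok], params, factors=fac
            )
        t1_maps[comp] = t1
        s0_maps[comp] = s0.reshape(shape)

    pdff = pdff_map(s0_maps["fat"], s0_maps["water"])

    from . import __version__

    prov = {
        "package": "wfmp2rage",
        "version": __version__,
        "protocol": params.model_dump(),
        "pulses": {
            k: {
                "coefficients": list(p.coefficients),
                "subpulse_duration_s": p.subpulse_duration,
                "centre_spacing_s": p.centre_spacing,
                "nominal_flip_deg": p.nominal_flip,
            }
            for k, p in pulses.items()
        },
        "field_maps": {"b0": b0_map is not None, "b1": b1_map is not None},
    }
    return QuantMaps(
        t1_water=t1_maps["water"],
        t1_fat=t1_maps["fat"],
        s0_water=s0_maps["water"],
        s0_fat=s0_maps["fat"],
        pdff=pdff,
        affine=images.affine,
        provenance=prov,
    )


def estimate_inversion_efficiency(signal_with_inversion, signal_without_inversion) -> float:
    """Mean per-ROI ratio |s_inv| / |s_no_inv| across paired ROI values."""
    s_inv = np.abs(np.atleast_1d(np.asarray(signal_with_inversion, dtype=complex)))
    s_ref = np.abs(np.atleast_1d(np.asarray(signal_without_inversion, dtype=complex)))
    if s_inv.shape != s_ref.shape:
        raise ValueError("ROI value arrays must have equal length")
    if np.any(s_ref == 0):
        raise ValueError("reference (no-inversion) signal must be non-zero in every ROI")
    return float(np.mean(s_inv / s_ref))
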