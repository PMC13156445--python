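"""Radial MP2RAGE steady-state signal model, UNI combination and look-up tables.

One component (water or fat) experiences, every MP2RAGE_TR: an inversion of
efficiency ``eff``, free relaxation, a first GRE train of small-flip
excitations at period ``TR_eff``, another free-relaxation gap, a second train,
and a trailing delay.  Because every excitation and relaxation step acts on
the longitudinal magnetization as an affine map ``m -> a*m + b``, the periodic
steady state is the fixed point of the composed map and can be solved in
closed form; a brute-force time-stepping integrator is kept in the test suite
as the independent oracle.

Radial encoding samples the k-space centre on every spoke, so the effective
GRE signal entering the UNI combination is the mean over all echoes of the
train rather than the single centre-of-k-space echo of a Cartesian readout;
this shifts the UNI-vs-T1 look-up table toward shorter T1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .protocol import ProtocolParams, SequenceTiming, derive_timing
from .pulses import BinomialPulse, excitation_profile

__all__ = [
    "ModelFactors",
    "LookUpTable",
    "VoxelLutBank",
    "DegenerateProtocolError",
    "component_train_signals",
    "uni_combine",
    "build_lut",
    "build_voxel_luts",
    "decode_t1",
]

logger = logging.getLogger(__name__)

Encoding = Literal["radial", "cartesian"]


class DegenerateProtocolError(ValueError):
    """Raised when the UNI-vs-T1 curve has no usable monotone segment."""


@dataclass(frozen=True)
class ModelFactors:
    """Per-unit-magnetization GRE train signal factors f1(T1), f2(T1).

    ``s_i = S0 * f_i`` with S0 the apparent proton density absorbing receive
    field and T2* decay; f1 may be negative (acquisition before the null
    crossing), f2 is positive for all relevant T1.
    """

    f1: np.ndarray | float
    f2: np.ndarray | float


def _relax(a, b, t_ms, t1_ms):
    """Compose free relaxation over ``t_ms`` onto the affine map (a, b)."""
    e = np.exp(-t_ms / t1_ms)
    return a * e, b * e + (1.0 - e)


def component_train_signals(
    params: ProtocolParams,
    t1_ms: np.ndarray | float,
    flip1_eff_deg: float | np.ndarray | None = None,
    flip2_eff_deg: float | np.ndarray | None = None,
    encoding: Encoding = "radial",
    timing: SequenceTiming | None = None,
) -> ModelFactors:
    """Steady-state GRE train factors for one component at unit M0.

    Solves the periodic steady state analytically: the whole MP2RAGE_TR cycle
    is an affine map on the longitudinal magnetization whose unique fixed
    point (|slope| < 1 for any T1 > 0) is the steady state.  The signal of
    echo ``i`` is ``m_i * sin(flip)`` sampled just before the excitation
    tips the magnetization; ``radial`` encoding averages all echoes of a
    train, ``cartesian`` takes the centre echo.

    Parameters are broadcast together, so ``t1_ms`` may be a grid and the
    flips per-voxel arrays.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    f1_deg = params.flip1_deg if flip1_eff_deg is None else flip1_eff_deg
    f2_deg = params.flip2_deg if flip2_eff_deg is None else flip2_eff_deg
    f1_deg = np.asarray(f1_deg, dtype=float)
    f2_deg = np.asarray(f2_deg, dtype=float)
    if np.any(f1_deg < 0) or np.any(f2_deg < 0):
        raise ValueError("effective flips must be non-negative")
    tim = timing if timing is not None else derive_timing(params)
    etl = params.etl_per_component
    eff = params.inversion_efficiency

    t1, f1_deg, f2_deg = np.broadcast_arrays(t1, f1_deg, f2_deg)
    cos1, sin1 = np.cos(np.radians(f1_deg)), np.sin(np.radians(f1_deg))
    cos2, sin2 = np.cos(np.radians(f2_deg)), np.sin(np.radians(f2_deg))

    # Compose the full-cycle affine map m -> a*m + b, cycle start just
    # before the inversion pulse.
    a, b = np.full(t1.shape, -eff), np.zeros(t1.shape)
    a, b = _relax(a, b, tim.ta, t1)
    for cos in (cos1, cos2):
        for _ in range(etl):
            a, b = a * cos, b * cos
            a, b = _relax(a, b, tim.tr_eff, t1)
        if cos is cos1:
            a, b = _relax(a, b, tim.gap, t1)
    a, b = _relax(a, b, tim.tc, t1)
    m_star = b / (1.0 - a)

    # Forward pass through one cycle from the fixed point, collecting echoes.
    m = -eff * m_star
    ea = np.exp(-tim.ta / t1)
    m = m * ea + (1.0 - ea)
    e_tr = np.exp(-tim.tr_eff / t1)
    factors = []
    for cos, sin in ((cos1, sin1), (cos2, sin2)):
        echoes = []
        for _ in range(etl):
            echoes.append(m * sin)
            m = m * cos
            m = m * e_tr + (1.0 - e_tr)
        echoes = np.stack(echoes)
        if encoding == "radial":
            factors.append(echoes.mean(axis=0))
        elif encoding == "cartesian":
            factors.append(echoes[etl // 2])
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
        if cos is cos1:
            eg = np.exp(-tim.gap / t1)
            m = m * eg + (1.0 - eg)

    f1, f2 = factors
    if np.isscalar(t1_ms) or np.ndim(t1_ms) == 0:
        return ModelFactors(f1=float(f1), f2=float(f2))
    return ModelFactors(f1=f1, f2=f2)


def uni_combine(s1, s2):
    """Standard MP2RAGE UNI combination, bounded in [-0.5, 0.5].

    ``Re(s1 * conj(s2)) / (|s1|^2 + |s2|^2)``; receive field and T2* cancel.
    Accepts signed real or complex inputs.  Where both inputs vanish the
    ratio is undefined and NaN is returned.
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    num = np.real(s1 * np.conj(s2))
    den = np.abs(s1) ** 2 + np.abs(s2) ** 2
    scalar = num.ndim == 0
    num, den = np.atleast_1d(num), np.atleast_1d(den)
    out = np.full(num.shape, np.nan, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    n_zero = int(np.sum(~nz))
    if n_zero:
        logger.warning("uni_combine: %d voxel(s) with zero signal set to NaN", n_zero)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class LookUpTable:
    """Monotone UNI-vs-T1 table with the train factors used to build it.

    Restricted at construction to the maximal strictly monotone segment of
    the UNI curve so that decoding is single-valued; UNI values outside the
    stored range decode to NaN.
    """

    t1_grid_ms: np.ndarray
    uni: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    flip1_eff_deg: float
    flip2_eff_deg: float
    inversion_efficiency: float
    encoding: Encoding

    @property
    def t1_range_ms(self) -> tuple[float, float]:
        return float(self.t1_grid_ms[0]), float(self.t1_grid_ms[-1])

    def decode(self, uni_values) -> np.ndarray | float:
        return decode_t1(uni_values, self)

    def encode(self, t1_ms) -> np.ndarray | float:
        """Forward-interpolate UNI at the given T1 (test/simulation helper)."""
        return np.interp(t1_ms, self.t1_grid_ms, self.uni, left=np.nan, right=np.nan)

    def factors_at(self, t1_ms) -> ModelFactors:
        """Interpolate the stored f1/f2 train factors at decoded T1 values."""
        t1 = np.asarray(t1_ms, dtype=float)
        f1 = np.interp(t1, self.t1_grid_ms, self.f1, left=np.nan, right=np.nan)
        f2 = np.interp(t1, self.t1_grid_ms, self.f2, left=np.nan, right=np.nan)
        return ModelFactors(f1=f1, f2=f2)


def _maximal_monotone_segment(y: np.ndarray) -> slice:
    """Longest run of strictly monotone consecutive values, as a slice."""
    d = np.diff(y)
    if d.size == 0 or not np.any(np.isfinite(d)) or np.all(d == 0):
        return slice(0, 0)
    sign = np.where(np.isfinite(d), np.sign(d), 0.0)
    best_start, best_len = 0, 0
    start = 0
    for i in range(1, len(sign) + 1):
        if i == len(sign) or sign[i] != sign[start] or sign[i] == 0:
            if sign[start] != 0 and i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    return slice(best_start, best_start + best_len + 1)


def build_lut(
    params: ProtocolParams,
    flip_scale: float = 1.0,
    b0_offset_hz: float = 0.0,
    encoding: Encoding = "radial",
    pulse: BinomialPulse | None = None,
    t1_min_ms: float = 100.0,
    t1_max_ms: float = 3500.0,
    t1_step_ms: float = 1.0,
) -> LookUpTable:
    """Build the UNI-vs-T1 look-up table for given field conditions.

    The effective flip at each train is the nominal flip scaled by the
    transmit-field factor ``flip_scale`` and, when a ``pulse`` is given, by
    its excitation efficiency at ``b0_offset_hz``.  The table is restricted
    to its maximal strictly monotone segment; with the default protocol this
    spans the whole 100-3500 ms grid.
    """
    if flip_scale < 0:
        raise ValueError("flip_scale must be non-negative")
    eps = 1.0
    if pulse is not None:
        eps = float(excitation_profile(pulse, np.array([b0_offset_hz])).efficiency[0])
    flip1 = params.flip1_deg * flip_scale * eps
    flip2 = params.flip2_deg * flip_scale * eps

    t1_grid = np.arange(t1_min_ms, t1_max_ms + 0.5 * t1_step_ms, t1_step_ms)
    factors = component_train_signals(params, t1_grid, flip1, flip2, encoding=encoding)
    uni = uni_combine(factors.f1, factors.f2)

    seg = _maximal_monotone_segment(uni)
    if seg.stop - seg.start < 2:
        raise DegenerateProtocolError(
            "UNI curve has no strictly monotone segment; the protocol cannot "
            "encode T1 (zero effective flip?)"
        )
    return LookUpTable(
        t1_grid_ms=t1_grid[seg],
        uni=uni[seg],
        f1=factors.f1[seg],
        f2=factors.f2[seg],
        flip1_eff_deg=flip1,
        flip2_eff_deg=flip2,
        inversion_efficiency=params.inversion_efficiency,
        encoding=encoding,
    )


def decode_t1(uni_values, lut: LookUpTable):
    """Invert the look-up table: UNI -> T1 in ms, NaN outside the table range.

    Linear inverse interpolation on the strictly monotone segment; the
    decode of an encoded T1 is exact to within one grid step.
    """
    uni = np.asarray(uni_values, dtype=float)
    scalar = uni.ndim == 0
    uni = np.atleast_1d(uni)
    x, y = lut.uni, lut.t1_grid_ms
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    out = np.full(uni.shape, np.nan)
    ok = np.isfinite(uni) & (uni >= x[0]) & (uni <= x[-1])
    out[ok] = np.interp(uni[ok], x, y)
    return float(out[0]) if scalar else out


class VoxelLutBank:
    """Per-voxel look-up tables keyed by quantized (B0, B1) field values.

    Building a table per voxel would be wasteful; instead B0 is quantized to
    ``b0_step_hz`` bins and B1 to ``b1_step`` bins and one table is built
    (lazily) per occupied bin.  With the small bin sizes the flip-angle error
    introduced by quantization is far below the table's decode resolution.
    """

    def __init__(
        self,
        params: ProtocolParams,
        pulse: BinomialPulse,
        b0_step_hz: float = 5.0,
        b1_step: float = 0.02,
        encoding: Encoding = "radial",
        component_offset_hz: float = 0.0,
        **lut_kwargs,
    ) -> None:
        self.params = params
        self.pulse = pulse
        self.b0_step_hz = b0_step_hz
        self.b1_step = b1_step
        self.encoding = encoding
        self.component_offset_hz = component_offset_hz
        self._lut_kwargs = lut_kwargs
        self._cache: dict[tuple[int, int], LookUpTable] = {}

    def _key(self, b0: float, b1: float) -> tuple[int, int]:
        return (int(round(b0 / self.b0_step_hz)), int(round(b1 / self.b1_step)))

    def lut_for(self, b0_hz: float, b1_scale: float) -> LookUpTable:
        key = self._key(b0_hz, b1_scale)
        if key not in self._cache:
            b0_q = key[0] * self.b0_step_hz
            b1_q = key[1] * self.b1_step
            self._cache[key] = build_lut(
                self.params,
                flip_scale=b1_q,
                b0_offset_hz=b0_q + self.component_offset_hz,
                encoding=self.encoding,
                pulse=self.pulse,
                **self._lut_kwargs,
            )
        return self._cache[key]

    def decode_map(
        self,
        uni_map: np.ndarray,
        b0_map: np.ndarray | None = None,
        b1_map: np.ndarray | None = None,
    ) -> np.ndarray:
        """Decode a UNI volume voxel-wise with field-matched tables.

        Missing maps default to on-resonance / unit transmit.  Non-finite
        field values mask the voxel (NaN output) with a logged count.
        """
        uni = np.asarray(uni_map, dtype=float)
        b0 = np.zeros_like(uni) if b0_map is None else np.asarray(b0_map, dtype=float)
        b1 = np.ones_like(uni) if b1_map is None else np.asarray(b1_map, dtype=float)
        if b0.shape != uni.shape or b1.shape != uni.shape:
            raise ValueError("field maps must match the UNI map shape")

        out = np.full(uni.shape, np.nan)
        finite = np.isfinite(b0) & np.isfinite(b1)
        n_masked = int(np.sum(~finite))
        if n_masked:
            logger.warning("decode_map: %d voxel(s) with non-finite field values masked", n_masked)

        k0 = np.round(np.where(finite, b0, 0.0) / self.b0_step_hz).astype(np.int64)
        k1 = np.round(np.where(finite, b1, 0.0) / self.b1_step).astype(np.int64)
        k0[~finite] = np.iinfo(np.int64).min
        keys = np.stack([k0.ravel(), k1.ravel()], axis=-1)
        uniq, inv = np.unique(keys, axis=0, return_inverse=True)
        flat_uni = uni.ravel()
        flat_out = out.ravel()
        for j, (q0, q1) in enumerate(uniq):
            if q0 == np.iinfo(np.int64).min:
                continue
            lut = self.lut_for(q0 * self.b0_step_hz, q1 * self.b1_step)
            sel = inv == j
            flat_out[sel] = decode_t1(flat_uni[sel], lut)
        return flat_out.reshape(uni.shape)


def build_voxel_luts(
    params: ProtocolParams,
    pulse: BinomialPulse,
    b0_step_hz: float = 5.0,
    b1_step: float = 0.02,
    **kwargs,
) -> VoxelLutBank:
    """Construct a :class:`VoxelLutBank` for per-voxel effective-flip decoding."""
    return VoxelLutBank(params, pulse, b0_step_hz=b0_step_hz, b1_step=b1_step, **kwargs)
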