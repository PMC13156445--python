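"""Acquisition protocol, sequence timing, and the 3D golden-means radial schedule.

The sequence interleaves water- and fat-selective excitations inside each GRE
train, so each component sees an effective repetition time of twice the
hardware TR and an effective train length of half the echo count.  Spoke
directions follow the 3D golden-means ("kooshball") generator, which fills the
sphere near-uniformly for any contiguous subset of spokes and therefore
tolerates retrospective undersampling by simply discarding the last
inversion blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ProtocolParams",
    "SequenceTiming",
    "SpokeSet",
    "InfeasibleProtocolError",
    "derive_timing",
    "generate_spokes",
    "undersample_discard_last",
    "scan_duration",
]

# 3D golden means: the two irrational increments driving z and azimuth.
# Derived from the modified Fibonacci (Chan et al.) construction.
GOLDEN_MEAN_Z = 0.4656145221945549
GOLDEN_MEAN_AZIMUTH = 0.6823278038280193


class InfeasibleProtocolError(ValueError):
    """Raised when the requested timing cannot fit inside one MP2RAGE_TR."""


class ProtocolParams(BaseModel, frozen=True):
    """Full protocol parameter set for the radial water/fat MP2RAGE sequence.

    Defaults reproduce the abdominal protocol: TR 10.1 ms, TE 3.45 ms,
    inversion times 668/2800 ms inside a 5 s MP2RAGE_TR, 64 echoes per
    component per train, 4 degree flips, inversion efficiency 0.9 and 9216
    spokes per component at 1.4 mm isotropic resolution.
    """

    tr_ms: float = Field(default=10.1, gt=0)
    te_ms: float = Field(default=3.45, gt=0)
    ti1_ms: float = Field(default=668.0, gt=0)
    ti2_ms: float = Field(default=2800.0, gt=0)
    mp2rage_tr_ms: float = Field(default=5000.0, gt=0)
    etl_per_component: int = Field(default=64, ge=1)
    flip1_deg: float = Field(default=4.0, ge=0)
    flip2_deg: float = Field(default=4.0, ge=0)
    inversion_efficiency: float = Field(default=0.9, ge=0, le=1)
    spokes_per_component: int = Field(default=9216, ge=1)
    matrix: tuple[int, int, int] = (256, 256, 256)
    voxel_mm: float = Field(default=1.4, gt=0)

    @model_validator(mode="after")
    def _check_consistency(self) -> "ProtocolParams":
        if self.ti2_ms <= self.ti1_ms:
            raise ValueError("ti2 must exceed ti1")
        if self.spokes_per_component % self.etl_per_component != 0:
            raise ValueError(
                f"spokes_per_component ({self.spokes_per_component}) must be a "
                f"multiple of etl_per_component ({self.etl_per_component})"
            )
        return self

    @property
    def tr_eff_ms(self) -> float:
        """Per-component repetition time: two TRs (water and fat alternate)."""
        return 2.0 * self.tr_ms

    @property
    def n_blocks(self) -> int:
        """Number of inversion blocks (MP2RAGE_TR periods) in the scan."""
        return self.spokes_per_component // self.etl_per_component

    @classmethod
    def from_toml(cls, path) -> "ProtocolParams":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data.get("protocol", data))


@dataclass(frozen=True)
class SequenceTiming:
    """Derived timing of one inversion block, all in milliseconds.

    ``ta`` runs from the inversion to the first excitation of train 1,
    ``gap`` separates the two trains, and ``tc`` runs from the end of
    train 2 to the next inversion.  Inversion times are referenced to the
    temporal centre of each train, the standard MP2RAGE convention.
    """

    tr_eff: float
    train_duration: float
    ta: float
    gap: float
    tc: float

    @property
    def mp2rage_tr(self) -> float:
        return self.ta + 2.0 * self.train_duration + self.gap + self.tc


def derive_timing(params: ProtocolParams) -> SequenceTiming:
    """Derive block timing from the protocol, validating feasibility.

    With the train centre at TI, the pre-train delay is
    ``ta = TI1 - train/2``, the inter-train gap ``(TI2 - TI1) - train`` and
    the post-train delay ``tc = MP2RAGE_TR - TI2 - train/2``.
    """
    tr_eff = params.tr_eff_ms
    train = params.etl_per_component * tr_eff
    ta = params.ti1_ms - train / 2.0
    gap = (params.ti2_ms - params.ti1_ms) - train
    tc = params.mp2rage_tr_ms - params.ti2_ms - train / 2.0
    if ta < 0 or gap < 0 or tc < 0:
        raise InfeasibleProtocolError(
            f"GRE trains do not fit the MP2RAGE_TR: ta={ta:.1f} ms, "
            f"gap={gap:.1f} ms, tc={tc:.1f} ms"
        )
    return SequenceTiming(tr_eff=tr_eff, train_duration=train, ta=ta, gap=gap, tc=tc)


@dataclass(frozen=True)
class SpokeSet:
    """A table of radial spokes with their acquisition bookkeeping.

    Arrays share the first dimension: ``directions`` (N, 3) unit vectors and,
    per spoke, the component (``"water"``/``"fat"``), the inversion-block
    index, the train (1 or 2) and the echo position within the train.
    """

    directions: np.ndarray
    component: np.ndarray
    block_index: np.ndarray
    train_index: np.ndarray
    echo_index: np.ndarray

    def __len__(self) -> int:
        return self.directions.shape[0]

    def count(self, component: str | None = None) -> int:
        """Spoke count per GRE image.

        Both trains acquire identical directions within a block and feed the
        two separate GRE images, so protocol accounting ("spokes per
        component") counts each direction once; without a component filter
        this is the per-image total across both components.
        """
        mask = self.train_index == 1
        if component is not None:
            mask &= self.component == component
        return int(np.sum(mask))


def _golden_direction(index: np.ndarray) -> np.ndarray:
    """Golden-means direction for global spoke index i.

    z descends by the first golden mean modulo 2, azimuth advances by the
    second golden mean modulo 1 (times 2*pi).
    """
    z = 1.0 - 2.0 * np.mod(index * GOLDEN_MEAN_Z, 1.0)
    az = 2.0 * math.pi * np.mod(index * GOLDEN_MEAN_AZIMUTH, 1.0)
    sin_theta = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([sin_theta * np.cos(az), sin_theta * np.sin(az), z], axis=-1)


def generate_spokes(params: ProtocolParams) -> SpokeSet:
    """Generate the full water/fat spoke schedule for the protocol.

    Water spokes follow the golden-means sequence in global (block-major,
    echo-minor) order; each fat spoke reuses its paired water spoke's polar
    angle with the azimuth advanced by 90 degrees.  Within a block both GRE
    trains acquire identical directions, and block ``n`` continues the
    sequence where block ``n-1`` stopped.
    """
    etl = params.etl_per_component
    n_blocks = params.n_blocks
    per_block = etl  # unique water directions per block (shared by both trains)

    idx = np.arange(n_blocks * per_block)
    water_dirs = _golden_direction(idx)

    z = water_dirs[:, 2]
    az = np.arctan2(water_dirs[:, 1], water_dirs[:, 0]) + math.pi / 2.0
    sin_theta = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    fat_dirs = np.stack([sin_theta * np.cos(az), sin_theta * np.sin(az), z], axis=-1)

    blocks = idx // per_block
    echoes = idx % per_block

    dir_list, comp_list, blk_list, trn_list, ech_list = [], [], [], [], []
    for train in (1, 2):
        for comp, dirs in (("water", water_dirs), ("fat", fat_dirs)):
            dir_list.append(dirs)
            comp_list.append(np.full(idx.shape, comp, dtype="U5"))
            blk_list.append(blocks)
            trn_list.append(np.full(idx.shape, train, dtype=int))
            ech_list.append(echoes)

    return SpokeSet(
        directions=np.concatenate(dir_list),
        component=np.concatenate(comp_list),
        block_index=np.concatenate(blk_list),
        train_index=np.concatenate(trn_list),
        echo_index=np.concatenate(ech_list),
    )


def undersample_discard_last(spokes: SpokeSet, n_blocks_discarded: int) -> SpokeSet:
    """Retrospective undersampling: drop the last ``n`` inversion blocks.

    Because the golden-means ordering keeps any prefix of blocks
    near-uniformly distributed, discarding trailing blocks emulates a
    proportionally shorter scan.
    """
    total_blocks = int(spokes.block_index.max()) + 1 if len(spokes) else 0
    if not 0 <= n_blocks_discarded <= total_blocks:
        raise ValueError(
            f"n_blocks_discarded must be in [0, {total_blocks}], got {n_blocks_discarded}"
        )
    keep = spokes.block_index < (total_blocks - n_blocks_discarded)
    return SpokeSet(
        directions=spokes.directions[keep],
        component=spokes.component[keep],
        block_index=spokes.block_index[keep],
        train_index=spokes.train_index[keep],
        echo_index=spokes.echo_index[keep],
    )


def scan_duration(params: ProtocolParams) -> float:
    """Total acquisition time in seconds: one MP2RAGE_TR per inversion block."""
    return params.n_blocks * params.mp2rage_tr_ms / 1000.0
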