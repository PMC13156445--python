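"""Evaluation statistics: ROI summaries, Bland-Altman agreement limits, and
normalized-difference quantiles for undersampling comparisons."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgreementResult",
    "roi_stats",
    "bland_altman",
    "normalized_difference_stats",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman mean difference and 95% limits of agreement.

    Limits are ``mean_difference +/- 1.96 * sd_difference`` with the sample
    (n-1) standard deviation, all in the input's units.
    """

    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float


def roi_stats(volume: np.ndarray, mask: np.ndarray) -> tuple[float, float, int]:
    """Sample mean, sample SD and count over the finite masked voxels.

    NaN voxels inside the mask are excluded with a logged count; an empty
    effective mask is an error.
    """
    vol = np.asarray(volume, dtype=float)
    msk = np.asarray(mask, dtype=bool)
    if vol.shape != msk.shape:
        raise ValueError("volume and mask shapes differ")
    vals = vol[msk]
    finite = np.isfinite(vals)
    n_dropped = int(vals.size - finite.sum())
    if n_dropped:
        logger.info("roi_stats: excluded %d non-finite voxel(s)", n_dropped)
    vals = vals[finite]
    if vals.size == 0:
        raise ValueError("ROI mask contains no finite voxels")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd, int(vals.size)


def bland_altman(values_a, values_b) -> AgreementResult:
    """Limits of agreement for paired measurements (differences a - b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value arrays must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        mean_difference=mean,
        sd_difference=sd,
        lower_limit=mean - 1.96 * sd,
        upper_limit=mean + 1.96 * sd,
    )


def normalized_difference_stats(
    map_ref: np.ndarray, map_test: np.ndarray, mask: np.ndarray
) -> tuple[float, float, float, float]:
    """Median, IQR and quartiles of the voxel-wise normalized difference (%).

    ``d = 100 * (test - ref) / ref`` over the masked voxels; background is
    excluded by the mask, non-finite and zero-reference voxels are dropped
    with a logged count.  Quartiles use linear (type-7) interpolation.

    Returns ``(median, iqr, q1, q3)`` in percent.
    """
    ref = np.asarray(map_ref, dtype=float)
    test = np.asarray(map_test, dtype=float)
    msk = np.asarray(mask, dtype=bool)
    if not (ref.shape == test.shape == msk.shape):
        raise ValueError("maps and mask must share one shape")
    r = ref[msk]
    t = test[msk]
    ok = np.isfinite(r) & np.isfinite(t) & (r != 0)
    n_dropped = int(r.size - ok.sum())
    if n_dropped:
        logger.info(
            "normalized_difference_stats: excluded %d zero-reference/non-finite voxel(s)",
            n_dropped,
        )
    if not np.any(ok):
        raise ValueError("no usable voxels in the mask")
    d = 100.0 * (t[ok] - r[ok]) / r[ok]
    q1, med, q3 = np.percentile(d, [25.0, 50.0, 75.0])
    return float(med), float(q3 - q1), float(q1), float(q3)
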