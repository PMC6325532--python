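"""Paired Gaussian-vs-Bessel line-profile streak metric ("bar code").

For a region imaged once with each illumination modality, the column-mean
intensity profile evidences shadows as drops.  Normalizing each profile by
its own median makes the two modalities comparable regardless of channel
gain; columns where the absolute normalized difference exceeds a threshold
(e.g. 0.05 = 5% relative deviation) form a bar-code pattern whose filled
fraction estimates the image area affected by streaking.  Sweeping the
threshold shows the sensitivity of that estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProfilePair",
    "BarcodeResult",
    "column_profile",
    "make_profile_pair",
    "profile_difference",
    "barcode",
    "threshold_sweep",
    "slab_summary",
]


@dataclass
class ProfilePair:
    """Column-mean profiles of the same region under two illuminations."""

    positions: np.ndarray  # column indices retained (along illumination axis)
    gauss_profile: np.ndarray
    bessel_profile: np.ndarray
    normalization: str = "q75"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.gauss_profile = np.asarray(self.gauss_profile, float)
        self.bessel_profile = np.asarray(self.bessel_profile, float)
        if not (
            len(self.positions) == len(self.gauss_profile) == len(self.bessel_profile)
        ):
            raise ValueError("profile arrays must have equal length")


@dataclass
class BarcodeResult:
    """Binarized profile difference and the affected-column percentage."""

    threshold: float
    barcode: np.ndarray  # bool per column
    affected_percent: float


def column_profile(image: np.ndarray, region_mask: np.ndarray | None = None):
    """Mean intensity of each column over the masked rows.

    Columns with no masked rows are dropped; returns ``(positions, profile)``
    where ``positions`` are the retained column indices.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if region_mask is None:
        region_mask = np.ones(img.shape, bool)
    m = np.asarray(region_mask, bool)
    counts = m.sum(axis=0)
    keep = counts > 0
    sums = (img * m).sum(axis=0)
    positions = np.flatnonzero(keep)
    return positions, sums[keep] / counts[keep]


def make_profile_pair(
    gauss_image: np.ndarray,
    bessel_image: np.ndarray,
    region_mask: np.ndarray | None = None,
    register: bool = True,
    max_shift: int = 10,
) -> ProfilePair:
    """Build co-registered column profiles from a Gaussian/Bessel image pair.

    The two acquisitions are sequential, so an integer-pixel shift along the
    illumination axis may separate them; profiles are aligned by the peak of
    their cross-correlation (within ``max_shift`` columns) before pairing.
    """
    pg, g = column_profile(gauss_image, region_mask)
    pb, b = column_profile(bessel_image, region_mask)
    common = np.intersect1d(pg, pb)
    g = g[np.isin(pg, common)]
    b = b[np.isin(pb, common)]
    if register and len(common) > 2 * max_shift + 2:
        gz = g - g.mean()
        bz = b - b.mean()
        shifts = range(-max_shift, max_shift + 1)
        score = [
            np.dot(gz[max(0, -s) : len(gz) - max(0, s)], bz[max(0, s) : len(bz) - max(0, -s)])
            for s in shifts
        ]
        s = list(shifts)[int(np.argmax(score))]
        if s > 0:
            g, b, common = g[: len(g) - s], b[s:], common[: len(common) - s]
        elif s < 0:
            g, b, common = g[-s:], b[: len(b) + s], common[-s:]
    return ProfilePair(common, g, b)


def profile_difference(
    pair: ProfilePair, normalize: bool = True, norm_quantile: float = 0.75
) -> np.ndarray:
    """Absolute difference of the two profiles in relative units.

    Each profile is divided by its own upper-quartile value over the analyzed
    region, so a difference of 0.05 means a 5% relative deviation; the result
    is symmetric in the two channels.  The scale statistic must come from the
    *unshadowed* columns to be comparable across channels; stripes only
    darken, so an upper quantile stays anchored there for striped fractions
    up to ``1 − norm_quantile`` of columns per channel (the median would drift
    once a third or more of the columns are shadowed).  With
    ``normalize=False`` the raw profiles are differenced (both assumed on a
    common scale already).
    """
    g, b = pair.gauss_profile, pair.bessel_profile
    if normalize:
        mg = float(np.quantile(g, norm_quantile))
        mb = float(np.quantile(b, norm_quantile))
        if mg <= 0 or mb <= 0:
            raise ValueError("cannot normalize a profile with non-positive scale")
        g, b = g / mg, b / mb
    return np.abs(g - b)


def barcode(diff: np.ndarray, threshold: float) -> BarcodeResult:
    """Binarize a profile difference into a bar code of affected columns."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    d = np.asarray(diff, float)
    code = d > threshold
    pct = 100.0 * float(code.sum()) / max(len(code), 1)
    return BarcodeResult(threshold, code, pct)


def threshold_sweep(pair: ProfilePair, thresholds) -> np.ndarray:
    """Affected percentage as a function of threshold (non-increasing curve).

    Returns an array of shape (n, 2): columns (threshold, affected_percent).
    """
    thresholds = np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    diff = profile_difference(pair)
    return np.array([[t, barcode(diff, t).affected_percent] for t in thresholds])


def slab_summary(per_slice_percents) -> tuple[float, float]:
    """Mean and sample SD of per-slice affected percentages over a slab."""
    p = np.asarray(per_slice_percents, float)
    if p.size < 2:
        raise ValueError("need >= 2 slices for a mean ± SD summary")
    return float(np.mean(p)), float(np.std(p, ddof=1))
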