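"""Per-locus "range of cis contacts" from a normalized contact map.

The statistic is the half-width, in kb, of the band of significant contacts
perpendicular to the main diagonal of the matrix.  The pipeline: (1) robust
background statistics (median and MAD-derived sigma) over the unmasked map;
(2) binarize above median + k*sigma, keep 8-connected components of at least
``min_component`` points, then fill holes by morphological closing with a
diamond (Manhattan-ball) structuring element; (3) at every bin walk the
anti-diagonal through (i, i) and count the contiguous significant run; the
range in kb is run_length * bin_size / 2, since the run spans both sides of
the locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contact_map import ContactMap

__all__ = [
    "RobustStats",
    "SignificanceMask",
    "WidthProfile",
    "RegionRangeSummary",
    "robust_stats",
    "significance_mask",
    "filter_components",
    "diamond_close",
    "diagonal_width_profile",
    "summarize_range",
    "contact_range",
]

MAD_SCALE = 1.4826  # consistency factor: sigma = 1.4826 * MAD for a Gaussian


@dataclass(frozen=True)
class RobustStats:
    median: float
    mad: float

    @property
    def sigma(self) -> float:
        return MAD_SCALE * self.mad


@dataclass
class SignificanceMask:
    mask: np.ndarray  # boolean N x N
    k_sigma: float
    min_component: int
    closing_radius: int
    circular: bool = True


@dataclass
class WidthProfile:
    width_bins: np.ndarray  # odd positive ints, 0 where diagonal not significant
    bin_size: int

    @property
    def range_kb(self) -> np.ndarray:
        return self.width_bins * (self.bin_size / 1000) / 2


@dataclass(frozen=True)
class RegionRangeSummary:
    start: int
    end: int  # bin interval, half-open; may wrap (end < start)
    median: float
    q25: float
    q75: float
    n_bins: int


def robust_stats(cm: ContactMap) -> RobustStats:
    """Median and MAD of the unmasked matrix entries."""
    keep = cm.unmasked
    vals = cm.matrix[np.ix_(keep, keep)].ravel()
    if vals.size == 0:
        raise ValueError("no unmasked entries")
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return RobustStats(med, mad)


def diamond_structure(radius: int) -> np.ndarray:
    """Manhattan ball of the given radius (|di|+|dj| <= radius)."""
    r = np.arange(-radius, radius + 1)
    return (np.abs(r)[:, None] + np.abs(r)[None, :]) <= radius


def filter_components(mask: np.ndarray, min_component: int = 30) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_component`` points."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_component) + 1
    return np.isin(labels, keep)


def diamond_close(mask: np.ndarray, radius: int = 5,
                  circular: bool = True) -> np.ndarray:
    """Morphological closing with a diamond structuring element.

    Closing = dilation then erosion.  Off-matrix area counts as background
    for the dilation and as foreground for the erosion, so closing never
    removes points at the matrix border; on a circular chromosome the matrix
    wraps in both axes instead.
    """
    if radius <= 0:
        return mask.astype(bool)
    st = diamond_structure(radius)
    if circular:
        pad = 2 * radius
        big = np.pad(mask, pad, mode="wrap")
        closed = ndimage.binary_erosion(
            ndimage.binary_dilation(big, structure=st, border_value=0),
            structure=st, border_value=1)
        return closed[pad:-pad, pad:-pad]
    dil = ndimage.binary_dilation(mask, structure=st, border_value=0)
    return ndimage.binary_erosion(dil, structure=st, border_value=1)


def significance_mask(cm: ContactMap, k_sigma: float = 1.0,
                      min_component: int = 30,
                      closing_radius: int = 5) -> SignificanceMask:
    """Binary map of significant contacts.

    Threshold at median + k_sigma * sigma, size-filter the 8-connected
    components, then close with a diamond of the given radius.  Masked bins
    never become significant.
    """
    if k_sigma < 0:
        raise ValueError("k_sigma must be nonnegative")
    stats = robust_stats(cm)
    thr = stats.median + k_sigma * stats.sigma
    raw = cm.matrix > thr
    keep = cm.unmasked
    raw &= keep[:, None] & keep[None, :]
    sig = filter_components(raw, min_component)
    closed = diamond_close(sig, closing_radius, cm.circular)
    return SignificanceMask(closed, k_sigma, min_component, closing_radius,
                            cm.circular)


def diagonal_width_profile(mask: SignificanceMask | np.ndarray,
                           bin_size: int = 5000,
                           circular: bool | None = None) -> WidthProfile:
    """Width of the significant band perpendicular to the main diagonal.

    For bin i, walk (i+t, i-t) for t = 0, +-1, ... and count the maximal
    contiguous run of significant points containing t = 0 (odd by symmetry);
    width is 0 where (i, i) itself is not significant.  Indices wrap on a
    circular chromosome and truncate at the matrix edge otherwise.
    """
    if isinstance(mask, SignificanceMask):
        m = mask.mask
        if circular is None:
            circular = mask.circular
    else:
        m = np.asarray(mask, dtype=bool)
        if circular is None:
            circular = True
    if not np.array_equal(m, m.T):
        raise ValueError("significance mask must be symmetric")
    n = m.shape[0]
    width = np.zeros(n, dtype=np.int64)
    tmax = n // 2 if circular else n - 1
    for i in range(n):
        if not m[i, i]:
            continue
        w = 1
        for t in range(1, tmax + 1):
            a, b = i + t, i - t
            if circular:
                a %= n
                b %= n
            elif a >= n or b < 0:
                break
            if m[a, b]:
                w += 2
            else:
                break
        width[i] = w
    return WidthProfile(width, bin_size)


def summarize_range(profile: WidthProfile, start: int, end: int) -> RegionRangeSummary:
    """Median and quartiles of range_kb over a (possibly wrapping) bin interval."""
    n = len(profile.width_bins)
    if start == end:
        raise ValueError("empty region")
    idx = np.arange(start, end if end > start else end + n) % n
    vals = profile.range_kb[idx]
    q25, med, q75 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    return RegionRangeSummary(start, end, float(med), float(q25), float(q75),
                              len(vals))


def contact_range(cm: ContactMap, k_sigma: float = 1.0, min_component: int = 30,
                  closing_radius: int = 5) -> WidthProfile:
    """Full pipeline: significance mask then per-bin diagonal width."""
    mask = significance_mask(cm, k_sigma, min_component, closing_radius)
    return diagonal_width_profile(mask, cm.bin_size)
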