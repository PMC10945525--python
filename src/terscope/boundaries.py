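"""Directional index and chromosome-interacting-domain (CID) boundaries.

The directional index asks, for every bin, whether its contacts are biased
upstream or downstream.  Each bin's contact vector is taken from the
Pearson-correlation matrix of the normalized contact map; the values at lags
1..K to the left are paired with the same lags to the right (K = 100 kb /
bin_size = 20 by default) and compared with a paired two-sided t-test.
Positive t means rightward (downstream) contacts dominate.  A boundary is
called wherever the sign of t flips between two adjacent bins and both
flanks are significant at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contact_map import ContactMap

__all__ = [
    "CorrelationMap",
    "DITrack",
    "BoundaryCall",
    "correlation_map",
    "directional_index",
    "call_cids",
]

T_DISPLAY_CLIP = 2.0  # |t| = 2 is approximately p = 0.05 at df ~ 19


@dataclass
class CorrelationMap:
    matrix: np.ndarray  # NaN on masked bins
    masked_bins: frozenset
    circular: bool = True
    bin_size: int = 5000


@dataclass
class DITrack:
    t_raw: np.ndarray  # NaN where undefined
    p: np.ndarray
    max_range: int
    bin_size: int

    @property
    def t_disp(self) -> np.ndarray:
        return np.clip(self.t_raw, -T_DISPLAY_CLIP, T_DISPLAY_CLIP)

    @property
    def n_lags(self) -> int:
        return self.max_range // self.bin_size


@dataclass(frozen=True)
class BoundaryCall:
    position: int  # boundary sits between bins position-1 and position
    left_sign: int
    right_sign: int
    significant: bool


def correlation_map(cm: ContactMap) -> CorrelationMap:
    """Pearson correlation between every pair of matrix rows.

    Masked bins are dropped from every row before correlating and are NaN in
    the output; rows with zero variance are masked as well.
    """
    keep = cm.unmasked
    sub = cm.matrix[np.ix_(keep, keep)]
    sd = sub.std(axis=1)
    flat = sd == 0
    n = cm.n_bins
    out = np.full((n, n), np.nan)
    if np.any(~flat):
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr[flat, :] = np.nan
        corr[:, flat] = np.nan
        idx = np.flatnonzero(keep)
        out[np.ix_(idx, idx)] = corr
    masked = set(cm.masked_bins) | set(np.flatnonzero(keep)[flat])
    return CorrelationMap(out, frozenset(int(b) for b in masked), cm.circular,
                          cm.bin_size)


def _paired_t(diff: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t on a vector of differences (textbook formula)."""
    d = diff[~np.isnan(diff)]
    if len(d) < 2:
        return np.nan, np.nan
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return np.sign(d.mean()) * np.inf, 0.0
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


def directional_index(corr: CorrelationMap | ContactMap,
                      max_range: int = 100_000) -> DITrack:
    """Per-bin paired t-statistic of right-vs-left contact strength.

    Lag d on the right is paired with lag d on the left (distance-matched);
    masked lags are dropped pairwise and the degrees of freedom shrink
    accordingly.  On a linear chromosome bins within ``max_range`` of an
    edge get no value.

    Contact vectors are usually taken from the correlation matrix.  Passing
    a normalized ContactMap instead uses the normalized contact counts
    themselves; note that nominal p-values are calibrated in that mode,
    whereas on a correlation matrix neighbouring-lag values share noise and
    the per-bin p-values are anticonservative (see docs/methods.md) — there
    the t-statistic is a ranking score, and boundary calling relies on the
    consistency of significant flanks rather than on single p-values.
    """
    if isinstance(corr, ContactMap):
        corr = CorrelationMap(
            np.where(np.add.outer(~corr.unmasked, ~corr.unmasked),
                     np.nan, corr.matrix),
            frozenset(corr.masked_bins), corr.circular, corr.bin_size)
    k = max_range // corr.bin_size
    n = corr.matrix.shape[0]
    if not corr.circular and n < 2 * k + 1:
        raise ValueError("chromosome too short for the requested range")
    t_raw = np.full(n, np.nan)
    p = np.full(n, np.nan)
    lags = np.arange(1, k + 1)
    for i in range(n):
        if i in corr.masked_bins:
            continue
        if corr.circular:
            right = corr.matrix[i, (i + lags) % n]
            left = corr.matrix[i, (i - lags) % n]
        else:
            if i - k < 0 or i + k >= n:
                continue
            right = corr.matrix[i, i + lags]
            left = corr.matrix[i, i - lags]
        t_raw[i], p[i] = _paired_t(right - left)
    return DITrack(t_raw, p, max_range, corr.bin_size)


def call_cids(di: DITrack, min_significant_flank: int = 3,
              alpha: float = 0.05, circular: bool = True) -> list[BoundaryCall]:
    """Boundaries at sign changes of the directional index.

    A boundary between bins b-1 and b requires sign(t[b-1]) != sign(t[b]);
    it is significant when the ``min_significant_flank`` bins immediately on
    each side all reach |t| >= t_crit(alpha, df) — i.e. the directional
    preference is strong right up against the flip.  Only significant
    boundaries are returned.
    """
    t = di.t_raw
    n = len(t)
    df = max(di.n_lags - 1, 1)
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    calls = []
    positions = range(n) if circular else range(1, n)
    for b in positions:
        lo, hi = t[(b - 1) % n], t[b]
        if np.isnan(lo) or np.isnan(hi):
            continue
        if np.sign(lo) == np.sign(hi) or lo == 0 or hi == 0:
            continue
        fl = min_significant_flank
        left = t[(np.arange(b - fl, b)) % n] if circular else t[b - fl:b]
        right = t[(np.arange(b, b + fl)) % n] if circular else t[b:b + fl]
        if len(left) < fl or len(right) < fl:
            continue
        ok = (np.all(np.abs(left) >= t_crit) and np.all(np.abs(right) >= t_crit)
              and not np.any(np.isnan(left)) and not np.any(np.isnan(right)))
        if ok:
            calls.append(BoundaryCall(b, int(np.sign(lo)), int(np.sign(hi)), True))
    return calls
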