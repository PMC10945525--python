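"""ChIP-seq enrichment, smoothing, and high-fold peak calling.

IP and input coverage are each normalized to their totals, their ratio gives
per-bp fold enrichment, a 50-kb circular sliding mean produces the
chromosome-scale profile, and narrow binding sites are called where the
unsmoothed enrichment stays at least 10x above background for at least 30
consecutive bp.  Peak centers feed sequence extraction for external motif
discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CoverageTrack",
    "Peak",
    "normalize_tracks",
    "smooth_track",
    "call_peaks",
    "peak_sequences",
]


@dataclass
class CoverageTrack:
    """Per-bp signal over a circular chromosome.

    ``values`` holds raw read counts, normalized density or fold enrichment
    depending on ``label``; NaN marks undefined positions (zero input).
    """

    values: np.ndarray
    label: str = "IP"  # IP | input | normalized | enrichment
    circular: bool = True
    total: float = field(default=None)  # raw read total, if known

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.total is None:
            self.total = float(np.nansum(self.values))

    @property
    def chrom_length(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Peak:
    start: int
    end: int  # half-open bp; end > chrom_length means the run wraps
    center: int
    max_fold: float

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_tracks(ip: CoverageTrack, input_: CoverageTrack) -> CoverageTrack:
    """Fold enrichment: (ip / total_ip) / (input / total_input) per position.

    Positions where the input is zero are undefined (NaN).
    """
    if ip.chrom_length != input_.chrom_length:
        raise ValueError("IP and input cover different chromosome lengths")
    if ip.total <= 0 or input_.total <= 0:
        raise ValueError("zero-total coverage track")
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = (ip.values / ip.total) / (input_.values / input_.total)
    enr[input_.values == 0] = np.nan
    return CoverageTrack(enr, "enrichment", ip.circular and input_.circular)


def smooth_track(track: CoverageTrack, window: int = 50_000) -> CoverageTrack:
    """Centered moving average over ``window`` bp.

    Wraps on a circular chromosome; undefined positions are excluded and the
    kernel renormalized over the defined ones.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window > track.chrom_length:
        raise ValueError("window exceeds chromosome length")
    v = track.values
    defined = ~np.isnan(v)
    kernel = np.ones(window)
    mode = "wrap" if track.circular else "constant"
    from scipy.ndimage import convolve1d
    num = convolve1d(np.where(defined, v, 0.0), kernel, mode=mode, cval=0.0)
    den = convolve1d(defined.astype(float), kernel, mode=mode, cval=0.0)
    with np.errstate(invalid="ignore"):
        sm = np.where(den > 0, num / den, np.nan)
    return CoverageTrack(sm, track.label + "-smoothed", track.circular)


def bin_track(track: CoverageTrack, bin_size: int) -> np.ndarray:
    """Mean of per-bp values inside each bin (NaN-aware)."""
    n = track.chrom_length
    nb = -(-n // bin_size)
    out = np.empty(nb)
    for b in range(nb):
        out[b] = np.nanmean(track.values[b * bin_size:(b + 1) * bin_size])
    return out


def call_peaks(track: CoverageTrack, background: float | None = None,
               fold: float = 10.0, min_run: int = 30) -> list[Peak]:
    """Maximal runs of positions >= fold * background, at least min_run bp.

    ``background`` defaults to the median of the defined track.  Runs touching
    both ends of a circular chromosome are merged across the origin (the
    merged peak is reported with end > chrom_length).
    """
    if background is None:
        background = float(np.nanmedian(track.values))
    if background <= 0:
        raise ValueError("background must be positive")
    v = track.values
    n = len(v)
    above = np.zeros(n, dtype=bool)
    ok = ~np.isnan(v)
    above[ok] = v[ok] >= fold * background
    if not above.any():
        return []
    if above.all():
        runs = [(0, n)]
    else:
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = list(edges[~above[edges]] + 1)
        ends = list(edges[above[edges]] + 1)
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            ends = ends + [n]
        runs = list(zip(starts, ends))
        if track.circular and above[0] and above[-1] and len(runs) > 1:
            (s0, e0), (sl, el) = runs[0], runs[-1]
            runs = runs[1:-1] + [(sl, e0 + n)]
    peaks = []
    for s, e in runs:
        if e - s < min_run:
            continue
        vals = v[np.arange(s, e) % n]
        center = (s + e) // 2 % n
        peaks.append(Peak(s, e, center, float(np.nanmax(vals))))
    return sorted(peaks, key=lambda p: p.start)


def peak_sequences(peaks: list[Peak], genome: str, flank: int = 50,
                   circular: bool = True) -> list[SeqRecord]:
    """Extract center +- flank for each peak (wrapping across the origin)."""
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    n = len(genome)
    records = []
    for k, p in enumerate(peaks):
        start, end = p.center - flank, p.center + flank + 1
        if circular:
            idx = np.arange(start, end) % n
            seq = "".join(genome[i] for i in idx)
        else:
            start, end = max(0, start), min(n, end)
            seq = genome[start:end]
        records.append(SeqRecord(Seq(seq), id=f"peak_{k + 1}",
                                 description=f"center={p.center + 1} fold={p.max_fold:.1f}"))
    return records
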