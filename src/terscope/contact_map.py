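"""Contact-map construction from proximity-ligation read pairs.

The workflow mirrors standard bacterial 3C/Hi-C processing: assign each mate
of a read pair to a restriction fragment, discard uninformative religation
products (same-fragment self-circles and uncut adjacent fragments), bin the
remaining events on a fixed grid (5 kb by default), balance the matrix by
sequential component normalization (SCN, iterative L1 row/column balancing),
and compare conditions with smoothed log2 ratio maps.

Coordinates are 0-based half-open internally; text output is 1-based
inclusive.  The chromosome is circular by default, as in *E. coli*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "RestrictionMap",
    "PairEvent",
    "ContactMap",
    "RatioMap",
    "digest_genome",
    "classify_events",
    "bin_contacts",
    "scn_normalize",
    "log_ratio_map",
]

DEFAULT_BIN_SIZE = 5000
DEFAULT_SITE = "CCGG"  # HpaII, cut C^CGG
DEFAULT_CUT_OFFSET = 1


@dataclass(frozen=True)
class RestrictionMap:
    """Fragment tiling of a chromosome induced by a restriction digest.

    ``cut_positions`` are the cut offsets on the chromosome (bp).  On a
    circular chromosome the last fragment wraps through the origin, so
    ``fragments`` are stored as (start, end) with end possibly > chrom_length
    for the wrapping fragment; fragment lengths always sum to chrom_length.
    """

    chrom_length: int
    circular: bool
    cut_positions: np.ndarray
    fragments: np.ndarray  # (n_frag, 2) half-open intervals

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def fragment_of(self, pos) -> np.ndarray:
        """Fragment index containing each position (vectorized)."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if np.any((pos < 0) | (pos >= self.chrom_length)):
            raise ValueError("position outside chromosome")
        cuts = self.cut_positions
        if len(cuts) == 0:
            return np.zeros(len(pos), dtype=np.int64)
        idx = np.searchsorted(cuts, pos, side="right") - 1
        if self.circular:
            # positions before the first cut belong to the wrapping fragment
            idx = np.where(idx < 0, self.n_fragments - 1, idx)
        else:
            idx = idx + 1  # fragment 0 precedes the first cut
        return idx


@dataclass(frozen=True)
class PairEvent:
    """A classified read pair."""

    pos1: int
    pos2: int
    strand1: str
    strand2: str
    frag1: int
    frag2: int
    event_class: str  # valid | self_fragment | uncut_adjacent


@dataclass
class ContactMap:
    """Symmetric binned contact matrix over a (circular) chromosome."""

    matrix: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE
    chrom_length: int = 0
    circular: bool = True
    masked_bins: frozenset = field(default_factory=frozenset)
    state: str = "raw"  # raw | normalized

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.chrom_length == 0:
            self.chrom_length = self.matrix.shape[0] * self.bin_size
        self.masked_bins = frozenset(int(b) for b in self.masked_bins)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def unmasked(self) -> np.ndarray:
        keep = np.ones(self.n_bins, dtype=bool)
        keep[list(self.masked_bins)] = False
        return keep

    def copy(self) -> "ContactMap":
        return ContactMap(self.matrix.copy(), self.bin_size, self.chrom_length,
                          self.circular, self.masked_bins, self.state)


@dataclass
class RatioMap:
    """log2 ratio of two normalized contact maps, optionally smoothed.

    Positive entries mean more contacts in the numerator condition (drawn
    red), negative fewer (blue).  ``undefined_mask`` marks entries where
    either input was zero or masked.
    """

    matrix: np.ndarray
    smoothing_sigma: float
    undefined_mask: np.ndarray


def n_bins_for(chrom_length: int, bin_size: int) -> int:
    return -(-chrom_length // bin_size)  # ceil


def digest_genome(sequence: str, circular: bool = True,
                  site: str = DEFAULT_SITE,
                  cut_offset: int = DEFAULT_CUT_OFFSET) -> RestrictionMap:
    """In-silico restriction digest.

    Finds every occurrence of ``site`` (overlaps allowed, wrapping across the
    origin when circular) and cuts ``cut_offset`` bases into the site.
    Returns the induced fragment tiling.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if len(site) > len(sequence):
        raise ValueError("recognition site longer than the sequence")
    seq = sequence.upper()
    site = site.upper()
    n, k = len(seq), len(site)
    search = seq + seq[: k - 1] if circular else seq
    cuts = []
    start = 0
    while True:
        hit = search.find(site, start)
        if hit == -1 or hit >= n:
            break
        cuts.append((hit + cut_offset) % n)
        start = hit + 1
    cuts = np.array(sorted(set(cuts)), dtype=np.int64)

    if len(cuts) == 0:
        frags = np.array([[0, n]], dtype=np.int64)
    elif circular:
        # fragment i runs from cut i to the next cut; the last wraps
        starts = cuts
        ends = np.r_[cuts[1:], cuts[0] + n]
        frags = np.stack([starts, ends], axis=1)
    else:
        bounds = np.r_[0, cuts, n]
        bounds = np.unique(bounds)
        frags = np.stack([bounds[:-1], bounds[1:]], axis=1)
    return RestrictionMap(n, circular, cuts, frags)


def classify_events(pairs: pd.DataFrame, rmap: RestrictionMap) -> list[PairEvent]:
    """Assign fragments and an event class to raw read pairs.

    ``pairs`` needs columns pos1, strand1, pos2, strand2.  Rules: both mates
    in one fragment -> ``self_fragment`` (self-circle); mates in adjacent
    fragments with inward-facing strands (+ on the upstream fragment, - on
    the downstream one, i.e. an unligated/religated cut) ->
    ``uncut_adjacent``; everything else -> ``valid``.
    """
    f1 = rmap.fragment_of(pairs["pos1"].to_numpy())
    f2 = rmap.fragment_of(pairs["pos2"].to_numpy())
    s1 = pairs["strand1"].astype(str).to_numpy()
    s2 = pairs["strand2"].astype(str).to_numpy()

    nf = rmap.n_fragments
    events = []
    for p1, p2, a, b, i, j in zip(pairs["pos1"], pairs["pos2"], s1, s2, f1, f2):
        if i == j:
            cls = "self_fragment"
        else:
            lo, hi = (i, j) if i < j else (j, i)
            adjacent = hi - lo == 1 or (rmap.circular and lo == 0 and hi == nf - 1)
            if adjacent:
                # strand of the mate on the upstream fragment must point
                # toward the shared cut (+), the downstream one away (-)
                if hi - lo == 1:
                    up, dn = (a, b) if i < j else (b, a)
                else:  # wrap: fragment nf-1 is upstream of fragment 0
                    up, dn = (a, b) if i == nf - 1 else (b, a)
                cls = "uncut_adjacent" if (up == "+" and dn == "-") else "valid"
            else:
                cls = "valid"
        events.append(PairEvent(int(p1), int(p2), a, b, int(i), int(j), cls))
    return events


def bin_contacts(events, bin_size: int = DEFAULT_BIN_SIZE,
                 chrom_length: int | None = None,
                 circular: bool = True) -> ContactMap:
    """Accumulate valid pair events into a symmetric binned count matrix.

    Each event increments (i, j) and (j, i); a within-bin event increments
    the diagonal once.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    events = [e for e in events if e.event_class == "valid"]
    if chrom_length is None:
        if not events:
            raise ValueError("chrom_length required for an empty event list")
        chrom_length = max(max(e.pos1, e.pos2) for e in events) + 1
    n = n_bins_for(chrom_length, bin_size)
    m = np.zeros((n, n))
    for e in events:
        i, j = e.pos1 // bin_size, e.pos2 // bin_size
        m[i, j] += 1
        if i != j:
            m[j, i] += 1
    return ContactMap(m, bin_size, chrom_length, circular, state="raw")


def scn_normalize(cm: ContactMap, max_iter: int = 200, tol: float = 1e-6,
                  mask_fraction: float = 0.10) -> ContactMap:
    """Sequential component normalization (iterative matrix balancing).

    Bins whose raw marginal falls below ``mask_fraction`` of the median
    marginal are masked (their rows/columns zeroed) before balancing.  Each
    sweep L1-normalizes rows then columns; iteration continues to the
    numerical fixed point (the unique balanced form D.A.D of a symmetric
    matrix), at which point the matrix is symmetric to machine precision
    and symmetry is restored exactly by one final transpose-average.
    Convergence requires the coefficient of variation of the unmasked row
    sums to drop below ``tol``.  The result is scaled so unmasked rows sum
    to 1.

    Raises if every bin is masked; flags non-convergence via ``state``.
    """
    m = cm.matrix.astype(float).copy()
    marg = m.sum(axis=1)
    med = np.median(marg[marg > 0]) if np.any(marg > 0) else 0.0
    masked = set(cm.masked_bins) | set(np.flatnonzero(marg < mask_fraction * med))
    keep = np.ones(cm.n_bins, dtype=bool)
    keep[list(masked)] = False
    if not keep.any():
        raise ValueError("all bins masked; nothing to normalize")
    m[~keep, :] = 0.0
    m[:, ~keep] = 0.0

    sub = m[np.ix_(keep, keep)]
    if np.any(sub.sum(axis=1) == 0):
        raise ValueError("unmasked bin with zero marginal during SCN")
    converged = False
    for _ in range(max_iter):
        prev = sub
        sub = sub / sub.sum(axis=1)[:, None]   # rows
        sub = sub / sub.sum(axis=0)[None, :]   # columns
        rs = sub.sum(axis=1)
        cv = rs.std() / rs.mean()
        if cv < tol:
            converged = True
            # keep sweeping to the numerical fixed point so that
            # renormalizing a normalized map is a no-op
            if np.max(np.abs(sub - prev)) < 1e-15:
                break
    sub = 0.5 * (sub + sub.T)  # exact symmetry (no-op at the fixed point)
    sub = sub / sub.sum(axis=1).mean()  # global scale: unit rows

    out = np.zeros_like(m)
    out[np.ix_(keep, keep)] = sub
    state = "normalized" if converged else "normalized-unconverged"
    return ContactMap(out, cm.bin_size, cm.chrom_length, cm.circular,
                      frozenset(masked), state)


def log_ratio_map(a: ContactMap, b: ContactMap, sigma: float = 1.0) -> RatioMap:
    """Smoothed log2 ratio of two normalized contact maps.

    Entries where either map is zero or masked are undefined and excluded
    from the Gaussian kernel (the kernel is renormalized over defined
    entries).  Smoothing wraps when the maps are circular.
    """
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("contact maps differ in shape")
    defined = (a.matrix > 0) & (b.matrix > 0)
    ratio = np.zeros_like(a.matrix)
    ratio[defined] = np.log2(a.matrix[defined] / b.matrix[defined])
    if sigma > 0:
        mode = "wrap" if (a.circular and b.circular) else "nearest"
        num = gaussian_filter(np.where(defined, ratio, 0.0), sigma, mode=mode)
        den = gaussian_filter(defined.astype(float), sigma, mode=mode)
        with np.errstate(invalid="ignore"):
            sm = np.where(den > 0, num / den, 0.0)
        out = np.where(defined, sm, np.nan)
    else:
        out = np.where(defined, ratio, np.nan)
    return RatioMap(out, sigma, ~defined)
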