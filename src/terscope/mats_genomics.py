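"""matS motif scanning, Ter-domain delimitation and comparative statistics.

MatP binds the 13-bp palindromic matS site; matS sites cluster in the
replication-terminus (Ter) region of enterobacterial chromosomes.  This
module scans circular genomes for the motif on both strands, delimits Ter as
the longest stretch of sites flanked on both sides by >= 100 kb devoid of
sites, computes the per-species summary statistics (site count, Ter span,
density per 100 kb, fraction of the chromosome, presence of dif), and builds
dif-centered site-density profiles with cross-species percentile envelopes.

The packaged default motif is the classical 13-bp palindromic consensus
GTGACRNYGTCAC in IUPAC exact-match mode; a position-weight-matrix mode with
a log-odds threshold is available when a matrix is supplied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "MATS_CONSENSUS",
    "Motif",
    "MotifSite",
    "TerDomain",
    "DensityProfile",
    "scan_motif",
    "delimit_ter",
    "ter_stats",
    "density_profile",
    "species_envelope",
]

MATS_CONSENSUS = "GTGACRNYGTCAC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement_iupac(word: str) -> str:
    return word.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """A DNA motif in IUPAC exact-match or PWM (log-odds) mode."""

    iupac: str | None = MATS_CONSENSUS
    pwm: np.ndarray | None = None  # (length, 4) log-odds, columns A C G T
    score_threshold: float = 0.0

    def __post_init__(self):
        if self.iupac is not None:
            word = self.iupac.upper()
            if len(word) < 4:
                raise ValueError("motif shorter than 4 bp")
            bad = set(word) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC code(s): {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.iupac) if self.iupac is not None else self.pwm.shape[0]

    def regex(self) -> str:
        return "".join(f"[{IUPAC[c]}]" for c in self.iupac.upper())

    def is_palindromic_word(self, word: str) -> bool:
        return word.upper() == str(Seq(word).reverse_complement()).upper()


@dataclass(frozen=True)
class MotifSite:
    position: int  # start, 0-based half-open on the forward strand
    strand: str
    score: float
    sequence: str


@dataclass
class TerDomain:
    """The Ter macrodomain: longest stretch of matS flanked by >= ``gap``
    site-free regions; start/end span first-site-start to last-site-end
    (end may exceed chrom_length when the stretch wraps the origin)."""

    start: int
    end: int
    sites: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def size_kb(self) -> float:
        return self.size_bp / 1000


def _scan_words(genome: str, motif: Motif, circular: bool):
    """Yield (position, strand, score, word) for every match on both strands."""
    g = genome.upper()
    n = len(g)
    k = motif.length
    search = g + g[: k - 1] if circular else g
    if motif.iupac is not None:
        pat = re.compile(f"(?=({motif.regex()}))")
        rc = reverse_complement_iupac(motif.iupac)
        pat_rc = re.compile(f"(?=({''.join(f'[{IUPAC[c]}]' for c in rc)}))")
        for m in pat.finditer(search):
            if m.start() < n:
                yield m.start(), "+", float(k), m.group(1)
        for m in pat_rc.finditer(search):
            if m.start() < n:
                yield m.start(), "-", float(k), m.group(1)
    else:
        lut = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i in range(n if circular else n - k + 1):
            word = search[i:i + k]
            if len(word) < k or any(c not in lut for c in word):
                continue
            fwd = sum(motif.pwm[j, lut[c]] for j, c in enumerate(word))
            if fwd >= motif.score_threshold:
                yield i, "+", float(fwd), word
            rcw = str(Seq(word).reverse_complement())
            rev = sum(motif.pwm[j, lut[c]] for j, c in enumerate(rcw))
            if rev >= motif.score_threshold:
                yield i, "-", float(rev), word


def scan_motif(genome: str, motif: Motif | None = None,
               circular: bool = True) -> list[MotifSite]:
    """All motif occurrences on both strands, sorted by position.

    A window matching on both strands (a perfect palindrome hit) is reported
    once, on the forward strand.
    """
    motif = motif or Motif()
    best: dict[int, MotifSite] = {}
    for pos, strand, score, word in _scan_words(genome, motif, circular):
        prev = best.get(pos)
        if prev is None or (strand == "+" and prev.strand == "-") or score > prev.score:
            best[pos] = MotifSite(pos, strand, score, word)
    return [best[p] for p in sorted(best)]


def delimit_ter(sites: list[MotifSite], chrom_length: int,
                circular: bool = True, gap: int = 100_000,
                site_length: int = len(MATS_CONSENSUS)) -> TerDomain:
    """Cluster sites by the gap rule and return the longest-span cluster.

    Consecutive sites (circularly) with an end-to-start gap < ``gap`` belong
    to one cluster; the Ter domain is the cluster with the longest first-to-
    last span, ties broken by more sites, then smaller start.  By
    construction the flanking gaps of every cluster are >= ``gap``.
    """
    if not sites:
        raise ValueError("no sites to delimit")
    sites = sorted(sites, key=lambda s: s.position)
    m = len(sites)
    if m == 1:
        s = sites[0]
        return TerDomain(s.position, s.position + site_length, [s])

    gaps = []  # gap following site i (end of i to start of i+1)
    for i in range(m - 1 if not circular else m):
        j = (i + 1) % m
        g = sites[j].position - (sites[i].position + site_length)
        if j == 0:
            g += chrom_length
        gaps.append(g)

    # split at gaps >= threshold
    breaks = [i for i, g in enumerate(gaps) if g >= gap]
    clusters: list[list[MotifSite]] = []
    if not breaks:
        clusters = [list(sites)]
    elif circular:
        for a, b in zip(breaks, breaks[1:] + [breaks[0] + m]):
            clusters.append([sites[(i + 1) % m] for i in range(a, b)])
    else:
        bounds = [-1] + breaks + ([m - 1] if breaks[-1] != m - 1 else [])
        for a, b in zip(bounds[:-1], bounds[1:]):
            clusters.append(sites[a + 1:b + 1])

    def cluster_key(cl):
        first, last = cl[0], cl[-1]
        span = last.position + site_length - first.position
        if span < 0:  # wraps the origin
            span += chrom_length
        return (span, len(cl), -first.position)

    best = max(clusters, key=cluster_key)
    first, last = best[0], best[-1]
    end = last.position + site_length
    if end < first.position:
        end += chrom_length
    return TerDomain(first.position, end, best)


def ter_stats(ter: TerDomain, chrom_length: int, dif: int | None = None) -> dict:
    """Table-style summary of a Ter domain.

    density_per_100kb = n_sites / size_kb * 100; fraction is the Ter span as
    a percentage of the chromosome.  A zero-span (single-site) domain has
    undefined density.
    """
    size_kb = ter.size_kb
    density = ter.n_sites / size_kb * 100 if size_kb > 0 else float("nan")
    contains_dif = None
    if dif is not None:
        rel = (dif - ter.start) % chrom_length
        contains_dif = rel < ter.size_bp
    return {
        "ter_size_kb": size_kb,
        "n_sites": ter.n_sites,
        "chrom_size_kb": chrom_length / 1000,
        "density_per_100kb": density,
        "fraction_pct": ter.size_bp / chrom_length * 100,
        "contains_dif": contains_dif,
    }


@dataclass
class DensityProfile:
    """matS counts per 100-kb window, indexed by signed offset from dif."""

    offsets_kb: np.ndarray  # window centers, kb from dif
    counts: np.ndarray
    window: int = 100_000


def density_profile(sites: list[MotifSite], dif: int, chrom_length: int,
                    window: int = 100_000) -> DensityProfile:
    """Site counts in contiguous windows centered on dif.

    The offset-0 window is centered on dif; every site falls in exactly one
    window, so counts sum to the number of sites.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 <= dif < chrom_length:
        raise ValueError("dif outside chromosome")
    pos = np.array([s.position for s in sites], dtype=np.int64)
    rel = (pos - dif + chrom_length // 2) % chrom_length - chrom_length // 2
    idx = np.floor((rel + window / 2) / window).astype(np.int64)
    lo = int(np.floor((-chrom_length // 2 + window / 2) / window))
    hi = int(np.floor((chrom_length // 2 - 1 + window / 2) / window))
    offsets = np.arange(lo, hi + 1)
    counts = np.zeros(len(offsets), dtype=np.int64)
    for i in idx:
        counts[i - lo] += 1
    return DensityProfile(offsets * (window / 1000), counts, window)


def species_envelope(profiles: list[DensityProfile]) -> dict:
    """Per-offset median and quartiles across species profiles.

    Profiles are aligned on the dif offset; offsets present in only some
    species use the values available there.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    all_offsets = sorted({float(o) for p in profiles for o in p.offsets_kb})
    if not all_offsets:
        raise ValueError("no overlapping offsets")
    med, q25, q75 = [], [], []
    for o in all_offsets:
        vals = []
        for p in profiles:
            hit = np.flatnonzero(p.offsets_kb == o)
            if len(hit):
                vals.append(p.counts[hit[0]])
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        med.append(q2)
        q25.append(q1)
        q75.append(q3)
    return {
        "offsets_kb": np.array(all_offsets),
        "median": np.array(med),
        "q25": np.array(q25),
        "q75": np.array(q75),
    }
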