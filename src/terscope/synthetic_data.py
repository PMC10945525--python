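"""Seeded generators for synthetic inputs with the structure the analyses assume.

Three families of artifacts:

* **Contact maps** with exponential distance decay whose decay length
  (lambda, bp) varies along a circular genome — a short lambda inside a
  "Ter" interval emulates a condensin-free terminus, multiplicative
  insulation factors at chosen bins emulate CID boundaries.  Expected counts
  for bins i, j at circular separation d are

      mu(i,j) = depth * [ exp(-d * bin_size / min(lambda_i, lambda_j))
                          * prod(insulation of boundaries between i and j)
                          + background_fraction ]

  and observed counts are Poisson around mu, symmetric by construction.
  The additive term emulates the random-ligation noise floor of real
  proximity-ligation libraries; it anchors the robust significance
  threshold of the width statistic, exactly as inter-molecular ligation
  noise does on real maps.
  min(lambda_i, lambda_j) couples loci, so a restricted locus has short-range
  contacts with everyone, as observed for Ter loci.

* **ChIP experiments**: a flat-Poisson input track and an IP track whose
  rate is multiplied by an enrichment fold inside a replicated interval
  (minus a Ter-excluded interval at baseline), plus optional narrow planted
  peaks for the peak caller.

* **Genomes** with planted matS motif instances, a dif site, and programmed
  segment transpositions with exact coordinate liftover.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._circular import pairwise_distance_matrix
from .chip_cov import CoverageTrack
from .contact_map import ContactMap
from .mats_genomics import MATS_CONSENSUS, IUPAC, Motif, reverse_complement_iupac

__all__ = [
    "SyntheticMapSpec",
    "SyntheticChipSpec",
    "Rearrangement",
    "gen_contact_map",
    "gen_chip_experiment",
    "gen_genome",
    "transpose_segment",
    "liftover",
]


@dataclass
class SyntheticMapSpec:
    """Parameters of a synthetic Hi-C map.

    lambda_bp may be a scalar (uniform decay length) or per-bin array;
    ter_interval is a bin interval [a, b) where lambda is divided by
    ter_lambda_factor; cid_boundaries maps bin positions to insulation
    factors in (0, 1].
    """

    chrom_length: int = 4_600_000
    bin_size: int = 5000
    lambda_bp: float | np.ndarray = 250_000.0
    ter_interval: tuple | None = None
    ter_lambda_factor: float = 4.0
    cid_boundaries: dict = field(default_factory=dict)
    depth: float = 1000.0
    background_fraction: float = 0.01  # random-ligation noise floor

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    def lambda_profile(self) -> np.ndarray:
        lam = np.broadcast_to(np.asarray(self.lambda_bp, dtype=float),
                              (self.n_bins,)).copy()
        if self.ter_interval is not None:
            a, b = self.ter_interval
            idx = np.arange(a, b) % self.n_bins
            lam[idx] = lam[idx] / self.ter_lambda_factor
        if np.any(lam <= 0):
            raise ValueError("lambda must be positive")
        return lam


def expected_counts(spec: SyntheticMapSpec) -> np.ndarray:
    """Closed-form expectation mu(i, j) of the synthetic map."""
    n = spec.n_bins
    lam = spec.lambda_profile()
    d = pairwise_distance_matrix(n, circular=True) * spec.bin_size
    lam_pair = np.minimum(lam[:, None], lam[None, :])
    decay = np.exp(-d / lam_pair)
    idx = np.arange(n)
    fwd = (idx[None, :] - idx[:, None]) % n  # forward arc length i -> j
    use_fwd = 2 * fwd <= n                   # shorter arc direction
    for pos, factor in spec.cid_boundaries.items():
        if not 0 < factor <= 1:
            raise ValueError("insulation factor must be in (0, 1]")
        # the boundary sits between bins pos-1 and pos; it is crossed when
        # the shorter arc from i to j passes between those bins
        steps_i = (pos - idx[:, None]) % n   # forward steps from i to boundary
        steps_j = (pos - idx[None, :]) % n   # forward steps from j to boundary
        cross = np.where(use_fwd,
                         (steps_i > 0) & (steps_i <= fwd),
                         (steps_j > 0) & (steps_j <= n - fwd))
        decay = np.where(cross, decay * factor, decay)
    # the random-ligation floor is not insulated: it is experimental noise
    return spec.depth * (decay + spec.background_fraction)


def gen_contact_map(spec: SyntheticMapSpec, seed: int = 0) -> ContactMap:
    """Poisson draw around the expected counts; symmetric raw ContactMap."""
    rng = np.random.default_rng(seed)
    mu = expected_counts(spec)
    n = spec.n_bins
    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(mu[iu])
    counts = counts + np.triu(counts, 1).T
    return ContactMap(counts, spec.bin_size, spec.chrom_length, circular=True,
                      state="raw")


@dataclass
class SyntheticChipSpec:
    """Parameters of a synthetic ChIP-seq experiment (per-bp Poisson)."""

    chrom_length: int = 200_000
    depth: float = 100.0  # mean input reads per bp
    replicated_interval: tuple | None = None  # bp interval with enrichment
    enrichment_fold: float = 3.0  # the replication-following fold (2-4x)
    ter_excluded_interval: tuple | None = None  # baseline inside
    peaks: list = field(default_factory=list)  # (center, width, fold)


def _interval_mask(n: int, interval) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    if interval is not None:
        a, b = interval
        mask[np.arange(a, b) % n] = True
    return mask


def chip_rate_profile(spec: SyntheticChipSpec) -> np.ndarray:
    """Expected IP rate per bp (input rate is flat at spec.depth)."""
    n = spec.chrom_length
    rate = np.full(n, spec.depth, dtype=float)
    rep = _interval_mask(n, spec.replicated_interval)
    ter = _interval_mask(n, spec.ter_excluded_interval)
    rate[rep & ~ter] *= spec.enrichment_fold
    for center, width, fold in spec.peaks:
        idx = np.arange(center - width // 2, center - width // 2 + width) % n
        rate[idx] = spec.depth * fold
    return rate


def gen_chip_experiment(spec: SyntheticChipSpec,
                        seed: int = 0) -> tuple[CoverageTrack, CoverageTrack]:
    """(IP, input) coverage pair drawn from the spec's Poisson rates."""
    rng = np.random.default_rng(seed)
    ip = rng.poisson(chip_rate_profile(spec)).astype(float)
    inp = rng.poisson(np.full(spec.chrom_length, spec.depth)).astype(float)
    return CoverageTrack(ip, "IP"), CoverageTrack(inp, "input")


def _instantiate(motif_word: str, rng) -> str:
    """Sample a concrete sequence from an IUPAC word."""
    return "".join(c if c in "ACGT" else rng.choice(list(IUPAC[c]))
                   for c in motif_word.upper())


DIF_SITE = "GGTGCGCATAATGTATATTATGTTAAAT"  # E. coli dif (28 bp)


def gen_genome(length: int, planted_sites: list[int], dif: int | None = None,
               motif: Motif | None = None, seed: int = 0,
               max_resample: int = 50) -> tuple[str, dict]:
    """Random genome with motif instances planted at the given positions.

    The background is rejection-resampled so it contains no spurious motif
    matches (on either strand); planted instances have degenerate codes
    sampled concretely.  Returns (sequence, features) where features records
    the planted site positions and dif.
    """
    motif = motif or Motif()
    rng = np.random.default_rng(seed)
    k = motif.length
    planted = sorted(planted_sites)
    for a, b in zip(planted, planted[1:]):
        if b - a < k:
            raise ValueError("planted sites overlap")
    if planted and (planted[0] + length - planted[-1]) < k:
        raise ValueError("planted sites overlap across the origin")

    import re
    from .mats_genomics import _scan_words

    seq = rng.choice(list("ACGT"), size=length)
    protected = np.zeros(length, dtype=bool)
    for p in planted:
        idx = np.arange(p, p + k) % length
        seq[idx] = list(_instantiate(motif.iupac or "", rng))
        protected[idx] = True
    if dif is not None:
        idx = np.arange(dif, dif + len(DIF_SITE)) % length
        if protected[idx].any():
            raise ValueError("dif overlaps a planted site")
        seq[idx] = list(DIF_SITE)
        protected[idx] = True

    planted_set = set(planted)
    for _ in range(max_resample):
        genome = "".join(seq)
        spurious = [pos for pos, *_ in _scan_words(genome, motif, circular=True)
                    if pos not in planted_set]
        if not spurious:
            return genome, {"matS": planted, "dif": dif,
                            "length": length, "motif": motif.iupac}
        for pos in spurious:
            idx = np.arange(pos, pos + k) % length
            free = idx[~protected[idx]]
            if len(free) == 0:
                raise ValueError("planted density too high to avoid "
                                 "spurious matches")
            seq[free] = rng.choice(list("ACGT"), size=len(free))
    raise ValueError("could not purge spurious motif matches")


def load_spec(path):
    """Load a generator spec from a YAML mapping.

    The mapping's ``kind`` key selects the spec type (``map`` or ``chip``);
    remaining keys are the dataclass fields.  Interval fields given as
    2-item lists become tuples.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    kind = data.pop("kind", "map")
    for key in ("ter_interval", "replicated_interval",
                "ter_excluded_interval"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    if "peaks" in data:
        data["peaks"] = [tuple(p) for p in data["peaks"]]
    if kind == "map":
        return SyntheticMapSpec(**data)
    if kind == "chip":
        return SyntheticChipSpec(**data)
    raise ValueError(f"unknown spec kind: {kind!r}")


@dataclass(frozen=True)
class Rearrangement:
    """Excision of segment [start, end) and reinsertion at insertion_point
    (a coordinate on the segment-free genome is *not* used: the insertion
    point is given on the original genome and must lie outside the segment)."""

    start: int
    end: int
    insertion_point: int
    inverted: bool = False

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("empty segment")
        if self.start <= self.insertion_point < self.end:
            raise ValueError("insertion point inside the segment")


def liftover(pos: int, r: Rearrangement, length: int) -> int:
    """New coordinate of an original position after the rearrangement.

    Convention: literal string cut-and-paste.  The segment is excised (gap
    closed by shifting everything downstream of it left), then reinserted
    immediately before the base that sat at ``insertion_point``.
    """
    if not 0 <= pos < length:
        raise ValueError("position outside chromosome")
    a, b, c = r.start, r.end, r.insertion_point
    seg_len = b - a
    ins = c - seg_len if c >= b else c  # insertion offset on the excised genome
    if a <= pos < b:  # inside the segment
        off = pos - a
        if r.inverted:
            off = seg_len - 1 - off
        return ins + off
    gapless = pos - seg_len if pos >= b else pos
    return gapless + seg_len if gapless >= ins else gapless


def liftover_inverse(newpos: int, r: Rearrangement, length: int) -> int:
    """Original coordinate of a position on the rearranged genome."""
    if not 0 <= newpos < length:
        raise ValueError("position outside chromosome")
    a, b, c = r.start, r.end, r.insertion_point
    seg_len = b - a
    ins = c - seg_len if c >= b else c
    if ins <= newpos < ins + seg_len:  # inside the relocated segment
        off = newpos - ins
        if r.inverted:
            off = seg_len - 1 - off
        return a + off
    gapless = newpos - seg_len if newpos >= ins + seg_len else newpos
    return gapless + seg_len if gapless >= a else gapless


def transpose_segment(genome: str, r: Rearrangement):
    """Apply the rearrangement to a sequence; returns (new_genome, lift, unlift).

    The liftover functions are exact coordinate bijections; base identity is
    preserved (reverse-complemented when inverted).
    """
    from Bio.Seq import Seq

    n = len(genome)
    if r.end > n:
        raise ValueError("segment outside chromosome")
    seg = genome[r.start:r.end]
    if r.inverted:
        seg = str(Seq(seg).reverse_complement())
    rest = genome[:r.start] + genome[r.end:]
    ins = r.insertion_point - (r.end - r.start) if r.insertion_point >= r.end \
        else r.insertion_point
    new = rest[:ins] + seg + rest[ins:]
    lift = lambda p: liftover(p, r, n)
    unlift = lambda p: liftover_inverse(p, r, n)
    return new, lift, unlift
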