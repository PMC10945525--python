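"""Readers and writers for the plain-text formats the pipeline consumes.

Internally everything is 0-based half-open; BED and bedGraph keep that
convention, other text output (pairs, site tables) is 1-based inclusive as
genome browsers expect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chip_cov import Peak
from .contact_map import ContactMap
from .mats_genomics import MotifSite

PAIRS_COLUMNS = ["readID", "pos1", "strand1", "pos2", "strand2"]


def read_pairs(path) -> pd.DataFrame:
    """Read a mapped read-pair table.

    Accepts the native 5-column TSV (readID pos1 strand1 pos2 strand2,
    1-based positions) or a 4DN .pairs-style file (# header lines, columns
    readID chrom1 pos1 chrom2 pos2 strand1 strand2).  Positions come back
    0-based.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):  # .pairs style
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        df = df.iloc[:, [0, 2, 4, 5, 6]]
        df.columns = ["readID", "pos1", "pos2", "strand1", "strand2"]
        df = df[PAIRS_COLUMNS]
    else:
        df = pd.read_csv(path, sep="\t")
        df = df[PAIRS_COLUMNS]
    df["pos1"] = df["pos1"].astype(np.int64) - 1
    df["pos2"] = df["pos2"].astype(np.int64) - 1
    return df


def write_pairs(df: pd.DataFrame, path) -> None:
    out = df[PAIRS_COLUMNS].copy()
    out["pos1"] = out["pos1"] + 1
    out["pos2"] = out["pos2"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path, bin_size: int = 5000, circular: bool = True,
                state: str = "raw") -> ContactMap:
    """Dense bin-by-bin TSV -> ContactMap (all-zero rows become masked bins)."""
    m = np.loadtxt(path, delimiter="\t")
    masked = frozenset(np.flatnonzero(m.sum(axis=1) == 0).tolist())
    return ContactMap(m, bin_size, circular=circular, masked_bins=masked,
                      state=state)


def write_matrix(cm: ContactMap, path) -> None:
    np.savetxt(path, cm.matrix, delimiter="\t", fmt="%.10g")


def read_genome(path) -> str:
    """First record of a FASTA file as an uppercase string."""
    rec = next(SeqIO.parse(path, "fasta"))
    return str(rec.seq).upper()


def write_bedgraph(values: np.ndarray, path, chrom: str = "chr",
                   step: int = 1) -> None:
    """Per-position (or per-bin, with step = bin size) track as bedGraph."""
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{i * step}\t{(i + 1) * step}\t{v:.6g}\n")


def read_bedgraph(path, chrom_length: int) -> np.ndarray:
    """bedGraph -> dense per-bp array (NaN where uncovered)."""
    out = np.full(chrom_length, np.nan)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    for _, row in df.iterrows():
        out[int(row.start):int(row.end)] = row.value
    return out


def write_peaks_bed(peaks: list[Peak], path, chrom: str = "chr",
                    chrom_length: int | None = None) -> None:
    with open(path, "w") as fh:
        for k, p in enumerate(peaks):
            end = p.end if chrom_length is None else min(p.end, chrom_length)
            fh.write(f"{chrom}\t{p.start}\t{end}\tpeak_{k + 1}\t"
                     f"{p.center}\t{p.max_fold:.3g}\n")


def write_sites_bed(sites: list[MotifSite], path, chrom: str = "chr",
                    site_length: int = 13) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{chrom}\t{s.position}\t{s.position + site_length}\t"
                     f"{s.sequence}\t{s.score:.3g}\t{s.strand}\n")
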