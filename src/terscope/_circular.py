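"""Helpers for arithmetic on circular (and linear) chromosome coordinates."""

from __future__ import annotations

import numpy as np


def circular_distance(i, j, n: int, circular: bool = True):
    """Shortest separation between coordinates ``i`` and ``j`` on a chromosome
    of ``n`` units.  Works elementwise on arrays."""
    d = np.abs(np.asarray(i) - np.asarray(j))
    if circular:
        d = np.minimum(d, n - d)
    return d


def pairwise_distance_matrix(n: int, circular: bool = True) -> np.ndarray:
    """N x N matrix of genomic separations between bin indices."""
    idx = np.arange(n)
    return circular_distance(idx[:, None], idx[None, :], n, circular)


def wrap(pos, n: int):
    """Map a (possibly negative or overflowing) coordinate onto [0, n)."""
    return np.asarray(pos) % n if not np.isscalar(pos) else pos % n


def signed_offset(pos, anchor: int, n: int):
    """Signed circular offset of ``pos`` from ``anchor``, in (-n/2, n/2]."""
    rel = (np.asarray(pos) - anchor) % n
    return np.where(rel > n / 2, rel - n, rel)
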