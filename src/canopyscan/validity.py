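"""Clustering-effect test: average fuzzy entropy of a partition.

v_PE(U) = -(1/n) sum_j sum_i u_ij ln(u_ij), with u ln u = 0 at u = 0 by
continuity.  A crisp partition scores 0; a maximally fuzzy one scores ln(c).
Smaller values mean less classification uncertainty, i.e. a better split of
the range stream into distinct echo layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .fuzzy_core import FuzzyPartition

__all__ = ["EntropyReport", "fuzzy_entropy"]


@dataclass(frozen=True)
class EntropyReport:
    """Partition entropy with its cluster count and ln(c)-normalized form."""

    v_pe: float
    c: int
    normalized: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_pe <= np.log(self.c) + 1e-12:
            raise ValueError("v_PE outside [0, ln(c)]")


def fuzzy_entropy(partition: FuzzyPartition) -> EntropyReport:
    """Average fuzzy entropy of the membership matrix (natural log)."""
    u = partition.memberships
    n = partition.n
    v = float(-xlogy(u, u).sum() / n)
    # Clamp the tiny negative values float summation can leave for crisp U.
    v = max(v, 0.0)
    return EntropyReport(v_pe=v, c=partition.c, normalized=v / np.log(partition.c))
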