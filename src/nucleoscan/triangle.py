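"""Triangle statistic over scan windows, built from median-unbiased odds.

A scan window of width W is split into flanks A, C and a central region B.
Central enrichment is measured as the smaller of the odds B/(A) and B/(C) --
estimated median-unbiasedly rather than by the MLE, which is unstable at
small mass -- divided by its value under a uniform landscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from nucleoscan.center_model import Landscape

logger = logging.getLogger(__name__)

#: Finite stand-in for infinite odds (p_hat == 1 happens only when a flank
#: carries exactly zero mass).
ODDS_CAP = 1e12


@dataclass(frozen=True)
class WindowPartition:
    """Widths of the scan window and its three sub-windows (bp)."""

    W: int = 200
    A_w: int = 75
    B_w: int = 50
    C_w: int = 75

    def __post_init__(self) -> None:
        if self.A_w + self.B_w + self.C_w != self.W:
            raise ValueError(
                f"A_w + B_w + C_w = {self.A_w + self.B_w + self.C_w} != W = {self.W}"
            )
        if min(self.A_w, self.B_w, self.C_w) < 1:
            raise ValueError("sub-window widths must all be >= 1")

    @property
    def null_odds(self) -> float:
        """Odds B/A (or B/C) expected under a uniform landscape."""
        return 2.0 * self.B_w / (self.W - self.B_w)


@dataclass(frozen=True)
class OddsEstimate:
    """Median-unbiased estimate of a success probability and its odds.

    ``p_hat`` is the midpoint of the boundary values ``p_hat1 >= p_hat2``
    delimiting the median-unbiased range.
    """

    p_hat1: float
    p_hat2: float
    p_hat: float
    odds: float


@dataclass
class TriangleTrack:
    """Triangle statistics indexed by scan-window start position.

    ``t_values[k]`` belongs to the window whose leftmost coordinate is
    ``start_offset + k`` (1-based).
    """

    chrom: str
    start_offset: int
    t_values: np.ndarray


def _mue_boundaries(m: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized boundary values (p_hat1, p_hat2) of the MUE range.

    p_hat1 solves I_p(m+1, M-m) = 1/2 and p_hat2 solves I_p(m, M-m+1) = 1/2
    via direct inversion of the regularized incomplete beta function.
    Conventions: m == 0 gives p_hat2 = 0; m == M gives p_hat1 = 1.
    Requires M > 0 elementwise.
    """
    m = np.asarray(m, dtype=float)
    M = np.asarray(M, dtype=float)
    m = np.clip(m, 0.0, M)  # guard float fuzz from prefix-sum differences
    p1 = np.ones_like(m)
    interior = M - m > 0
    if np.any(interior):
        p1[interior] = special.betaincinv(
            m[interior] + 1.0, (M - m)[interior], 0.5
        )
    p2 = np.zeros_like(m)
    interior = m > 0
    if np.any(interior):
        p2[interior] = special.betaincinv(
            m[interior], (M - m)[interior] + 1.0, 0.5
        )
    return p1, p2


def _odds_from_p(p: np.ndarray) -> np.ndarray:
    odds = np.full_like(p, ODDS_CAP)
    finite = p < 1.0
    odds[finite] = p[finite] / (1.0 - p[finite])
    return np.minimum(odds, ODDS_CAP)


def mue_success_prob(m: float, M: float) -> OddsEstimate:
    """Median-unbiased estimate of a Bernoulli success probability.

    ``m`` successes (non-negative real) out of ``M`` trials (positive real,
    ``m <= M``); the binomial tail conditions generalize to non-integer
    counts through the regularized incomplete beta function.
    """
    if M <= 0:
        raise ValueError(f"M must be positive, got {M}")
    if not 0 <= m <= M:
        raise ValueError(f"m must lie in [0, M]; got m={m}, M={M}")
    p1, p2 = _mue_boundaries(np.array([m]), np.array([M]))
    p_hat = 0.5 * (p1 + p2)
    odds = _odds_from_p(p_hat)
    return OddsEstimate(
        p_hat1=float(p1[0]),
        p_hat2=float(p2[0]),
        p_hat=float(p_hat[0]),
        odds=float(odds[0]),
    )


def _side_odds_vec(m: np.ndarray, M: np.ndarray) -> np.ndarray:
    """MUE odds per element; sides with zero trials get the odds cap."""
    out = np.full(m.shape, ODDS_CAP)
    pos = M > 0
    if np.any(pos):
        p1, p2 = _mue_boundaries(m[pos], M[pos])
        out[pos] = _odds_from_p(0.5 * (p1 + p2))
    return out


def triangle_statistic(
    A: float, B: float, C: float, partition: WindowPartition | None = None
) -> float:
    """Triangle statistic of one window from its three sub-window masses.

    Returns ``min(odds(B, A+B), odds(B, C+B)) / null_odds`` where the odds
    are median-unbiased.  An all-zero window scores 0 by convention; a side
    with zero total mass is treated as uninformative (odds cap), so the
    other side decides.
    """
    partition = partition or WindowPartition()
    if A < 0 or B < 0 or C < 0:
        raise ValueError(f"window masses must be non-negative: {(A, B, C)}")
    if A == 0 and B == 0 and C == 0:
        return 0.0
    m = np.array([B, B])
    M = np.array([A + B, C + B])
    odds = _side_odds_vec(m, M)
    return float(min(odds[0], odds[1]) / partition.null_odds)


def scan_triangle(
    landscape: Landscape, partition: WindowPartition | None = None
) -> TriangleTrack:
    """Triangle statistic for every window start position of a landscape.

    Windows advance 1 bp at a time; sub-window masses come from prefix sums
    so the scan is linear in chromosome length, with the incomplete-beta
    inversions vectorized across windows.
    """
    partition = partition or WindowPartition()
    W, A_w, B_w = partition.W, partition.A_w, partition.B_w
    scores = landscape.scores
    n = len(scores) - W + 1
    if n < 1:
        logger.warning(
            "%s: landscape span %d shorter than scan window %d; empty track",
            landscape.chrom,
            len(scores),
            W,
        )
        return TriangleTrack(
            chrom=landscape.chrom,
            start_offset=landscape.start,
            t_values=np.zeros(0),
        )
    prefix = np.concatenate([[0.0], np.cumsum(scores)])
    A = prefix[A_w : A_w + n] - prefix[0:n]
    B = prefix[A_w + B_w : A_w + B_w + n] - prefix[A_w : A_w + n]
    C = prefix[W : W + n] - prefix[A_w + B_w : A_w + B_w + n]
    # prefix differences can go negative by an ulp on long zero stretches
    np.maximum(A, 0.0, out=A)
    np.maximum(B, 0.0, out=B)
    np.maximum(C, 0.0, out=C)
    odds_ba = _side_odds_vec(B, A + B)
    odds_bc = _side_odds_vec(B, C + B)
    t = np.minimum(odds_ba, odds_bc) / partition.null_odds
    t[(A + B + C) == 0.0] = 0.0
    return TriangleTrack(
        chrom=landscape.chrom, start_offset=landscape.start, t_values=t
    )
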