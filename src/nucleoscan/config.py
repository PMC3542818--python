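"""Run configuration shared by the detection and FDR stages."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

#: Half-range of the uniform read-shaking distribution used in FDR
#: simulations; fixed at half a nucleosome footprint.
SHAKE_HALF_RANGE = 73

#: Default beta shape parameters of the read-offset distribution
#: (maximum-likelihood fit to paired-end yeast mononucleosome data).
DEFAULT_ALPHA = 1.9204
DEFAULT_BETA = 1.8937


@dataclass
class ScanConfig:
    """All tunables of a detection run.

    Attributes
    ----------
    W : int
        Scan-window width in bp.
    A_w, B_w, C_w : int
        Widths of the left, central and right sub-windows; must sum to ``W``.
    t_c : float
        Triangle-statistic cutoff a window must reach to be callable.
    F : float
        FDR cutoff; candidates with estimated FDR above ``F`` are dropped.
    S : int
        Number of read-shaking simulations used for FDR estimation.
    T : int
        Worker-pool size for chunked scanning (does not affect results).
    shake_half_range : int
        Half-range of the uniform shake distribution (fixed at 73).
    alpha, beta_param : float
        Beta shape parameters of the read-to-center offset distribution.
    seed : int
        Master seed driving every stochastic stage.
    min_mapq : int
        Minimum mapping quality for SAM/BAM records (BED is never filtered).
    chunk_interval : int
        Target core length of one scanning chunk in bp.
    """

    W: int = 200
    A_w: int = 75
    B_w: int = 50
    C_w: int = 75
    t_c: float = 1.7
    F: float = 0.01
    S: int = 3
    T: int = field(default_factory=lambda: os.cpu_count() or 1)
    shake_half_range: int = SHAKE_HALF_RANGE
    alpha: float = DEFAULT_ALPHA
    beta_param: float = DEFAULT_BETA
    seed: int = 0
    min_mapq: int = 0
    chunk_interval: int = 1_000_000

    def __post_init__(self) -> None:
        if self.A_w + self.B_w + self.C_w != self.W:
            raise ValueError(
                f"sub-window widths {self.A_w}+{self.B_w}+{self.C_w} "
                f"must sum to W={self.W}"
            )
        if min(self.A_w, self.B_w, self.C_w) < 1:
            raise ValueError("all sub-window widths must be >= 1")
        if self.t_c <= 0:
            raise ValueError("t_c must be positive")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must lie in [0, 1]")
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.alpha <= 0 or self.beta_param <= 0:
            raise ValueError("beta shape parameters must be positive")
        if self.chunk_interval < 10 * self.W:
            raise ValueError("chunk_interval must be >= 10*W")

    @property
    def partition(self):
        from nucleoscan.triangle import WindowPartition

        return WindowPartition(self.W, self.A_w, self.B_w, self.C_w)
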