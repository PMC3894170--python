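"""Copy-number estimation from read depth and from qPCR delta-delta-Ct.

Read depth scales linearly with the number of genomic copies: a region
present in ``c`` copies in a genome sequenced to haploid depth ``λ``
accumulates Poisson(c*λ) reads per base.  Normalizing smoothed per-base
depth by the mean depth of known-diploid control regions therefore gives
per-base copy estimates ``2 * depth / control_mean``, a region mean, and
a discrete call by rounding.  Fractional region means are first-class
output (real lineages show intermediate values, e.g. three-to-four
copies); no GC correction is applied.

qPCR copy number follows the standard delta-delta-Ct model: each cycle
multiplies template by the amplification efficiency, so
copies = calibrator_copies * efficiency ** (-ΔΔCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import InvalidParameterError

__all__ = [
    "DepthTrack",
    "CopyCall",
    "copy_number_from_depth",
    "qpcr_copy_number",
]


@dataclass
class DepthTrack:
    """Per-base read depth for a target contig plus a diploid control mean."""

    contig: str
    depth: np.ndarray  # (L,) reads per base, 0-based positions
    control_mean: float  # mean depth over known-diploid control regions
    window: int = 1000  # default window for window-averaged output

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if np.any(self.depth < 0):
            raise InvalidParameterError("depths must be >= 0")

    def windowed(self) -> pd.DataFrame:
        """Window-averaged depth (BED-style 0-based half-open intervals)."""
        L = len(self.depth)
        n = -(-L // self.window)
        starts = np.arange(n) * self.window
        ends = np.minimum(starts + self.window, L)
        means = [self.depth[s:e].mean() for s, e in zip(starts, ends)]
        return pd.DataFrame(
            {"chrom": self.contig, "start": starts, "end": ends, "depth": means}
        )


@dataclass
class CopyCall:
    """Copy-number estimate for a region: per-base track, mean, discrete call."""

    contig: str
    region: tuple[int, int]  # 0-based half-open
    per_base: np.ndarray  # copy estimate per base over the region
    region_mean: float
    call: int

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [self.contig],
                "start": [self.region[0]],
                "end": [self.region[1]],
                "mean_copy": [self.region_mean],
                "call": [self.call],
            }
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def copy_number_from_depth(
    track: DepthTrack,
    region: tuple[int, int] | None = None,
    smoothing_window: int = 1000,
) -> CopyCall:
    """Estimate copy number over a region from a normalized depth track.

    Per-base copy = 2 * smoothed depth / control diploid mean, with a
    sliding-mean smoother of ``smoothing_window`` bp; the discrete call
    rounds the region mean half-up.  Scale-invariant: multiplying target
    and control depths by a constant leaves estimates unchanged.
    """
    if track.control_mean <= 0:
        raise InvalidParameterError("control mean depth must be > 0 to normalize")
    L = len(track.depth)
    if region is None:
        region = (0, L)
    start, end = region
    if not (0 <= start < end <= L):
        raise InvalidParameterError(f"region {region} empty or outside track [0, {L})")
    smoothed = uniform_filter1d(
        track.depth, size=max(1, smoothing_window), mode="nearest"
    )
    per_base = 2.0 * smoothed[start:end] / track.control_mean
    region_mean = float(per_base.mean())
    return CopyCall(
        contig=track.contig,
        region=(start, end),
        per_base=per_base,
        region_mean=region_mean,
        call=_round_half_up(region_mean),
    )


def qpcr_copy_number(
    delta_delta_ct: float,
    efficiency: float = 2.0,
    calibrator_copies: int = 2,
) -> float:
    """Copy number from a qPCR delta-delta-Ct measurement.

    ``efficiency`` is the per-cycle amplification factor in (1, 2]
    (2 = perfect doubling); the calibrator is a known-copy reference
    (default diploid).
    """
    if not (1.0 < efficiency <= 2.0):
        raise InvalidParameterError("efficiency must be in (1, 2]")
    if calibrator_copies <= 0:
        raise InvalidParameterError("calibrator_copies must be > 0")
    return calibrator_copies * efficiency ** (-delta_delta_ct)
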