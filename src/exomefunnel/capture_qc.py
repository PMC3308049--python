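"""Capture-performance metrics over per-target-base depth.

The panel mirrors standard exome-capture QC reporting: percent of target
bases covered at 1/5/10/20x, covered/uncovered base counts, mean and
median depth, the on-target read fraction, and the uniformity statistic
NC80 — the depth exceeded by 80% of targeted bases divided by the mean
depth (1.0 for perfectly uniform capture). Its reciprocal 1/NC80
approximates the extra sequencing needed to reach uniform coverage of
80% of the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .genome_model import TargetSet

__all__ = [
    "DepthProfile",
    "CaptureMetrics",
    "compute_metrics",
    "coverage_identity_check",
    "on_target_fraction",
    "round_half_up",
    "read_depth_tsv",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at the given decimal, as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DepthProfile:
    """Per-target-base read depths plus read-placement counts."""

    depths: np.ndarray  # one non-negative int per targeted position
    target_set: TargetSet | None = None
    total_reads: int = 0
    on_target_reads: int = 0

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one value per targeted base")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")
        if self.target_set is not None and len(self.depths) != self.target_set.total_bases:
            raise ValueError(
                f"{len(self.depths)} depth values for "
                f"{self.target_set.total_bases} target bases"
            )
        if self.on_target_reads > self.total_reads:
            raise ValueError("on_target_reads exceeds total_reads")


@dataclass
class CaptureMetrics:
    pct_covered_1x: float
    pct_covered_5x: float
    pct_covered_10x: float
    pct_covered_20x: float
    bases_covered: int
    bases_not_covered: int
    mean_depth: float
    median_depth: float
    nc80: float | None
    inv_nc80: float | None
    pct_on_target: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def d80(depths: np.ndarray) -> int:
    """Largest depth d such that >= 80% of target bases have depth >= d."""
    n = len(depths)
    k = int(np.ceil(0.8 * n))  # need at least k bases at >= d
    return int(np.sort(depths)[::-1][k - 1])


def compute_metrics(profile: DepthProfile) -> CaptureMetrics:
    """Compute the full coverage panel from a depth profile.

    Percentages are rounded half-up to 2 decimals; NC80 and 1/NC80 are
    computed from unrounded intermediates. An all-zero profile reports
    NC80 as missing (None).
    """
    d = profile.depths
    if len(d) == 0:
        raise ValueError("empty depth profile")
    n = len(d)
    covered = int((d >= 1).sum())
    mean = float(d.mean())
    pct = {
        t: round_half_up(100.0 * float((d >= t).sum()) / n) for t in (1, 5, 10, 20)
    }
    if mean > 0:
        depth80 = d80(d)
        nc80 = depth80 / mean
        inv = mean / depth80 if depth80 > 0 else None
    else:
        nc80 = inv = None
    pct_on = None
    if profile.total_reads > 0:
        pct_on = on_target_fraction(profile.on_target_reads, profile.total_reads)
    return CaptureMetrics(
        pct_covered_1x=pct[1],
        pct_covered_5x=pct[5],
        pct_covered_10x=pct[10],
        pct_covered_20x=pct[20],
        bases_covered=covered,
        bases_not_covered=n - covered,
        mean_depth=mean,
        median_depth=float(np.median(d)),
        nc80=nc80,
        inv_nc80=inv,
        pct_on_target=pct_on,
    )


def coverage_identity_check(bases_covered: int, total_target_bases: int) -> float:
    """Percent of target bases covered, half-up to 2 decimals."""
    if total_target_bases == 0:
        raise ValueError("total_target_bases must be positive")
    if not (0 <= bases_covered <= total_target_bases):
        raise ValueError("bases_covered out of range")
    return round_half_up(100.0 * bases_covered / total_target_bases)


def on_target_fraction(on_target_reads: int, total_reads: int) -> float:
    """Percent of reads placed inside target regions, half-up to 2 decimals."""
    if total_reads == 0:
        raise ValueError("total_reads must be positive")
    if not (0 <= on_target_reads <= total_reads):
        raise ValueError("on_target_reads out of range")
    return round_half_up(100.0 * on_target_reads / total_reads)


def read_depth_tsv(path, targets: TargetSet | None = None) -> DepthProfile:
    """Read samtools-depth-style TSV (chrom, 1-based pos, depth) over targets."""
    depths = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, depth = line.split("\t")[:3]
            if targets is None or targets.contains(chrom, int(pos) - 1):
                depths.append(int(depth))
    return DepthProfile(np.array(depths, dtype=np.int64), target_set=None)


def metrics_table(samples: dict[str, CaptureMetrics]):
    """One column per sample, rows in the conventional report order."""
    import pandas as pd

    return pd.DataFrame({name: m.to_dict() for name, m in samples.items()})
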