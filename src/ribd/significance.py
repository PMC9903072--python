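"""Genome-wide rIBD distribution summary, normal-theory cut-offs, and regions.

The genome-wide rIBD scores are approximately normal, so extreme windows are
flagged with empirical cut-offs mean ± k·SD (k = 3 by default, a stringent
threshold leaving about 0.27% — commonly rounded to 0.3% — of a normal
distribution in the two tails combined).  Windows strictly beyond a cut-off
form the significant positive / negative lists, which are then merged into
contiguous candidate regions of adaptive introgression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import WindowGrid
from .io import ValidationError, WindowRecord

__all__ = [
    "RibdSummary",
    "SignificantRegion",
    "distribution_summary",
    "normal_tail_mass",
    "significant_windows",
    "merge_regions",
]


@dataclass(frozen=True)
class RibdSummary:
    """Mean, sample SD (n−1 denominator), and derived mean ± k·SD cut-offs."""

    mean: float
    sd: float
    n_windows: int
    k: float
    cut_high: float
    cut_low: float
    tail_mass: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError(f"negative SD {self.sd}")
        if not math.isclose(self.cut_high, self.mean + self.k * self.sd, rel_tol=1e-12, abs_tol=1e-12):
            raise ValidationError("cut_high != mean + k*sd")
        if not math.isclose(self.cut_low, self.mean - self.k * self.sd, rel_tol=1e-12, abs_tol=1e-12):
            raise ValidationError("cut_low != mean - k*sd")


def normal_tail_mass(k: float) -> float:
    """Two-tailed standard-normal mass beyond ±k SD: 2·(1 − Φ(k)) = erfc(k/√2).

    At k = 3 this is ≈ 0.0027, i.e. about 0.3% of the distribution split
    between the two tails.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return math.erfc(k / math.sqrt(2.0))


def cutoffs_from_moments(mean: float, sd: float, k: float = 3.0) -> tuple[float, float]:
    """(cut_high, cut_low) = mean ± k·SD."""
    return mean + k * sd, mean - k * sd


def _included(
    records: Sequence[WindowRecord], exclude_truncated: bool, exclude_zero_evidence: bool
) -> list[WindowRecord]:
    out = []
    for rec in records:
        if exclude_truncated and rec.truncated:
            continue
        if exclude_zero_evidence and rec.zero_evidence:
            continue
        out.append(rec)
    return out


def distribution_summary(
    records: Sequence[WindowRecord],
    k: float = 3.0,
    exclude_truncated: bool = False,
    exclude_zero_evidence: bool = False,
) -> RibdSummary:
    """Summarize the pooled rIBD distribution and derive mean ± k·SD cut-offs.

    Truncated terminal windows and windows with no IBD evidence (which carry
    rIBD = 0) are included by default; either class can be excluded for
    sparse datasets.  Requires at least two windows after exclusions.
    """
    included = _included(records, exclude_truncated, exclude_zero_evidence)
    if len(included) < 2:
        raise ValidationError(
            f"need at least 2 windows to summarize, have {len(included)} after exclusions"
        )
    scores = np.array([rec.ribd for rec in included], dtype=float)
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    cut_high, cut_low = cutoffs_from_moments(mean, sd, k)
    return RibdSummary(
        mean=mean,
        sd=sd,
        n_windows=len(included),
        k=k,
        cut_high=cut_high,
        cut_low=cut_low,
        tail_mass=normal_tail_mass(k),
    )


def significant_windows(
    records: Sequence[WindowRecord],
    summary: RibdSummary,
    exclude_truncated: bool = False,
    exclude_zero_evidence: bool = False,
) -> tuple[list[WindowRecord], list[WindowRecord]]:
    """Split windows into (positive, negative) significant lists.

    Significance is strict: a window exactly at a cut-off is not significant.
    Both lists preserve the input (positional) order.
    """
    included = _included(records, exclude_truncated, exclude_zero_evidence)
    positive = [rec for rec in included if rec.ribd > summary.cut_high]
    negative = [rec for rec in included if rec.ribd < summary.cut_low]
    return positive, negative


@dataclass(frozen=True)
class SignificantRegion:
    """A run of contiguous significant windows merged into one reportable region."""

    chrom: str
    start: int
    end: int
    sign: str  # "positive" | "negative"
    n_windows: int
    peak_ribd: float
    mean_ribd: float

    def __post_init__(self):
        if self.sign not in ("positive", "negative"):
            raise ValidationError(f"sign must be positive/negative, got {self.sign!r}")
        if self.start >= self.end:
            raise ValidationError(f"invalid region interval [{self.start}, {self.end})")


def merge_regions(
    windows: Sequence[WindowRecord],
    grid: WindowGrid,
    max_gap_windows: int = 0,
    sign: str | None = None,
) -> list[SignificantRegion]:
    """Merge one tail's significant windows into regions.

    Windows must all come from the same tail (``sign`` is inferred from the
    scores when not given; a mix of positive and negative scores is an
    error) and be position-sorted.  Runs separated by at most
    ``max_gap_windows`` non-significant grid windows are merged; the region
    spans its member windows, ``peak_ribd`` is the most extreme member score.
    """
    if max_gap_windows < 0:
        raise ValueError("max_gap_windows must be >= 0")
    if not windows:
        return []
    if sign is None:
        has_pos = any(w.ribd > 0 for w in windows)
        has_neg = any(w.ribd < 0 for w in windows)
        if has_pos and has_neg:
            raise ValidationError(
                "mixed positive and negative scores in one merge call; "
                "merge each tail separately"
            )
        sign = "negative" if has_neg else "positive"
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be positive/negative, got {sign!r}")

    extreme = max if sign == "positive" else min
    regions: list[SignificantRegion] = []
    run: list[WindowRecord] = []
    run_idx = -1

    def flush():
        if not run:
            return
        scores = [w.ribd for w in run]
        regions.append(
            SignificantRegion(
                chrom=run[0].chrom,
                start=run[0].start,
                end=run[-1].end,
                sign=sign,
                n_windows=len(run),
                peak_ribd=extreme(scores),
                mean_ribd=float(np.mean(scores)),
            )
        )

    for rec in windows:
        idx = grid.window_index(rec.chrom, rec.start)
        if run and rec.chrom == run[-1].chrom and 0 < idx - run_idx <= max_gap_windows + 1:
            run.append(rec)
        else:
            if run and rec.chrom == run[-1].chrom and idx <= run_idx:
                raise ValidationError("significant windows not sorted or duplicated")
            flush()
            run = [rec]
        run_idx = idx
    flush()
    return regions
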