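"""Window grid construction, per-window IBD calling, and the rIBD score.

The scan partitions each chromosome into consecutive windows of nominal size
``w`` (default 10 kbp, the finest scale at which a single gene can still be
mapped).  For every admixed *unit* — by default each of the two haplotypes of
every admixed individual — and each source breed, the unit is called "IBD
with that breed" in a window when the union of its IBD tracts shared with any
member of that breed covers at least ``min_cov`` of the window.  The
population-level sharing fractions IBD_S1 and IBD_S2 are the fractions of
admixed units so called, and

    rIBD = IBD_S1 - IBD_S2

per window, ranging from -1 (all sharing with source breed 2) to +1 (all
sharing with source breed 1).  In normalized mode the two fractions are
rescaled to sum to one wherever there is any IBD evidence, which makes rIBD
directly interpretable as a two-way ancestry contrast: rIBD = 0.5 means
IBD_S1 = 0.75 against IBD_S2 = 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .io import (
    GenomeLayout,
    IbdSegment,
    PopulationManifest,
    ValidationError,
    WindowRecord,
)

__all__ = [
    "WindowGrid",
    "WindowCallMatrix",
    "build_window_grid",
    "window_coverage",
    "merge_intervals",
    "call_windows",
    "population_fraction",
    "ribd_scores",
    "invert_ribd",
    "compute_pipeline",
    "SIDES",
    "UNITS",
    "MODES",
]

SIDES = ("source1", "source2")
UNITS = ("haplotype", "individual", "pairwise")
MODES = ("raw", "normalized")

DEFAULT_WINDOW_SIZE = 10_000


@dataclass(frozen=True)
class WindowGrid:
    """Per-chromosome window starts/ends (0-based half-open), in layout order.

    With ``step == window_size`` (the default) windows tile each chromosome
    exactly: disjoint, union ``[0, L)``, terminal window truncated when the
    length is not a multiple of the window size.  A ``step < window_size``
    yields a true overlapping sliding grid.
    """

    layout: GenomeLayout
    window_size: int
    step: int
    starts: Mapping[str, np.ndarray]
    ends: Mapping[str, np.ndarray]

    def n_windows(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.starts[chrom])
        return sum(len(s) for s in self.starts.values())

    def bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self.starts[chrom], self.ends[chrom]

    def window_index(self, chrom: str, start: int) -> int:
        """Ordinal of the window starting at ``start`` on ``chrom``."""
        starts = self.starts[chrom]
        i = int(np.searchsorted(starts, start))
        if i >= len(starts) or starts[i] != start:
            raise KeyError(f"no window starting at {chrom}:{start}")
        return i

    def iter_windows(self) -> Iterable[tuple[str, int, int]]:
        for chrom in self.layout.names:
            for s, e in zip(self.starts[chrom], self.ends[chrom]):
                yield chrom, int(s), int(e)


def grid_from_records(records: Sequence[WindowRecord]) -> WindowGrid:
    """Reconstruct the window grid underlying a sorted window table.

    Used when significance runs from a saved table and the original layout
    is not at hand; chromosome lengths are taken as the last window end.
    """
    if not records:
        raise ValidationError("cannot build a grid from an empty table")
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    order: list[str] = []
    for rec in records:
        if rec.chrom not in starts:
            starts[rec.chrom] = []
            ends[rec.chrom] = []
            order.append(rec.chrom)
        starts[rec.chrom].append(rec.start)
        ends[rec.chrom].append(rec.end)
    layout = GenomeLayout(tuple((c, ends[c][-1]) for c in order))
    window_size = max(e - s for rec_s, rec_e in zip(starts.values(), ends.values())
                      for s, e in zip(rec_s, rec_e))
    steps = [b - a for c in order for a, b in zip(starts[c], starts[c][1:])]
    step = min(steps) if steps else window_size
    return WindowGrid(
        layout,
        window_size,
        step,
        {c: np.asarray(v, dtype=np.int64) for c, v in starts.items()},
        {c: np.asarray(v, dtype=np.int64) for c, v in ends.items()},
    )


def build_window_grid(
    layout: GenomeLayout, window_size: int = DEFAULT_WINDOW_SIZE, step: int | None = None
) -> WindowGrid:
    """Build the window grid for ``layout``.

    Parameters
    ----------
    window_size
        Nominal window length in bp (default 10,000).
    step
        Distance between consecutive window starts; defaults to
        ``window_size`` (non-overlapping tiling).
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    if step is None:
        step = window_size
    if step <= 0 or step > window_size:
        raise ValueError(f"step must be in (0, window_size], got {step}")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, length in layout.chromosomes:
        s = np.arange(0, length, step, dtype=np.int64)
        e = np.minimum(s + window_size, length)
        starts[chrom] = s
        ends[chrom] = e
    return WindowGrid(layout, window_size, step, starts, ends)


def window_coverage(
    seg_start: int, seg_end: int, win_start: int, win_end: int
) -> float:
    """Fraction of the window ``[win_start, win_end)`` covered by the segment."""
    if win_end <= win_start:
        raise ValueError("window must have positive length")
    overlap = min(seg_end, win_end) - max(seg_start, win_start)
    return max(overlap, 0) / (win_end - win_start)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Merge possibly-overlapping half-open intervals into a sorted disjoint set.

    Returns an ``(n, 2)`` int64 array; abutting intervals are coalesced.
    """
    ivs = sorted(intervals)
    if not ivs:
        return np.empty((0, 2), dtype=np.int64)
    merged: list[list[int]] = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _covered_lengths(
    merged: np.ndarray, win_starts: np.ndarray, win_ends: np.ndarray
) -> np.ndarray:
    """Covered bp per window given merged disjoint intervals (vectorized sweep)."""
    n_win = len(win_starts)
    if len(merged) == 0:
        return np.zeros(n_win, dtype=np.int64)
    s, e = merged[:, 0], merged[:, 1]
    cum = np.concatenate(([0], np.cumsum(e - s)))
    lo = np.searchsorted(e, win_starts, side="right")
    hi = np.searchsorted(s, win_ends, side="left")
    covered = cum[hi] - cum[lo]
    has = hi > lo
    lo_c = np.minimum(lo, len(s) - 1)
    hi_c = np.maximum(hi, 1) - 1
    covered -= np.where(has, np.maximum(0, win_starts - s[lo_c]), 0)
    covered -= np.where(has, np.maximum(0, e[hi_c] - win_ends), 0)
    return covered


@dataclass(frozen=True)
class WindowCallMatrix:
    """Boolean IBD calls for one source side: units × windows, per chromosome.

    ``units`` fixes the row order; absence of a call is False.  The
    aggregation unit is recorded so downstream code can interpret rows:
    ``haplotype`` rows are (sample, hap index) of the admixed breed,
    ``individual`` rows are admixed sample IDs, and ``pairwise`` rows are
    ((admixed sample, hap), (source sample, hap)) pairs.
    """

    grid: WindowGrid
    side: str
    unit: str
    units: tuple[Hashable, ...]
    calls: Mapping[str, np.ndarray]  # chrom -> bool array (n_units, n_windows)

    def counts(self, chrom: str) -> np.ndarray:
        """Number of units called IBD per window on ``chrom``."""
        return self.calls[chrom].sum(axis=0)

    @property
    def n_units(self) -> int:
        return len(self.units)


def _admixed_end(
    seg: IbdSegment, manifest: PopulationManifest, side: str
) -> tuple[tuple[str, int], tuple[str, int]] | None:
    """Return ((admixed sample, hap), (source sample, hap)) or None if not a side-pair."""
    role_a = manifest.role_of(seg.sample_a)
    role_b = manifest.role_of(seg.sample_b)
    if role_a == "admixed" and role_b == side:
        return (seg.sample_a, seg.hap_a), (seg.sample_b, seg.hap_b)
    if role_b == "admixed" and role_a == side:
        return (seg.sample_b, seg.hap_b), (seg.sample_a, seg.hap_a)
    return None


def _unit_list(manifest: PopulationManifest, side: str, unit: str) -> tuple[Hashable, ...]:
    admixed = manifest.samples("admixed")
    if unit == "haplotype":
        return tuple((s, h) for s in admixed for h in (1, 2))
    if unit == "individual":
        return tuple(admixed)
    if unit == "pairwise":
        source = manifest.samples(side)
        return tuple(
            ((s, h), (t, g)) for s in admixed for h in (1, 2) for t in source for g in (1, 2)
        )
    raise ValueError(f"unknown unit {unit!r}")


def call_windows(
    segments: Sequence[IbdSegment],
    grid: WindowGrid,
    manifest: PopulationManifest,
    side: str,
    unit: str = "haplotype",
    min_cov: float = 0.5,
) -> WindowCallMatrix:
    """Call per-unit, per-window IBD status against one source breed.

    For each admixed unit the IBD tracts it shares with *any* member of the
    side's breed are merged (overlapping tracts counted once) and the unit is
    called IBD in a window when the merged cover is at least
    ``min_cov`` × window length.  ``unit="individual"`` calls an individual
    when either of its haplotypes would be called; ``unit="pairwise"``
    produces one row per (admixed haplotype × source haplotype) pair with no
    cross-partner merging.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    if unit not in UNITS:
        raise ValueError(f"unit must be one of {UNITS}, got {unit!r}")
    if not (0 < min_cov <= 1):
        raise ValueError(f"min_cov must be in (0, 1], got {min_cov}")

    units = _unit_list(manifest, side, unit)
    # Thresholding always happens at the finest key: an admixed haplotype
    # (tracts from all side members merged) or, in pairwise mode, one
    # admixed-hap x source-hap pair.  An individual is called when either of
    # its haplotypes is called, not when their pooled coverage passes.
    if unit == "individual":
        fine_keys: tuple[Hashable, ...] = _unit_list(manifest, side, "haplotype")
    else:
        fine_keys = units
    index = {u: i for i, u in enumerate(fine_keys)}

    # (fine row, chrom) -> interval list
    buckets: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for seg in segments:
        pair = _admixed_end(seg, manifest, side)
        if pair is None:
            continue
        if seg.chrom not in grid.starts:
            raise ValidationError(f"segment chromosome {seg.chrom!r} not in window grid")
        adm_hap, src_hap = pair
        key: Hashable = (adm_hap, src_hap) if unit == "pairwise" else adm_hap
        buckets.setdefault((index[key], seg.chrom), []).append((seg.start, seg.end))

    calls: dict[str, np.ndarray] = {}
    for chrom in grid.layout.names:
        fine = np.zeros((len(fine_keys), grid.n_windows(chrom)), dtype=bool)
        ws, we = grid.bounds(chrom)
        for (row, seg_chrom), ivs in buckets.items():
            if seg_chrom != chrom:
                continue
            merged = merge_intervals(ivs)
            covered = _covered_lengths(merged, ws, we)
            fine[row] = covered >= min_cov * (we - ws)
        if unit == "individual":
            # rows come in (sample, 1), (sample, 2) pairs, in sample order
            calls[chrom] = fine[0::2] | fine[1::2]
        else:
            calls[chrom] = fine
    return WindowCallMatrix(grid, side, unit, units, calls)


def population_fraction(
    calls: WindowCallMatrix, manifest: PopulationManifest
) -> dict[str, np.ndarray]:
    """Per-window fraction of admixed units called IBD, per chromosome.

    For haplotype/individual units the denominator is the number of admixed
    haplotypes/individuals; for pairwise it is the number of
    admixed-haplotype × source-haplotype pairs.
    """
    if calls.n_units == 0:
        raise ValidationError("call matrix has no units (manifest had no admixed samples?)")
    return {
        chrom: calls.counts(chrom) / calls.n_units for chrom in calls.grid.layout.names
    }


def ribd_scores(
    f1: np.ndarray, f2: np.ndarray, mode: str = "normalized"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compute per-window (ibd_s1, ibd_s2, rIBD) from raw sharing fractions.

    Raw mode reports the fractions as given and rIBD = f1 - f2.  Normalized
    mode rescales so ibd_s1 + ibd_s2 = 1 wherever f1 + f2 > 0 (windows with
    no evidence report 0, 0, 0), which is the scale on which rIBD = 0.5
    means a 0.75 / 0.25 split between the two source breeds.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != f2.shape:
        raise ValidationError(f"fraction grids differ in shape: {f1.shape} vs {f2.shape}")
    if mode == "raw":
        return f1, f2, f1 - f2
    if mode == "normalized":
        total = f1 + f2
        with np.errstate(invalid="ignore", divide="ignore"):
            g1 = np.where(total > 0, f1 / np.where(total > 0, total, 1.0), 0.0)
            g2 = np.where(total > 0, f2 / np.where(total > 0, total, 1.0), 0.0)
        return g1, g2, g1 - g2
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def invert_ribd(ribd: float) -> tuple[float, float]:
    """Recover (IBD_S1, IBD_S2) from an rIBD score under the sum-to-one constraint.

    Since IBD_S1 + IBD_S2 = 1 and IBD_S1 - IBD_S2 = rIBD,
    IBD_S1 = (1 + rIBD) / 2 and IBD_S2 = (1 - rIBD) / 2; e.g. rIBD = 0.5
    corresponds to sharing fractions 0.75 and 0.25.
    """
    if not -1.0 <= ribd <= 1.0:
        raise ValueError(f"rIBD must be in [-1, 1], got {ribd}")
    return (1.0 + ribd) / 2.0, (1.0 - ribd) / 2.0


def compute_pipeline(
    segments: Sequence[IbdSegment],
    layout: GenomeLayout,
    manifest: PopulationManifest,
    window_size: int = DEFAULT_WINDOW_SIZE,
    unit: str = "haplotype",
    min_cov: float = 0.5,
    mode: str = "normalized",
    step: int | None = None,
) -> list[WindowRecord]:
    """Run the full scan: grid → per-side calls → fractions → rIBD records.

    Returns one :class:`~ribd.io.WindowRecord` per grid window, sorted by
    layout order and start position.  Deterministic for fixed inputs.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    grid = build_window_grid(layout, window_size, step)
    calls1 = call_windows(segments, grid, manifest, "source1", unit, min_cov)
    calls2 = call_windows(segments, grid, manifest, "source2", unit, min_cov)
    records: list[WindowRecord] = []
    for chrom in layout.names:
        c1 = calls1.counts(chrom)
        c2 = calls2.counts(chrom)
        f1 = c1 / calls1.n_units
        f2 = c2 / calls2.n_units
        g1, g2, r = ribd_scores(f1, f2, mode)
        ws, we = grid.bounds(chrom)
        for i in range(len(ws)):
            records.append(
                WindowRecord(
                    chrom=chrom,
                    start=int(ws[i]),
                    end=int(we[i]),
                    n_ibd_s1=int(c1[i]),
                    n_total_s1=calls1.n_units,
                    n_ibd_s2=int(c2[i]),
                    n_total_s2=calls2.n_units,
                    ibd_s1=float(g1[i]),
                    ibd_s2=float(g2[i]),
                    ribd=float(r[i]),
                    truncated=bool(we[i] - ws[i] < window_size),
                )
            )
    return records
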