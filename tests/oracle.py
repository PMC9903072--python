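"""Per-base brute-force re-implementation of the windowed rIBD scan.

Deliberately naive and independent of ribd.core: every unit is scored by
marking covered base pairs in a per-chromosome boolean mask and counting
them window by window.  Only usable at toy scale; the test-suite keeps
chromosomes to a few kilobases.
"""

from __future__ import annotations

import numpy as np

from ribd.io import GenomeLayout, IbdSegment, PopulationManifest, WindowRecord


def _partner_of(seg: IbdSegment, manifest: PopulationManifest, side: str, adm_hap):
    role_a = manifest.role_of(seg.sample_a)
    role_b = manifest.role_of(seg.sample_b)
    if role_a == "admixed" and role_b == side and (seg.sample_a, seg.hap_a) == adm_hap:
        return (seg.sample_b, seg.hap_b)
    if role_b == "admixed" and role_a == side and (seg.sample_b, seg.hap_b) == adm_hap:
        return (seg.sample_a, seg.hap_a)
    return None


def _hap_called(segments, manifest, side, adm_hap, chrom, length,
                win_bounds, min_cov, src_hap=None):
    mask = np.zeros(length, dtype=bool)
    for seg in segments:
        if seg.chrom != chrom:
            continue
        partner = _partner_of(seg, manifest, side, adm_hap)
        if partner is None:
            continue
        if src_hap is not None and partner != src_hap:
            continue
        mask[seg.start:seg.end] = True
    return [
        int(mask[ws:we].sum()) >= min_cov * (we - ws) for ws, we in win_bounds
    ]


def brute_force_pipeline(
    segments,
    layout: GenomeLayout,
    manifest: PopulationManifest,
    window_size: int,
    unit: str = "haplotype",
    min_cov: float = 0.5,
    mode: str = "normalized",
) -> list[WindowRecord]:
    adm_haps = [(s, h) for s in manifest.samples("admixed") for h in (1, 2)]
    records: list[WindowRecord] = []
    for chrom, length in layout.chromosomes:
        starts = list(range(0, length, window_size))
        win_bounds = [(s, min(s + window_size, length)) for s in starts]
        counts = {}
        totals = {}
        for side in ("source1", "source2"):
            if unit == "pairwise":
                src_haps = [(t, g) for t in manifest.samples(side) for g in (1, 2)]
                calls = [
                    _hap_called(segments, manifest, side, a, chrom, length,
                                win_bounds, min_cov, src_hap=b)
                    for a in adm_haps
                    for b in src_haps
                ]
            elif unit == "individual":
                calls = []
                for sample in manifest.samples("admixed"):
                    c1 = _hap_called(segments, manifest, side, (sample, 1), chrom,
                                     length, win_bounds, min_cov)
                    c2 = _hap_called(segments, manifest, side, (sample, 2), chrom,
                                     length, win_bounds, min_cov)
                    calls.append([a or b for a, b in zip(c1, c2)])
            else:
                calls = [
                    _hap_called(segments, manifest, side, a, chrom, length,
                                win_bounds, min_cov)
                    for a in adm_haps
                ]
            counts[side] = [sum(col) for col in zip(*calls)]
            totals[side] = len(calls)
        for i, (ws, we) in enumerate(win_bounds):
            c1, c2 = counts["source1"][i], counts["source2"][i]
            f1, f2 = c1 / totals["source1"], c2 / totals["source2"]
            if mode == "normalized":
                tot = f1 + f2
                if tot > 0:
                    f1, f2 = f1 / tot, f2 / tot
                else:
                    f1 = f2 = 0.0
            records.append(
                WindowRecord(
                    chrom=chrom, start=ws, end=we,
                    n_ibd_s1=c1, n_total_s1=totals["source1"],
                    n_ibd_s2=c2, n_total_s2=totals["source2"],
                    ibd_s1=f1, ibd_s2=f2, ribd=f1 - f2,
                    truncated=we - ws < window_size,
                )
            )
    return records
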