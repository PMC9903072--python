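"""Synthetic three-breed IBD-segment datasets with known local-ancestry truth.

The generator emulates the situation the scan is built for: an admixed breed
whose haplotypes are mosaics of material from two source breeds.  Each
admixed haplotype is partitioned into ancestry tracts with i.i.d.
exponential lengths (mean ``mean_tract_bp``); each tract derives from source
breed 1 with a position-dependent probability p(x) — ``baseline_p``
genome-wide, overridden inside configured introgressed intervals — and is
reported as IBD with ``segments_per_tract`` uniformly chosen haplotypes of
its source breed.  Detector imperfection is modelled by dropping true
segments independently (``drop_rate``, false negatives) and adding spurious
segments as a Poisson process (``spurious_rate`` per haplotype per Mb, false
positives).  Tracts are split at introgressed-interval boundaries before the
source draw, so the expected normalized rIBD has the exact closed form
2·p(x) − 1 everywhere, which is the analytic surface the test-suite checks
recovery against.

All randomness flows through one :func:`numpy.random.default_rng` stream
seeded from the config, with draws in a documented fixed order (per admixed
individual in manifest order, haplotype 1 then 2, chromosomes in layout
order: tract lengths, then per-tract source / partners / drop flags / LODs;
spurious segments last, in the same haplotype order), so identical configs
produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .core import WindowGrid, merge_intervals, _covered_lengths
from .io import GenomeLayout, IbdSegment, PopulationManifest, ValidationError

__all__ = [
    "SimulationConfig",
    "AncestryTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "true_window_ribd",
    "write_dataset",
    "load_config",
    "save_config",
]

HapKey = tuple[str, int]


def _default_layout() -> GenomeLayout:
    return GenomeLayout((("1", 5_000_000),))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic three-breed dataset.

    Defaults describe a modest livestock-style scan: 10 individuals per
    source breed, 20 admixed individuals, one 5 Mb chromosome, balanced
    ancestry (``baseline_p`` = 0.5), 500 kb mean ancestry tracts (admixture a
    handful of generations back), two reported IBD partners per tract, a 5%
    false-negative rate and 0.1 spurious segments per haplotype per Mb.
    """

    n_source1: int = 10
    n_source2: int = 10
    n_admixed: int = 20
    layout: GenomeLayout = field(default_factory=_default_layout)
    baseline_p: float = 0.5
    introgressed_intervals: tuple[tuple[str, int, int, float], ...] = ()
    mean_tract_bp: float = 500_000.0
    segments_per_tract: int = 2
    drop_rate: float = 0.05
    spurious_rate: float = 0.1
    lod_mean: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_source1, self.n_source2, self.n_admixed) < 1:
            raise ValidationError("each breed needs at least one individual")
        for name, val in (
            ("baseline_p", self.baseline_p),
            ("drop_rate", self.drop_rate),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {val}")
        if self.mean_tract_bp <= 0:
            raise ValidationError(f"mean_tract_bp must be positive, got {self.mean_tract_bp}")
        if self.segments_per_tract < 1:
            raise ValidationError("segments_per_tract must be >= 1")
        if self.spurious_rate < 0:
            raise ValidationError("spurious_rate must be >= 0")
        if self.lod_mean <= 0:
            raise ValidationError("lod_mean must be positive")
        ivs = tuple(
            (str(c), int(s), int(e), float(p)) for c, s, e, p in self.introgressed_intervals
        )
        object.__setattr__(self, "introgressed_intervals", ivs)
        for chrom, start, end, p in ivs:
            if chrom not in self.layout:
                raise ValidationError(f"introgressed interval on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.layout.length_of(chrom)):
                raise ValidationError(
                    f"introgressed interval [{start}, {end}) outside chromosome {chrom}"
                )
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"p_local must be in [0,1], got {p}")

    # -- flat-dict round trip for YAML configs --------------------------------

    def to_dict(self) -> dict:
        return {
            "n_source1": self.n_source1,
            "n_source2": self.n_source2,
            "n_admixed": self.n_admixed,
            "chromosomes": [[c, l] for c, l in self.layout.chromosomes],
            "baseline_p": self.baseline_p,
            "introgressed_intervals": [list(iv) for iv in self.introgressed_intervals],
            "mean_tract_bp": self.mean_tract_bp,
            "segments_per_tract": self.segments_per_tract,
            "drop_rate": self.drop_rate,
            "spurious_rate": self.spurious_rate,
            "lod_mean": self.lod_mean,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "chromosomes" in d:
            d["layout"] = GenomeLayout(tuple((c, int(l)) for c, l in d.pop("chromosomes")))
        if "introgressed_intervals" in d:
            d["introgressed_intervals"] = tuple(
                tuple(iv) for iv in d["introgressed_intervals"]
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> SimulationConfig:
    """Load a flat-YAML simulation config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValidationError(f"config {path} is not a key-value mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "wt") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class AncestryTruth:
    """Ground-truth ancestry mosaic of every admixed haplotype.

    ``tracts[(sample, hap)]`` is the ordered tuple of
    ``(chrom, start, end, source)`` tracts tiling each chromosome exactly
    (0-based half-open; source is 1 or 2).
    """

    haplotypes: tuple[HapKey, ...]
    tracts: Mapping[HapKey, tuple[tuple[str, int, int, int], ...]]

    def source_intervals(self, hap: HapKey, chrom: str, source: int) -> np.ndarray:
        ivs = [
            (s, e) for c, s, e, src in self.tracts[hap] if c == chrom and src == source
        ]
        return merge_intervals(ivs)

    def window_p(self, grid: WindowGrid) -> dict[str, np.ndarray]:
        """Per-window true source-1 ancestry fraction p̂, averaged over haplotypes."""
        out: dict[str, np.ndarray] = {}
        for chrom in grid.layout.names:
            ws, we = grid.bounds(chrom)
            acc = np.zeros(len(ws), dtype=float)
            for hap in self.haplotypes:
                merged = self.source_intervals(hap, chrom, 1)
                acc += _covered_lengths(merged, ws, we) / (we - ws)
            out[chrom] = acc / len(self.haplotypes)
        return out


@dataclass(frozen=True)
class SimulatedDataset:
    segments: tuple[IbdSegment, ...]
    manifest: PopulationManifest
    layout: GenomeLayout
    truth: AncestryTruth
    config: SimulationConfig


def true_window_ribd(truth: AncestryTruth, grid: WindowGrid) -> dict[str, np.ndarray]:
    """Expected normalized rIBD per window under perfect detection: 2·p̂ − 1.

    With every tract detected, the sharing fractions are p̂ and 1 − p̂, so
    e.g. p̂ = 0.75 gives rIBD = 0.5.
    """
    return {chrom: 2.0 * p - 1.0 for chrom, p in truth.window_p(grid).items()}


def _sample_names(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    s1 = [f"S1_{i + 1:03d}" for i in range(config.n_source1)]
    s2 = [f"S2_{i + 1:03d}" for i in range(config.n_source2)]
    adm = [f"ADM_{i + 1:03d}" for i in range(config.n_admixed)]
    return s1, s2, adm


def _split_points(config: SimulationConfig, chrom: str) -> np.ndarray:
    """Sorted interior breakpoints of p(x) on one chromosome."""
    pts = set()
    length = config.layout.length_of(chrom)
    for c, s, e, _ in config.introgressed_intervals:
        if c == chrom:
            for x in (s, e):
                if 0 < x < length:
                    pts.add(x)
    return np.array(sorted(pts), dtype=np.int64)


def _local_p(config: SimulationConfig, chrom: str, start: int, end: int) -> float:
    """p(x) for a tract fully inside one piece of the piecewise-constant map."""
    mid = (start + end) / 2
    for c, s, e, p in config.introgressed_intervals:
        if c == chrom and s <= mid < e:
            return p
    return config.baseline_p


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate segments, manifest, layout, and ancestry truth from ``config``."""
    rng = np.random.default_rng(config.seed)
    s1_names, s2_names, adm_names = _sample_names(config)
    manifest = PopulationManifest(
        tuple((s, "source1") for s in s1_names)
        + tuple((s, "source2") for s in s2_names)
        + tuple((s, "admixed") for s in adm_names)
    )
    source_names = {1: s1_names, 2: s2_names}
    all_source_haps = [(s, h) for s in s1_names + s2_names for h in (1, 2)]

    hap_keys: list[HapKey] = [(s, h) for s in adm_names for h in (1, 2)]
    tracts: dict[HapKey, tuple[tuple[str, int, int, int], ...]] = {}
    segments: list[IbdSegment] = []

    for sample, hap in hap_keys:
        hap_tracts: list[tuple[str, int, int, int]] = []
        for chrom, length in config.layout.chromosomes:
            # 1) recombination mosaic: exponential tract lengths, truncated at L
            cuts: list[int] = []
            pos = 0.0
            while True:
                pos += rng.exponential(config.mean_tract_bp)
                if pos >= length:
                    break
                cut = int(round(pos))
                if 0 < cut < length and (not cuts or cut > cuts[-1]):
                    cuts.append(cut)
            bounds = np.concatenate(([0], cuts, [length])).astype(np.int64)
            # 2) split at introgressed-interval boundaries so each piece sees one p
            bounds = np.unique(np.concatenate((bounds, _split_points(config, chrom))))
            for s, e in zip(bounds[:-1], bounds[1:]):
                s, e = int(s), int(e)
                p = _local_p(config, chrom, s, e)
                source = 1 if rng.random() < p else 2
                hap_tracts.append((chrom, s, e, source))
                # 3) emitted IBD segments spanning the tract
                partners = source_names[source]
                for _ in range(config.segments_per_tract):
                    p_idx = int(rng.integers(len(partners)))
                    p_hap = int(rng.integers(1, 3))
                    dropped = rng.random() < config.drop_rate
                    lod = float(rng.exponential(config.lod_mean))
                    if not dropped:
                        segments.append(
                            IbdSegment(
                                sample, hap, partners[p_idx], p_hap, chrom, s, e, lod
                            )
                        )
        tracts[(sample, hap)] = tuple(hap_tracts)

    # 4) spurious segments: Poisson(spurious_rate per Mb) per haplotype
    if config.spurious_rate > 0:
        for sample, hap in hap_keys:
            for chrom, length in config.layout.chromosomes:
                n_sp = int(rng.poisson(config.spurious_rate * length / 1e6))
                for _ in range(n_sp):
                    start = int(rng.integers(length))
                    seg_len = max(1, int(round(rng.exponential(config.mean_tract_bp))))
                    end = min(length, start + seg_len)
                    p_sample, p_hap = all_source_haps[int(rng.integers(len(all_source_haps)))]
                    lod = float(rng.exponential(config.lod_mean))
                    segments.append(
                        IbdSegment(sample, hap, p_sample, p_hap, chrom, start, end, lod)
                    )

    truth = AncestryTruth(tuple(hap_keys), tracts)
    return SimulatedDataset(tuple(segments), manifest, config.layout, truth, config)


# ---------------------------------------------------------------------------
# File emission (the same dialects ribd.io reads)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write the dataset as the input files the readers consume, plus truth.

    Files written under ``outdir``:

    * ``chromosomes.tsv`` — name, length
    * ``manifest.tsv`` — sample, role
    * ``ibd_segments.tsv`` — 8-column Refined-IBD dialect, 1-based inclusive
    * ``truth_tracts.tsv`` — sample, hap, chrom, start, end (0-based
      half-open), source
    * ``true_ribd.tsv`` — per 10 kbp window (bed0): chrom, start, end,
      expected rIBD 2·p̂ − 1
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chromosomes": outdir / "chromosomes.tsv",
        "manifest": outdir / "manifest.tsv",
        "segments": outdir / "ibd_segments.tsv",
        "truth": outdir / "truth_tracts.tsv",
        "true_ribd": outdir / "true_ribd.tsv",
    }
    with open(paths["chromosomes"], "wt") as fh:
        for chrom, length in dataset.layout.chromosomes:
            fh.write(f"{chrom}\t{length}\n")
    with open(paths["manifest"], "wt") as fh:
        for sample, role in dataset.manifest.roles:
            fh.write(f"{sample}\t{role}\n")
    with open(paths["segments"], "wt") as fh:
        for seg in dataset.segments:
            fh.write(
                f"{seg.sample_a}\t{seg.hap_a}\t{seg.sample_b}\t{seg.hap_b}\t"
                f"{seg.chrom}\t{seg.start + 1}\t{seg.end}\t{seg.lod:.4f}\n"
            )
    with open(paths["truth"], "wt") as fh:
        fh.write("# ancestry truth tracts; dialect=bed0\n")
        fh.write("sample\thap\tchrom\tstart\tend\tsource\n")
        for sample, hap in dataset.truth.haplotypes:
            for chrom, s, e, src in dataset.truth.tracts[(sample, hap)]:
                fh.write(f"{sample}\t{hap}\t{chrom}\t{s}\t{e}\t{src}\n")
    from .core import build_window_grid  # local import to avoid cycle at module load

    grid = build_window_grid(dataset.layout)
    expected = true_window_ribd(dataset.truth, grid)
    with open(paths["true_ribd"], "wt") as fh:
        fh.write("# expected rIBD per window; dialect=bed0\n")
        fh.write("chrom\tstart\tend\ttrue_ribd\n")
        for chrom in dataset.layout.names:
            ws, we = grid.bounds(chrom)
            for s, e, r in zip(ws, we, expected[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{r!r}\n")
    return paths
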