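"""Readers and writers for the three rIBD inputs and the windowed score table.

Input files
-----------
* **IBD segments** — 8-column tab-separated text in the Refined-IBD output
  dialect: sample A, haplotype A index (1/2), sample B, haplotype B index,
  chromosome, start, end, LOD.  File coordinates are 1-based inclusive.
* **Population manifest** — 2 columns: sample ID, role
  (``source1`` / ``source2`` / ``admixed``, case-insensitive).
* **Chromosome table** — 2 columns: chromosome name, length in bp.

Internally every interval is 0-based half-open; the conversion happens only
at the I/O boundary.  Window tables are written with a mandatory header that
records the coordinate dialect (``bed0`` = 0-based half-open, BED-compatible;
``one_based`` = 1-based inclusive) so that files can never be re-read under
the wrong convention.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, fields
from typing import IO, Iterator, Sequence

__all__ = [
    "RibdError",
    "ParseError",
    "ValidationError",
    "GenomeLayout",
    "PopulationManifest",
    "IbdSegment",
    "WindowRecord",
    "SkipReport",
    "ROLES",
    "read_chromosome_table",
    "read_population_manifest",
    "read_ibd_segments",
    "write_window_table",
    "read_window_table",
    "write_region_table",
    "write_summary_table",
]

ROLES = ("source1", "source2", "admixed")

DIALECTS = ("bed0", "one_based")


class RibdError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(RibdError):
    """A line of an input file could not be parsed."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f", line {line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


class ValidationError(RibdError):
    """Input parsed but violates an invariant of its type."""


def _open_text(path) -> IO[str]:
    """Open plain or gzip-compressed text transparently (magic-byte sniff)."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _data_lines(handle: IO[str]) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and '#' comments."""
    for i, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield i, line


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; order is preserved in all output.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs in the order they should be
        reported and plotted.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple((str(c), int(l)) for c, l in self.chromosomes))
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate chromosome name(s): {', '.join(dupes)}")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def index_of(self, chrom: str) -> int:
        return self.names.index(chrom)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


def read_chromosome_table(path) -> GenomeLayout:
    """Read a 2-column ``name<TAB>length`` table into a :class:`GenomeLayout`."""
    rows: list[tuple[str, int]] = []
    with _open_text(path) as fh:
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"expected 2 tab-separated columns, got {len(parts)}", str(path), lineno
                )
            name, length_str = parts
            try:
                length = int(length_str)
            except ValueError:
                raise ParseError(f"non-integer chromosome length {length_str!r}", str(path), lineno)
            if length <= 0:
                raise ParseError(f"non-positive chromosome length {length}", str(path), lineno)
            rows.append((name, length))
    if not rows:
        raise ValidationError(f"chromosome table {path} is empty")
    return GenomeLayout(tuple(rows))


# ---------------------------------------------------------------------------
# Population manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationManifest:
    """Sample → role assignment defining the three-breed comparison.

    Roles are ``source1`` and ``source2`` (the two donor breeds) and
    ``admixed`` (the recipient breed).  Every role must have at least one
    sample.  Sample order within a role follows the input file and is the
    canonical unit ordering used throughout the pipeline.
    """

    roles: tuple[tuple[str, str], ...]  # (sample, role), input order

    def __post_init__(self):
        object.__setattr__(self, "roles", tuple((str(s), str(r)) for s, r in self.roles))
        seen: set[str] = set()
        for sample, role in self.roles:
            if sample in seen:
                raise ValidationError(f"duplicate sample ID {sample!r} in manifest")
            seen.add(sample)
            if role not in ROLES:
                raise ValidationError(
                    f"unknown role {role!r} for sample {sample!r}; expected one of {ROLES}"
                )
        for role in ROLES:
            if not any(r == role for _, r in self.roles):
                raise ValidationError(f"manifest has no sample with role {role!r}")

    def samples(self, role: str) -> tuple[str, ...]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return tuple(s for s, r in self.roles if r == role)

    def role_of(self, sample: str) -> str | None:
        for s, r in self.roles:
            if s == sample:
                return r
        return None

    @property
    def n_source1(self) -> int:
        return len(self.samples("source1"))

    @property
    def n_source2(self) -> int:
        return len(self.samples("source2"))

    @property
    def n_admixed(self) -> int:
        return len(self.samples("admixed"))

    def swap_sources(self) -> "PopulationManifest":
        """Return a manifest with the source1/source2 labels exchanged."""
        swap = {"source1": "source2", "source2": "source1", "admixed": "admixed"}
        return PopulationManifest(tuple((s, swap[r]) for s, r in self.roles))


def read_population_manifest(path) -> PopulationManifest:
    """Read a 2-column ``sample<TAB>role`` table; roles matched case-insensitively."""
    rows: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"expected 2 tab-separated columns, got {len(parts)}", str(path), lineno
                )
            sample, role = parts[0].strip(), parts[1].strip().lower()
            if role not in ROLES:
                raise ParseError(
                    f"unknown role {parts[1]!r} for sample {sample!r}; "
                    f"expected one of {ROLES}",
                    str(path),
                    lineno,
                )
            rows.append((sample, role))
    if not rows:
        raise ValidationError(f"population manifest {path} is empty")
    return PopulationManifest(tuple(rows))


# ---------------------------------------------------------------------------
# IBD segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IbdSegment:
    """One pairwise IBD tract between two haplotypes.

    ``start``/``end`` are in the internal 0-based half-open convention.
    """

    sample_a: str
    hap_a: int
    sample_b: str
    hap_b: int
    chrom: str
    start: int
    end: int
    lod: float

    def __post_init__(self):
        if self.hap_a not in (1, 2) or self.hap_b not in (1, 2):
            raise ValidationError(
                f"haplotype index must be 1 or 2 (got {self.hap_a}, {self.hap_b})"
            )
        if self.start >= self.end:
            raise ValidationError(f"empty/negative interval [{self.start}, {self.end})")
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if (self.sample_a, self.hap_a) == (self.sample_b, self.hap_b):
            raise ValidationError(
                f"segment pairs haplotype ({self.sample_a},{self.hap_a}) with itself"
            )
        if self.lod < 0:
            raise ValidationError(f"negative LOD {self.lod}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SkipReport:
    """Why data lines were skipped while reading an IBD segment file."""

    accepted: int = 0
    low_lod: int = 0
    short_segment: int = 0
    unknown_sample: int = 0
    source_source: int = 0
    admixed_admixed: int = 0

    @property
    def skipped(self) -> int:
        return (
            self.low_lod
            + self.short_segment
            + self.unknown_sample
            + self.source_source
            + self.admixed_admixed
        )

    @property
    def total(self) -> int:
        return self.accepted + self.skipped

    def __str__(self) -> str:
        parts = [f"accepted={self.accepted}"]
        for f in fields(self):
            if f.name != "accepted":
                parts.append(f"{f.name}={getattr(self, f.name)}")
        return "skip report: " + ", ".join(parts)


def read_ibd_segments(
    path,
    layout: GenomeLayout,
    manifest: PopulationManifest,
    min_lod: float = 3.0,
    min_length: int = 0,
) -> tuple[list[IbdSegment], SkipReport]:
    """Read Refined-IBD-style segments, keeping only source-vs-admixed pairs.

    File coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Segments are skipped — and counted in the
    returned :class:`SkipReport` — when their LOD is below ``min_lod``, they
    are shorter than ``min_length`` bp, either sample is absent from the
    manifest, or both samples belong to source breeds (irrelevant to the rIBD
    contrast) or both are admixed.

    Returns
    -------
    (segments, report)
        Accepted segments in file order, and the skip accounting such that
        ``report.total`` equals the number of data lines.
    """
    if min_lod < 0:
        raise ValueError("min_lod must be >= 0")
    segments: list[IbdSegment] = []
    report = SkipReport()
    spath = str(path)
    with _open_text(path) as fh:
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) != 8:
                raise ParseError(
                    f"expected 8 tab-separated columns, got {len(parts)}", spath, lineno
                )
            sa, ha_s, sb, hb_s, chrom, start_s, end_s, lod_s = parts
            try:
                ha, hb = int(ha_s), int(hb_s)
                start1, end1 = int(start_s), int(end_s)
                lod = float(lod_s)
            except ValueError as exc:
                raise ParseError(f"malformed field: {exc}", spath, lineno)
            if ha not in (1, 2) or hb not in (1, 2):
                raise ParseError(f"haplotype index must be 1 or 2", spath, lineno)
            if chrom not in layout:
                raise ParseError(f"chromosome {chrom!r} not in chromosome table", spath, lineno)
            if start1 < 1 or end1 < start1:
                raise ParseError(
                    f"invalid 1-based inclusive interval [{start1}, {end1}]", spath, lineno
                )
            if end1 > layout.length_of(chrom):
                raise ParseError(
                    f"segment end {end1} beyond length of chromosome {chrom} "
                    f"({layout.length_of(chrom)})",
                    spath,
                    lineno,
                )
            # 1-based inclusive -> 0-based half-open
            start, end = start1 - 1, end1

            if lod < min_lod:
                report.low_lod += 1
                continue
            if end - start < min_length:
                report.short_segment += 1
                continue
            role_a, role_b = manifest.role_of(sa), manifest.role_of(sb)
            if role_a is None or role_b is None:
                report.unknown_sample += 1
                continue
            if role_a != "admixed" and role_b != "admixed":
                report.source_source += 1
                continue
            if role_a == "admixed" and role_b == "admixed":
                report.admixed_admixed += 1
                continue
            try:
                seg = IbdSegment(sa, ha, sb, hb, chrom, start, end, lod)
            except ValidationError as exc:
                raise ParseError(str(exc), spath, lineno)
            segments.append(seg)
            report.accepted += 1
    return segments, report


# ---------------------------------------------------------------------------
# Window tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowRecord:
    """Per-window IBD sharing counts, fractions, and the rIBD score.

    ``n_ibd_sk`` is the number of admixed units (haplotypes by default)
    called IBD with source breed *k* in the window, out of ``n_total_sk``.
    In raw mode ``ibd_sk = n_ibd_sk / n_total_sk``; in normalized mode the
    two fractions are rescaled to sum to 1 (or both 0 for windows with no
    IBD evidence).  ``ribd = ibd_s1 - ibd_s2`` always holds.  ``truncated``
    marks a terminal window shorter than the nominal window size.
    """

    chrom: str
    start: int
    end: int
    n_ibd_s1: int
    n_total_s1: int
    n_ibd_s2: int
    n_total_s2: int
    ibd_s1: float
    ibd_s2: float
    ribd: float
    truncated: bool = False

    def __post_init__(self):
        if self.start >= self.end or self.start < 0:
            raise ValidationError(f"invalid window interval [{self.start}, {self.end})")
        for k in (1, 2):
            n_ibd = getattr(self, f"n_ibd_s{k}")
            n_tot = getattr(self, f"n_total_s{k}")
            if not (0 <= n_ibd <= n_tot):
                raise ValidationError(
                    f"window {self.chrom}:{self.start}-{self.end}: "
                    f"n_ibd_s{k}={n_ibd} outside [0, n_total_s{k}={n_tot}]"
                )
            frac = getattr(self, f"ibd_s{k}")
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(
                    f"window {self.chrom}:{self.start}-{self.end}: ibd_s{k}={frac} not in [0,1]"
                )
        if not (-1.0 <= self.ribd <= 1.0):
            raise ValidationError(
                f"window {self.chrom}:{self.start}-{self.end}: rIBD={self.ribd} not in [-1,1]"
            )
        if not math.isclose(self.ribd, self.ibd_s1 - self.ibd_s2, abs_tol=1e-9):
            raise ValidationError(
                f"window {self.chrom}:{self.start}-{self.end}: "
                f"rIBD={self.ribd} != ibd_s1 - ibd_s2 = {self.ibd_s1 - self.ibd_s2}"
            )

    @property
    def zero_evidence(self) -> bool:
        """True when no admixed unit is IBD with either source in this window."""
        return self.n_ibd_s1 == 0 and self.n_ibd_s2 == 0

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


_WINDOW_COLUMNS = (
    "chrom",
    "start",
    "end",
    "n_ibd_s1",
    "n_total_s1",
    "n_ibd_s2",
    "n_total_s2",
    "ibd_s1",
    "ibd_s2",
    "ribd",
    "truncated",
)


def _check_sorted(records: Sequence[WindowRecord]) -> None:
    seen_chroms: list[str] = []
    prev_chrom: str | None = None
    prev_start = -1
    for rec in records:
        if rec.chrom != prev_chrom:
            if rec.chrom in seen_chroms:
                raise ValidationError(
                    f"records not sorted: chromosome {rec.chrom!r} appears in "
                    "two separate blocks"
                )
            seen_chroms.append(rec.chrom)
            prev_chrom = rec.chrom
            prev_start = -1
        if rec.start <= prev_start:
            raise ValidationError(
                f"records not sorted: window start {rec.start} after {prev_start} "
                f"on chromosome {rec.chrom}"
            )
        prev_start = rec.start


def write_window_table(
    records: Sequence[WindowRecord], path, coordinate_dialect: str = "bed0"
) -> None:
    """Write a window score table as TSV with a dialect-tagged header.

    ``bed0`` writes internal 0-based half-open coordinates (the first three
    columns are BED-compatible); ``one_based`` writes 1-based inclusive
    coordinates as displayed to end users.  Floats are written with ``repr``
    so a round-trip through :func:`read_window_table` is lossless.  Records
    must already be sorted by (chromosome block, start).
    """
    if coordinate_dialect not in DIALECTS:
        raise ValueError(f"unknown coordinate dialect {coordinate_dialect!r}")
    _check_sorted(records)
    with open(path, "wt") as fh:
        fh.write(f"# rIBD window table; dialect={coordinate_dialect}\n")
        fh.write("\t".join(_WINDOW_COLUMNS) + "\n")
        for rec in records:
            if coordinate_dialect == "bed0":
                start, end = rec.start, rec.end
            else:
                start, end = rec.start + 1, rec.end
            fh.write(
                "\t".join(
                    (
                        rec.chrom,
                        str(start),
                        str(end),
                        str(rec.n_ibd_s1),
                        str(rec.n_total_s1),
                        str(rec.n_ibd_s2),
                        str(rec.n_total_s2),
                        repr(rec.ibd_s1),
                        repr(rec.ibd_s2),
                        repr(rec.ribd),
                        str(int(rec.truncated)),
                    )
                )
                + "\n"
            )


def read_window_table(path) -> list[WindowRecord]:
    """Read a table produced by :func:`write_window_table`, re-validating invariants."""
    spath = str(path)
    records: list[WindowRecord] = []
    with _open_text(path) as fh:
        first = fh.readline()
        if "dialect=" not in first:
            raise ParseError(
                "missing dialect header (expected '# rIBD window table; dialect=...')",
                spath,
                1,
            )
        dialect = first.rsplit("dialect=", 1)[1].strip()
        if dialect not in DIALECTS:
            raise ParseError(f"unknown coordinate dialect {dialect!r}", spath, 1)
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != _WINDOW_COLUMNS:
            raise ParseError(
                f"unexpected column header {header!r}", spath, 2
            )
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) != len(_WINDOW_COLUMNS):
                raise ParseError(
                    f"expected {len(_WINDOW_COLUMNS)} columns, got {len(parts)}",
                    spath,
                    lineno + 2,
                )
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                counts = tuple(int(x) for x in parts[3:7])
                ibd_s1, ibd_s2, ribd = (float(x) for x in parts[7:10])
                truncated = bool(int(parts[10]))
            except ValueError as exc:
                raise ParseError(f"malformed field: {exc}", spath, lineno + 2)
            if dialect == "one_based":
                start -= 1
            try:
                records.append(
                    WindowRecord(
                        chrom, start, end, *counts, ibd_s1, ibd_s2, ribd, truncated
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{exc} [{spath}, line {lineno + 2}]")
    return records


# ---------------------------------------------------------------------------
# Significance outputs
# ---------------------------------------------------------------------------

def _summary_comment_lines(summary) -> list[str]:
    return [
        f"# mean={summary.mean!r}",
        f"# sd={summary.sd!r}",
        f"# n_windows={summary.n_windows}",
        f"# k={summary.k!r}",
        f"# cut_high={summary.cut_high!r}",
        f"# cut_low={summary.cut_low!r}",
        f"# tail_mass={summary.tail_mass!r}",
    ]


def write_summary_table(summary, path) -> None:
    """Write an rIBD distribution summary as a 2-column key/value TSV."""
    with open(path, "wt") as fh:
        fh.write("# rIBD distribution summary\n")
        fh.write("statistic\tvalue\n")
        for key in ("mean", "sd", "n_windows", "k", "cut_high", "cut_low", "tail_mass"):
            val = getattr(summary, key)
            fh.write(f"{key}\t{val!r}\n" if isinstance(val, float) else f"{key}\t{val}\n")


def write_region_table(regions, path, summary=None) -> None:
    """Write significant regions as BED-compatible TSV (bed0 coordinates).

    When ``summary`` is given, the mean/SD/k/cut-offs it carries are recorded
    as ``#`` comment lines so the thresholds behind the list are auditable.
    """
    with open(path, "wt") as fh:
        fh.write("# rIBD significant regions; dialect=bed0\n")
        if summary is not None:
            for line in _summary_comment_lines(summary):
                fh.write(line + "\n")
        fh.write("chrom\tstart\tend\tsign\tn_windows\tpeak_ribd\tmean_ribd\n")
        for reg in regions:
            fh.write(
                f"{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.sign}\t"
                f"{reg.n_windows}\t{reg.peak_ribd!r}\t{reg.mean_ribd!r}\n"
            )
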