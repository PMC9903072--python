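import numpy as np
import pytest

from ribd.core import invert_ribd
from ribd.io import GenomeLayout, IbdSegment, PopulationManifest, WindowRecord


@pytest.fixture
def small_layout():
    return GenomeLayout((("chr1", 50_000), ("chr2", 25_000)))


@pytest.fixture
def small_manifest():
    return PopulationManifest(
        (
            ("S1a", "source1"),
            ("S1b", "source1"),
            ("S2a", "source2"),
            ("S2b", "source2"),
            ("A1", "admixed"),
            ("A2", "admixed"),
        )
    )


def random_instance(seed, n_per_role=3, chrom_lens=(2_000, 1_500), n_segments=60):
    """A seeded random toy problem: layout, manifest, and segments of every
    pair type (admixed-source, source-source, admixed-admixed)."""
    rng = np.random.default_rng(seed)
    layout = GenomeLayout(tuple((f"c{i+1}", l) for i, l in enumerate(chrom_lens)))
    roles = []
    for role, tag in (("source1", "S1"), ("source2", "S2"), ("admixed", "A")):
        roles += [(f"{tag}_{j}", role) for j in range(n_per_role)]
    manifest = PopulationManifest(tuple(roles))
    samples = [s for s, _ in manifest.roles]
    segments = []
    while len(segments) < n_segments:
        sa, sb = rng.choice(samples, size=2, replace=False)
        ha, hb = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        chrom, length = layout.chromosomes[int(rng.integers(len(layout.chromosomes)))]
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, length + 1))
        segments.append(
            IbdSegment(sa, ha, sb, hb, chrom, start, end, float(rng.exponential(8.0)))
        )
    return layout, manifest, segments


def records_from_scores(scores, window_size=10_000, chrom="chr1"):
    """Wrap a 1-D array of rIBD scores into valid sum-to-one WindowRecords."""
    records = []
    for i, r in enumerate(np.asarray(scores, dtype=float)):
        s1, s2 = invert_ribd(float(r))
        records.append(
            WindowRecord(
                chrom=chrom,
                start=i * window_size,
                end=(i + 1) * window_size,
                n_ibd_s1=1,
                n_total_s1=2,
                n_ibd_s2=1,
                n_total_s2=2,
                ibd_s1=s1,
                ibd_s2=s2,
                ribd=float(r),
            )
        )
    return records
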