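"""Shared fixtures: small genomes, random interval sets and a seeded RNG."""
import numpy as np
import pytest

from dmvscan.genomic_io import GenomeLayout, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 60_000})


def random_interval_set(rng, layout, n, max_len=5_000, with_names=False):
    rows = []
    chroms = layout.chroms
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, layout[chrom] - length))
        rows.append((chrom, start, start + length, f"iv{i}" if with_names else None))
    return IntervalSet.from_records(rows, layout=layout)


def coverage_mask(iset, layout):
    """Per-bp boolean oracle of the set's coverage."""
    masks = {c: np.zeros(layout[c], dtype=bool) for c in layout.chroms}
    for rec in iset:
        masks[rec.chrom][rec.start:rec.end] = True
    return masks
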