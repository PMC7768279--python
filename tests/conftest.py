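"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from prescout.intervals import GenomicInterval, IntervalSet

TOY_GENOME = {"chrA": 10_000, "chrB": 10_000}


def bitmap(intervals: IntervalSet, genome=TOY_GENOME) -> dict[str, np.ndarray]:
    """Per-base boolean membership mask — the reference semantics for all
    interval arithmetic."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in genome.items()}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def set_from_bitmap(masks, genome=TOY_GENOME) -> IntervalSet:
    out = []
    for chrom, m in masks.items():
        padded = np.concatenate([[False], m, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for lo, hi in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(chrom, int(lo), int(hi)))
    return IntervalSet(out, genome=dict(genome), merged=True)


def random_interval_set(rng, genome=TOY_GENOME, n=30, max_len=400, scored=False):
    ivs = []
    chroms = sorted(genome)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, genome[chrom] - max_len))
        length = int(rng.integers(1, max_len))
        score = float(rng.uniform(0, 10)) if scored else None
        ivs.append(GenomicInterval(chrom, start, start + length, None, score))
    return IntervalSet(ivs, genome=dict(genome))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
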