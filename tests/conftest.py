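"""Shared fixtures: toy segment profiles, random profile factory, and one
moderate synthetic cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hrdimmune as h
from hrdimmune.genome import MB
from hrdimmune.scars import SEGMENT_COLUMNS, SegmentProfile


def make_profile(rows, sample="T1", genome=None):
    """Build a SegmentProfile from (chrom, start, end, total, minor) rows."""
    genome = genome or h.toy_genome()
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return SegmentProfile(sample, df, genome)


def random_profile(rng: np.random.Generator, genome=None, max_segments_per_chrom=8):
    """A random valid segment profile on the toy genome: per chromosome, a
    random partition into alternating segments and gaps with random
    allele-specific states."""
    genome = genome or h.toy_genome()
    rows = []
    for ann in genome.chromosomes.values():
        k = int(rng.integers(0, max_segments_per_chrom + 1))
        if k == 0:
            continue
        cuts = np.sort(rng.choice(np.arange(1, ann.length, MB // 2), size=2 * k, replace=False))
        for i in range(k):
            start, end = int(cuts[2 * i]), int(cuts[2 * i + 1])
            if rng.random() < 0.5:  # half the segments abut the previous one
                start = int(cuts[2 * i - 1]) + 1 if i > 0 else 1
            total = int(rng.integers(0, 5))
            minor = int(rng.integers(0, total + 1)) if total else 0
            rows.append((ann.name, start, end, total, minor))
    if not rows:
        rows = [("chr1", 1, 10 * MB, 2, 1)]
    return make_profile(rows, sample="R", genome=genome)


@pytest.fixture(scope="session")
def toy_genome():
    return h.toy_genome()


@pytest.fixture(scope="session")
def small_cohort():
    """One 80-sample cohort with all planted effects, shared read-only."""
    config = h.CohortConfig(n_samples=80, n_genes=300, seed=42)
    bundle, truth = h.generate_cohort(config)
    return config, bundle, truth
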