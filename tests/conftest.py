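"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from syntenykit import BuildParams
from syntenykit.simulate import (
    anchors_from_truth,
    simulate_karyotype,
    simulate_rearrangements,
)

# study-scale simulation conditions: a 5-chromosome ~10 Mb reference genome
# evolved through 20 mixed rearrangements, tiled by ~20 kb anchors with
# ~2 kb gaps, built at 50 kb resolution
GENOME_KW = dict(n_chroms=5, length_range=(1_600_000, 2_400_000))
N_OPS = 20
ANCHOR_KW = dict(anchor_len_mean=20_000, gap_mean=2_000)
RESOLUTION = 50_000


@pytest.fixture(scope="session")
def karyotype():
    return simulate_karyotype(seed=1, **GENOME_KW)


@pytest.fixture(scope="session")
def truth(karyotype):
    return simulate_rearrangements(karyotype, n_ops=N_OPS, seed=1)


@pytest.fixture(scope="session")
def clean_anchors(truth):
    return anchors_from_truth(truth.truth_map, truth.tgt_karyotype, seed=1, **ANCHOR_KW)


@pytest.fixture(scope="session")
def params():
    return BuildParams(resolution=RESOLUTION, max_gap=10_000)
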