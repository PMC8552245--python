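"""Shared fixtures: a small simulated scenario and random-interval helpers."""

from __future__ import annotations

import numpy as np
import pytest

from dreamtargets.genome import GenomicInterval, PeakSet
from dreamtargets.simulate import ScenarioConfig, simulate_scenario, write_scenario


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     max_pos: int = 10_000, max_len: int = 400) -> PeakSet:
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return PeakSet(out)


def coverage_mask(peaks: PeakSet, chroms, max_pos: int) -> dict[str, np.ndarray]:
    """Brute-force boolean covered-base masks (the oracle for merge)."""
    masks = {c: np.zeros(max_pos, dtype=bool) for c in chroms}
    for iv in peaks:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    return ScenarioConfig(
        seed=11,
        n_genes=120,
        chrom_length=400_000,
        n_lin36_shared=25,
        n_lin15b_shared=12,
        n_lin35_only=15,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return simulate_scenario(small_config)


@pytest.fixture(scope="session")
def small_scenario_dir(small_scenario, tmp_path_factory):
    path = tmp_path_factory.mktemp("scenario") / "in"
    write_scenario(small_scenario, path)
    return path
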