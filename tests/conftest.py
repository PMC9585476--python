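"""Shared fixtures: small simulated trio panels and helper builders."""

import numpy as np
import pytest

from baiyue_scan import sim
from baiyue_scan.io import SiteCounts
from baiyue_scan.scan import TrioSpec


@pytest.fixture(scope="session")
def trio():
    return TrioSpec(target="A", ingroup="B", outgroup="C")


@pytest.fixture(scope="session")
def small_config():
    """A small three-population recipe used by several suites."""
    return sim.SimConfig(
        n_sites=300,
        chrom_plan=[("chr1", 2_000_000), ("chr2", 1_000_000)],
        drift={"A": 0.05, "B": 0.05, "C": 0.1},
        sample_sizes={"A": 12, "B": 10, "C": 15},
        missing_rate=0.05,
        depth_mean=30.0,
        depth_overdispersion=3.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    freqs = sim.simulate_trio_frequencies(small_config)
    return sim.sample_genotypes(freqs, small_config)


def make_site(
    chrom="chr1",
    pos=100,
    counts=None,
    depth=30.0,
    missing=0.0,
    polarizable=True,
):
    """Hand-built SiteCounts for filter/PBS fixtures."""
    return SiteCounts(
        chrom=chrom,
        pos=pos,
        site_id=f"{chrom}:{pos}",
        ref="A",
        alt="G",
        ancestral="A" if polarizable else None,
        counts=counts or {"A": (5, 20), "B": (5, 20), "C": (5, 20)},
        site_mean_depth=depth,
        missing_fraction=missing,
        polarizable=polarizable,
    )
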