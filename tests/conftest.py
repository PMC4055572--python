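"""Shared fixtures: deterministic synthetic study setups.

All simulated datasets here mirror the study conditions used throughout the
package: common-SNP ancestral frequencies, Balding–Nichols source divergence
around FST ≈ 0.15 (CEU/YRI-like), multi-chromosome maps in Morgans, admixed
cohorts of 20 diploids.
"""

from __future__ import annotations

import numpy as np
import pytest

from hoa_admixkit import (
    DriftTree,
    HaplotypePanel,
    generate_fixtures,
    make_genetic_map,
    simulate_drift_frequencies,
    simulate_panels,
)


@pytest.fixture(scope="session")
def small_map():
    """4 chromosomes x 1 Morgan, 8,000 loci."""
    return make_genetic_map(4, 1.0, 8_000, seed=11)


@pytest.fixture(scope="session")
def two_source_setup(small_map):
    """Two diverged sources (pairwise FST ~ 0.15) split into template and
    reference pools, plus exact frequencies."""
    tree = DriftTree.star(["A", "B"], 0.15)
    freqs = simulate_drift_frequencies(tree, small_map.n_loci, seed=21)
    panels = simulate_panels(freqs, 240, small_map, seed=22)
    return {
        "map": small_map,
        "tree": tree,
        "freqs": freqs,
        "panels": panels,
        "templates": {
            "A": HaplotypePanel("A", panels["A"].haplotypes[:40]),
            "B": HaplotypePanel("B", panels["B"].haplotypes[:40]),
        },
        "ref_freq": {
            "A": panels["A"].haplotypes[40:].mean(axis=0),
            "B": panels["B"].haplotypes[40:].mean(axis=0),
        },
    }


@pytest.fixture(scope="session")
def quartet_setup(small_map):
    """Four populations on a symmetric tree ((W,X),(Y,Z)) with no gene flow."""
    tree = DriftTree.from_dict(
        {
            "name": "root",
            "children": [
                {"name": "wx", "f": 0.05, "children": [
                    {"name": "W", "f": 0.05}, {"name": "X", "f": 0.05}]},
                {"name": "yz", "f": 0.05, "children": [
                    {"name": "Y", "f": 0.05}, {"name": "Z", "f": 0.05}]},
            ],
        }
    )
    freqs = simulate_drift_frequencies(tree, small_map.n_loci, seed=31)
    panels = simulate_panels(freqs, 60, small_map, seed=32)
    return {"map": small_map, "tree": tree, "freqs": freqs, "panels": panels}


@pytest.fixture(scope="session")
def bundled_fixture():
    """The pipeline's bundled small dataset (3 populations, admixed cohort)."""
    return generate_fixtures(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
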