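"""Shared fixtures: synthetic populations at several scales.

Everything is generated programmatically with fixed seeds; the heavier
populations are session-scoped so REML-level tests can share kernels.
"""

import numpy as np
import pytest

from hetscan import (MPHSimulator, background_kernels, build_codings,
                     build_mph_transform, generate_population)


class PopBundle:
    """A generated population with its codings, transform and kernels."""

    def __init__(self, n_parents, n_hybrids, n_markers, n_chromosomes, seed,
                 **kw):
        self.pop, self.panel, self.pedigree = generate_population(
            n_parents, n_hybrids, n_markers, n_chromosomes, seed=seed, **kw)
        self.codings = build_codings(self.pop, self.panel)
        self.transform = build_mph_transform(self.pedigree,
                                             self.pop.combined_ids)
        self.kernels = background_kernels(self.codings, self.transform)
        self.simulator = MPHSimulator(self.codings, self.transform,
                                      self.kernels, self.panel)

    @property
    def n(self):
        return self.pop.n_hybrids


@pytest.fixture(scope="session")
def toy():
    """Tiny population for exact / oracle checks: 12 hybrids, 12 markers."""
    return PopBundle(8, 12, 12, 3, seed=3, n_females=5)


@pytest.fixture(scope="session")
def pop200():
    """Mid-size population for mixed-model tests: n=200, p=100, 21 chromosomes."""
    return PopBundle(90, 200, 100, 21, seed=7)


@pytest.fixture(scope="session")
def pop300():
    """Simulation-study scale population: n=300, p=300, 21 chromosomes."""
    return PopBundle(90, 300, 300, 21, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
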