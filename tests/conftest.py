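import numpy as np
import pytest

from replisim import (
    EffectiveIPLS,
    GenomeLattice,
    Profile,
    SimParams,
    simulate_ensemble,
)


@pytest.fixture
def small_lattice():
    """Two chromosomes, 400 + 300 bins of 5 kb (3.5 Mb total)."""
    return GenomeLattice(["chrA", "chrB"], [400, 300], 5.0)


@pytest.fixture
def uniform_ipls(small_lattice):
    n = small_lattice.n_bins
    return Profile(np.full(n, 1.0 / n), "ipls", small_lattice)


def point_mass_ipls(lattice, bins):
    vals = np.zeros(lattice.n_bins)
    for b in np.atleast_1d(bins):
        vals[b] = 1.0
    vals /= vals.sum()
    return Profile(vals, "ipls", lattice)


@pytest.fixture(scope="session")
def toy_ensemble():
    """A 10 Mb uniform-landscape ensemble used by several observable tests.

    rho_F is raised so the toy genome replicates with a handful of factors
    in a few hundred minutes.
    """
    lat = GenomeLattice(["c1"], [2000], 5.0)
    ipls = Profile(np.full(2000, 1.0 / 2000), "ipls", lat)
    params = SimParams(rho_F=2.0, d_PO=20.0, n_sims=60, seed=1234)
    return simulate_ensemble(lat, EffectiveIPLS(ipls, 0.0), params)
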