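from types import SimpleNamespace

import numpy as np
import pytest

from landla.landscape import LandscapeMap, generate_map
from landla.simulator import SimParams, run_simulation


class MiniSnapshot:
    """Hand-specified metapopulation for closed-form oracle tests.

    Behaves like a simulator snapshot (phenotypes = baseline + dosage @
    effects) but allows an arbitrary list of demes with explicit optima and
    genotypes, so expected statistics can be evaluated by hand.
    """

    def __init__(self, optima, deme, geno, eff, v_s=1.0, generation=0, origin=None):
        self.optima = np.asarray(optima, dtype=float).reshape(len(optima), -1)
        self.deme = np.asarray(deme, dtype=np.int64)
        self.geno = np.asarray(geno, dtype=np.uint8)
        self.eff = np.asarray(eff, dtype=float).reshape(-1, self.optima.shape[1])
        self.pos = np.arange(1.0, self.eff.shape[0] + 1)
        self.origin = (
            np.zeros(self.eff.shape[0], dtype=np.int64) if origin is None else origin
        )
        self.generation = generation
        self.baseline = np.zeros(self.optima.shape[1])
        n_demes = self.optima.shape[0]
        self.params = SimpleNamespace(
            n_demes=n_demes,
            grid_size=int(np.sqrt(n_demes)),
            v_s=v_s,
            n_total=self.deme.size,
            n_traits=self.optima.shape[1],
            deme_size=self.deme.size // n_demes,
        )

    @property
    def n_mut(self):
        return self.eff.shape[0]

    def phenotypes(self):
        dosage = (self.geno[0::2].astype(float) + self.geno[1::2])
        return self.baseline + dosage @ self.eff

    def deme_frequencies(self):
        hap_deme = np.repeat(self.deme, 2)
        freq = np.zeros((self.params.n_demes, self.n_mut))
        np.add.at(freq, hap_deme, self.geno)
        counts = 2 * np.bincount(self.deme, minlength=self.params.n_demes).astype(float)
        return freq / counts[:, None]


def two_deme_snapshot(n_per_deme=4, v_s=1.0):
    """Two demes with optima (0, 1); residents carry one shared mutation.

    Deme-0 individuals have phenotype 0 (no copies) and deme-1 individuals
    phenotype 1 (homozygous for a gamma = 0.5 mutation), so each deme sits
    exactly on its optimum.
    """
    n = n_per_deme
    deme = np.repeat([0, 1], n)
    geno = np.zeros((4 * n, 1), dtype=np.uint8)
    geno[2 * n :, 0] = 1  # both haplotypes of every deme-1 individual
    return MiniSnapshot([0.0, 1.0], deme, geno, [[0.5]], v_s=v_s)


@pytest.fixture(scope="session")
def desk_params():
    """Scaled simulation constants: short genome with genome-wide totals
    (mutational variance, map length) preserved by scaling mu and r up."""
    return SimParams(
        grid_size=7,
        deme_size=50,
        m=0.07,
        v_s=2.5,
        genome_length=1e5,
        recomb_rate=1e-5,
        mut_rate=1e-8,
        burn_in=100,
        main_gens=1200,
        seed=20,
    )


@pytest.fixture(scope="session")
def high_i_map():
    return generate_map(0.8, size=7, seed=101)


@pytest.fixture(scope="session")
def evolved_snapshot(desk_params, high_i_map):
    """One equilibrated desk-scale simulation, shared across stats tests."""
    return run_simulation(desk_params, high_i_map, la_log_interval=300)


@pytest.fixture()
def uniform_map():
    vals = np.full((4, 4), 0.5)
    return LandscapeMap(vals, 0.0, 0.0, seed=0)
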