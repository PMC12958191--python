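import numpy as np
import pandas as pd
import pytest

import apyrel as a
from apyrel.simulate import UNKNOWN


@pytest.fixture
def trio_pedigree():
    """Unrelated sire and dam with one offspring."""
    return a.Pedigree(
        ids=np.array([1, 2, 3]),
        sire=np.array([UNKNOWN, UNKNOWN, 0]),
        dam=np.array([UNKNOWN, UNKNOWN, 1]),
        generation=np.array([0, 0, 1]),
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Two founders, two full sibs, and an offspring of the full-sib mating."""
    return a.Pedigree(
        ids=np.arange(1, 6),
        sire=np.array([UNKNOWN, UNKNOWN, 0, 0, 2]),
        dam=np.array([UNKNOWN, UNKNOWN, 1, 1, 3]),
        generation=np.array([0, 0, 1, 1, 2]),
    )


def random_pd_matrix(n, rng, jitter=0.5):
    """Random symmetric positive-definite matrix resembling a GRM."""
    B = rng.normal(size=(n, max(n // 2, 2)))
    G = B @ B.T / B.shape[1]
    return G + jitter * np.eye(n)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_population(seed=7, h2=0.30, mode="continuous", **kw):
    """A compact simulated population with all matrices built."""
    defaults = dict(
        n_founders=24,
        n_generations=3,
        offspring_per_dam=2,
        m_snps=120,
        genotyped_fraction=0.5,
        heritability=h2,
        trait_mode=mode,
        seed=seed,
    )
    defaults.update(kw)
    cfg = a.SimConfig(**defaults)
    ped = a.simulate_pedigree(cfg)
    geno = a.simulate_genotypes(ped, cfg)
    phen = a.simulate_phenotypes(ped, geno, cfg)
    gids = a.select_genotyped(ped, cfg)
    numrel = a.build_A_inverse(ped)
    A22 = a.build_A22(ped, gids)
    numrel.A22, numrel.A22_ids = A22, gids
    grm = a.build_grm(geno.subset(gids), A22)
    params = a.ModelParams.from_heritability(h2)
    return dict(
        cfg=cfg, ped=ped, geno=geno, phen=phen, gids=gids,
        numrel=numrel, A22=A22, grm=grm, params=params,
    )


@pytest.fixture(scope="session")
def small_pop():
    return small_population()
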