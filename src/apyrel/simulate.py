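"""Synthetic dairy-style populations: pedigree, gene-dropped SNP genotypes, phenotypes.

The generator emulates the structure of a national dairy evaluation at desk
scale: a multi-generation pedigree produced by random mating, SNP genotypes
obtained by Mendelian gene dropping from founder haplotypes, an additive
animal-model trait at configurable heritability (either a continuous record
or a 1/2-coded binary outcome such as calf respiratory disease), and a
genotyped subset of the pedigree.  Everything is reproducible bit-for-bit
from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Pedigree",
    "PhenotypeSet",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "select_genotyped",
]

UNKNOWN = -1  # sentinel parent index

# sub-stream labels so each operation draws from an independent, named stream
_STREAM_PEDIGREE = 1
_STREAM_GENOTYPES = 2
_STREAM_PHENOTYPES = 3
_STREAM_SELECT = 4


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic population.

    Defaults follow the low-heritability binary disease trait that motivates
    the reliability study: ``heritability=0.042`` with a 1/2-coded outcome.
    ``fixed_effect_levels=1`` means a mean-only fixed effect; a value > 1
    adds one categorical fixed effect (e.g. a herd analogue) with that many
    levels.  ``phenotyped_fraction`` controls how many animals carry a
    record, so that some animals are informed only through relatives.
    """

    n_founders: int = 150
    n_generations: int = 4
    offspring_per_dam: int = 3
    genotyped_fraction: float = 0.4
    m_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    heritability: float = 0.042
    trait_mode: str = "binary_1_2"
    binary_incidence: float = 0.15
    phenotyped_fraction: float = 0.9
    fixed_effect_levels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if self.offspring_per_dam < 1:
            raise ConfigurationError("offspring_per_dam must be >= 1")
        if not (0.0 < self.genotyped_fraction <= 1.0):
            raise ConfigurationError("genotyped_fraction must be in (0, 1]")
        if self.m_snps < 1:
            raise ConfigurationError("m_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lower <= upper <= 0.5")
        if not (0.0 < self.heritability < 1.0):
            raise ConfigurationError("heritability must be in (0, 1)")
        if self.trait_mode not in ("continuous", "binary_1_2"):
            raise ConfigurationError("trait_mode must be 'continuous' or 'binary_1_2'")
        if not (0.0 < self.binary_incidence < 1.0):
            raise ConfigurationError("binary_incidence must be in (0, 1)")
        if not (0.0 < self.phenotyped_fraction <= 1.0):
            raise ConfigurationError("phenotyped_fraction must be in (0, 1]")
        if self.fixed_effect_levels < 1:
            raise ConfigurationError("fixed_effect_levels must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Pedigree:
    """An acyclic pedigree in birth order (every parent precedes its offspring).

    ``sire`` and ``dam`` hold positional indices into ``ids`` (``UNKNOWN`` = -1
    for an unknown parent).  ``ids`` are the external animal identifiers.
    """

    ids: np.ndarray  # external ids, dtype object or int
    sire: np.ndarray  # int index into ids, UNKNOWN if unknown
    dam: np.ndarray
    generation: np.ndarray  # 0 for founders
    sex: Optional[np.ndarray] = None  # "M"/"F" where known

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        self._index = {a: i for i, a in enumerate(self.ids.tolist())}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate animal ids in pedigree")
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        for name, parent in (("sire", self.sire), ("dam", self.dam)):
            known = parent != UNKNOWN
            if np.any(parent[known] < 0) or np.any(parent[known] >= n):
                raise ValueError(f"{name} index out of range")
            bad = np.nonzero(known & (parent >= np.arange(n)))[0]
            if bad.size:
                a = self.ids[bad[0]]
                raise ValueError(
                    f"pedigree not in birth order or cyclic: animal {a!r} "
                    f"does not follow its {name}"
                )

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal {exc.args[0]!r} not in pedigree") from None

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def progeny_counts(self) -> pd.Series:
        """Number of offspring per animal (as sire or dam)."""
        counts = np.zeros(self.n_animals, dtype=np.int64)
        for parent in (self.sire, self.dam):
            known = parent[parent != UNKNOWN]
            np.add.at(counts, known, 1)
        return pd.Series(counts, index=self.ids)

    def to_frame(self) -> pd.DataFrame:
        def ext(parent):
            return [self.ids[p] if p != UNKNOWN else 0 for p in parent]

        return pd.DataFrame(
            {"animal": self.ids, "sire": ext(self.sire), "dam": ext(self.dam)}
        )


@dataclass
class PhenotypeSet:
    """Single-record phenotypes plus the simulation-truth breeding values.

    ``records`` maps animal id -> observed value (real, or the 1/2 disease
    code); ``true_breeding_value`` covers every animal.  ``fixed_level``
    holds the categorical fixed-effect level of each recorded animal (all
    zeros when the model is mean-only).
    """

    records: pd.Series
    true_breeding_value: pd.Series
    fixed_level: pd.Series
    trait_mode: str
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.trait_mode == "binary_1_2":
            vals = set(np.unique(self.records.to_numpy()))
            if not vals <= {1.0, 2.0}:
                raise ValueError("binary_1_2 records must be coded 1/2")
        if self.records.index.has_duplicates:
            raise ValueError("an animal may carry at most one record")


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Random-mating discrete-generation pedigree.

    Founders (generation 0) have unknown parents and alternate M/F starting
    with a male.  In each later generation every female of the previous
    generation becomes a dam of ``offspring_per_dam`` offspring, each sired
    by a male drawn uniformly from the previous generation's males.
    """
    rng = config.rng(_STREAM_PEDIGREE)
    sexes = ["M" if i % 2 == 0 else "F" for i in range(config.n_founders)]
    sire = [UNKNOWN] * config.n_founders
    dam = [UNKNOWN] * config.n_founders
    gen = [0] * config.n_founders

    prev = list(range(config.n_founders))
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sexes[i] == "M"]
        females = [i for i in prev if sexes[i] == "F"]
        if not males or not females:
            raise ConfigurationError(
                f"generation {g - 1} has no {'males' if not males else 'females'}; "
                "cannot mate"
            )
        current: list[int] = []
        for d in females:
            chosen_sires = rng.choice(males, size=config.offspring_per_dam)
            for s in chosen_sires:
                idx = len(sire)
                sire.append(int(s))
                dam.append(int(d))
                gen.append(g)
                sexes.append("M" if rng.random() < 0.5 else "F")
                current.append(idx)
        prev = current

    n = len(sire)
    return Pedigree(
        ids=np.arange(1, n + 1),
        sire=np.array(sire),
        dam=np.array(dam),
        generation=np.array(gen),
        sex=np.array(sexes, dtype=object),
    )


def simulate_genotypes(pedigree: Pedigree, config: SimConfig):
    """Gene-drop SNP genotypes for every animal in the pedigree.

    Per-locus founder allele frequencies are drawn uniformly from
    ``maf_range``.  Founders receive Binomial(2, p) gene content; offspring
    inherit one allele per parent, a heterozygous parent transmitting either
    allele with probability 1/2; a gamete from an unknown parent is drawn at
    the locus founder frequency.  Returns a :class:`~apyrel.relationships.GenotypeSet`
    over all pedigree animals (restrict with ``subset`` for the genotyped pool).
    """
    from .relationships import GenotypeSet

    if pedigree.n_animals == 0:
        raise ValueError("empty pedigree")
    rng = config.rng(_STREAM_GENOTYPES)
    m = config.m_snps
    founder_p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    n = pedigree.n_animals
    Z = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            Z[i] = rng.binomial(2, founder_p)
            continue
        gametes = np.zeros(m, dtype=np.int8)
        for parent in (s, d):
            if parent == UNKNOWN:
                gametes += rng.random(m) < founder_p
            else:
                # transmit 1 with prob (gene content)/2: exact Mendelian rule
                gametes += rng.random(m) < (Z[parent] / 2.0)
        Z[i] = gametes
    return GenotypeSet(ids=pedigree.ids.copy(), Z=Z)


def simulate_phenotypes(pedigree: Pedigree, genotypes, config: SimConfig) -> PhenotypeSet:
    """Additive animal-model phenotypes at the configured heritability.

    True breeding values are ``u = W a`` with ``W`` the column-centered gene
    content of all animals and iid marker effects, rescaled so the realized
    variance of ``u`` equals sigma_a^2 = h^2 (total phenotypic variance 1).
    Residuals are iid N(0, 1 - h^2).  In ``binary_1_2`` mode the liability
    is thresholded at the empirical quantile giving ``binary_incidence`` of
    code 2.
    """
    h2 = config.heritability
    rng = config.rng(_STREAM_PHENOTYPES)
    ids = pedigree.ids

    order = genotypes.index_of(ids)
    Z = np.asarray(genotypes.Z, dtype=np.float64)[order]
    W = Z - Z.mean(axis=0)
    a = rng.normal(size=W.shape[1])
    u = W @ a
    sd = u.std()
    if sd == 0:
        raise ValueError("degenerate genotypes: no additive variance")
    sigma_a = np.sqrt(h2)
    u = u * (sigma_a / sd)

    sigma_e = np.sqrt(1.0 - h2)
    e = rng.normal(scale=sigma_e, size=len(ids))

    levels = np.zeros(len(ids), dtype=np.int64)
    level_effects = np.zeros(1)
    if config.fixed_effect_levels > 1:
        levels = rng.integers(0, config.fixed_effect_levels, size=len(ids))
        level_effects = rng.normal(scale=0.5 * sigma_e, size=config.fixed_effect_levels)
    liability = u + e + level_effects[levels]

    n_rec = max(1, int(np.floor(config.phenotyped_fraction * len(ids))))
    rec_idx = np.sort(rng.choice(len(ids), size=n_rec, replace=False))

    if config.trait_mode == "binary_1_2":
        thresh = np.quantile(liability[rec_idx], 1.0 - config.binary_incidence)
        y = np.where(liability[rec_idx] > thresh, 2.0, 1.0)
    else:
        y = liability[rec_idx]

    return PhenotypeSet(
        records=pd.Series(y, index=ids[rec_idx]),
        true_breeding_value=pd.Series(u, index=ids),
        fixed_level=pd.Series(levels[rec_idx], index=ids[rec_idx]),
        trait_mode=config.trait_mode,
    )


def select_genotyped(pedigree: Pedigree, config: SimConfig) -> np.ndarray:
    """Random genotyped subset: floor(fraction * n) animals, at least 1.

    Sampling is uniform without replacement; the returned ids are in pedigree
    birth order so the output ordering is fixed under a given seed.
    """
    n = pedigree.n_animals
    k = int(np.floor(config.genotyped_fraction * n))
    k = max(k, 1)
    if k == 0:
        raise ConfigurationError("genotyped_fraction selects zero animals")
    rng = config.rng(_STREAM_SELECT)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return pedigree.ids[idx]
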