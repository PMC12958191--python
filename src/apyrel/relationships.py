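"""Pedigree and genomic relationship matrices and the APY sparse inverse.

Builds the numerator relationship machinery (tabular A, inbreeding, Henderson's
sparse A-inverse, the genotyped submatrix A22), the VanRaden genomic
relationship matrix blended with A22, SVD-based core sizing, nested random
core selection, and the algorithm-for-proven-and-young (APY) block inverse of
the GRM.

APY conditions noncore animals on a core subset: writing G in core/noncore
blocks, the noncore conditional variances  m_ii = g_ii - g_ic Gcc^-1 g_ci
form a diagonal M_nn, and the implied inverse

    G_APY^-1 = [ Gcc^-1 + Gcc^-1 Gcn Mnn^-1 Gnc Gcc^-1   -Gcc^-1 Gcn Mnn^-1 ]
               [          -Mnn^-1 Gnc Gcc^-1                    Mnn^-1       ]

is sparse: its noncore-noncore block is exactly diagonal, so storage and cost
grow quadratically in the number of core animals and only linearly in the
number of noncore animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .simulate import UNKNOWN, Pedigree

__all__ = [
    "GenotypeSet",
    "NumeratorRelationship",
    "GRM",
    "CorePartition",
    "APYInverse",
    "tabular_A",
    "build_A_inverse",
    "build_A22",
    "build_grm",
    "choose_core_size",
    "round_up_core",
    "select_nested_cores",
    "build_apy_inverse",
]

logger = logging.getLogger(__name__)


@dataclass
class GenotypeSet:
    """Gene-content matrix Z (n animals x m SNPs, entries in [0, 2]).

    Entries are 0/1/2 allele counts; imputed missing genotypes may be
    real-valued.  ``allele_freq`` is the observed per-locus frequency
    p_j = column mean / 2.
    """

    ids: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.Z = np.asarray(self.Z)
        if self.Z.ndim != 2 or self.Z.shape[0] != len(self.ids):
            raise ValueError("Z must be n_animals x m_snps")
        if self.Z.shape[0] < 1 or self.Z.shape[1] < 1:
            raise ValueError("need at least one animal and one locus")
        self._index = {a: i for i, a in enumerate(self.ids.tolist())}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate ids in genotype set")

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        return np.asarray(self.Z, dtype=np.float64).mean(axis=0) / 2.0

    def index_of(self, animal_ids) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal {exc.args[0]!r} has no genotype") from None

    def subset(self, animal_ids) -> "GenotypeSet":
        idx = self.index_of(animal_ids)
        return GenotypeSet(ids=np.asarray(animal_ids), Z=self.Z[idx])

    def centered(self) -> np.ndarray:
        """W = Z - 2P with columns centered at twice the observed frequency."""
        Z = np.asarray(self.Z, dtype=np.float64)
        return Z - 2.0 * self.allele_freq


@dataclass
class NumeratorRelationship:
    """Pedigree relationship products: sparse A^-1, inbreeding F, optional A22."""

    ids: np.ndarray
    A_inverse: sp.csr_matrix
    inbreeding: pd.Series
    A22: Optional[np.ndarray] = None
    A22_ids: Optional[np.ndarray] = None


@dataclass
class GRM:
    """Blended genomic relationship matrix G = alpha*G0 + (1-alpha)*A22."""

    ids: np.ndarray
    G: np.ndarray
    blend_weights: tuple[float, float]

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.G), index=self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.ids.tolist())}
        return np.array([index[a] for a in animal_ids], dtype=np.int64)


@dataclass
class CorePartition:
    """Split of the genotyped animals into core and noncore sets."""

    core_ids: np.ndarray
    noncore_ids: np.ndarray
    scenario_label: str = ""

    def __post_init__(self) -> None:
        self.core_ids = np.asarray(self.core_ids)
        self.noncore_ids = np.asarray(self.noncore_ids)
        if len(self.core_ids) < 1:
            raise ValueError("core must contain at least one animal")
        if set(self.core_ids.tolist()) & set(self.noncore_ids.tolist()):
            raise ValueError("core and noncore sets overlap")

    @property
    def n_core(self) -> int:
        return len(self.core_ids)

    @property
    def n_noncore(self) -> int:
        return len(self.noncore_ids)

    @property
    def all_ids(self) -> np.ndarray:
        return np.concatenate([self.core_ids, self.noncore_ids])


class APYError(RuntimeError):
    pass


@dataclass
class APYInverse:
    """Block representation of the APY inverse of a GRM.

    ``Gcc``/``Gcn`` are the core-core and core-noncore blocks of G in
    partition order; ``Mnn`` is the positive diagonal of noncore conditional
    variances.  The assembled inverse is exposed either as dense blocks
    (:meth:`inverse_blocks`) or as a sparse matrix in an arbitrary id order
    (:meth:`to_sparse`).
    """

    partition: CorePartition
    Gcc: np.ndarray
    Gcn: np.ndarray
    Mnn: np.ndarray
    _cho: tuple = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.Mnn <= 0):
            raise APYError("all Mnn entries must be positive")
        if self._cho is None:
            self._cho = sla.cho_factor(self.Gcc, lower=True)

    def gcc_solve(self, B: np.ndarray) -> np.ndarray:
        return sla.cho_solve(self._cho, B)

    def inverse_blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense blocks (core-core, core-noncore, noncore diagonal) of G_APY^-1."""
        nc = self.partition.n_core
        X = self.gcc_solve(self.Gcn)  # Gcc^-1 Gcn
        icn = -X / self.Mnn
        icc = self.gcc_solve(np.eye(nc)) - icn @ X.T
        icc = 0.5 * (icc + icc.T)
        return icc, icn, 1.0 / self.Mnn

    def to_sparse(self, order_ids: Optional[Sequence] = None) -> sp.csr_matrix:
        """Assembled sparse inverse, optionally permuted to ``order_ids``."""
        icc, icn, inn = self.inverse_blocks()
        M = sp.bmat(
            [[sp.csr_matrix(icc), sp.csr_matrix(icn)],
             [sp.csr_matrix(icn.T), sp.diags(inn)]],
            format="csr",
        )
        if order_ids is None:
            return M
        own = self.partition.all_ids
        pos = {a: i for i, a in enumerate(own.tolist())}
        try:
            perm = np.array([pos[a] for a in order_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal {exc.args[0]!r} not in partition") from None
        if len(perm) != len(own):
            raise ValueError("order_ids must cover the whole partition")
        P = sp.csr_matrix(
            (np.ones(len(perm)), (np.arange(len(perm)), perm)), shape=(len(perm),) * 2
        )
        return (P @ M @ P.T).tocsr()


def tabular_A(pedigree: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the recursive tabular method."""
    n = pedigree.n_animals
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return A


def build_A_inverse(pedigree: Pedigree) -> NumeratorRelationship:
    """Sparse A^-1 by Henderson's parent-contribution rules with inbreeding.

    The within-family variance for animal i is
    b_i = 0.5 - 0.25 (F_s + F_d), with an unknown parent contributing F = -1
    (i.e. one unknown parent gives b = 0.75 - 0.25 F_known, two give b = 1).
    """
    A = tabular_A(pedigree)
    F = np.diag(A) - 1.0
    n = pedigree.n_animals
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        fs = F[s] if s != UNKNOWN else -1.0
        fd = F[d] if d != UNKNOWN else -1.0
        b = 0.5 - 0.25 * (fs + fd)
        alpha = 1.0 / b
        add(i, i, alpha)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        for p in (s, d):
            if p != UNKNOWN:
                add(p, p, alpha / 4.0)
        if s != UNKNOWN and d != UNKNOWN:
            add(s, d, alpha / 4.0)
            add(d, s, alpha / 4.0)

    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return NumeratorRelationship(
        ids=pedigree.ids.copy(),
        A_inverse=Ainv,
        inbreeding=pd.Series(F, index=pedigree.ids),
    )


def build_A22(pedigree: Pedigree, genotyped_ids) -> np.ndarray:
    """Submatrix of tabular A for the genotyped animals, in the given order."""
    idx = pedigree.index_of(genotyped_ids)
    A = tabular_A(pedigree)
    return A[np.ix_(idx, idx)]


def build_grm(genotypes: GenotypeSet, A22: np.ndarray, alpha: float = 0.95) -> GRM:
    """VanRaden GRM blended with the pedigree submatrix.

    G0 = W W' / (2 sum_j p_j (1 - p_j)) with W the gene content centered at
    twice the observed allele frequencies; G = alpha*G0 + (1-alpha)*A22.
    Monomorphic loci carry no information and are dropped with a warning.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    p = genotypes.allele_freq
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if poly.sum() == 0:
        raise ValueError("all loci are monomorphic; GRM undefined")
    if n_mono:
        logger.warning("dropping %d monomorphic loci before GRM scaling", n_mono)
    Z = np.asarray(genotypes.Z, dtype=np.float64)[:, poly]
    pp = p[poly]
    W = Z - 2.0 * pp
    denom = 2.0 * np.sum(pp * (1.0 - pp))
    G0 = (W @ W.T) / denom
    A22 = np.asarray(A22, dtype=np.float64)
    if A22.shape != G0.shape:
        raise ValueError("A22 shape does not match the genotyped set")
    G = alpha * G0 + (1.0 - alpha) * A22
    return GRM(ids=genotypes.ids.copy(), G=G, blend_weights=(alpha, 1.0 - alpha))


def choose_core_size(genotypes: GenotypeSet, threshold: float) -> int:
    """Smallest k whose top-k squared singular values of centered W reach
    ``threshold`` of the total genetic variance in the GRM."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    W = genotypes.centered()
    s = sla.svdvals(W)
    total = float(np.sum(s**2))
    if total <= 0.0:
        raise ValueError("centered gene content is zero: no genetic variance")
    frac = np.cumsum(s**2) / total
    # guard against cumulative rounding at threshold 1.0
    k = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    return min(k, len(s))


def round_up_core(k: int, step: int = 5000) -> int:
    """Round a core size up to the nearest multiple of ``step``."""
    if k < 1 or step < 1:
        raise ValueError("k and step must be positive")
    return int(-(-k // step) * step)


def select_nested_cores(
    genotyped_ids, sizes: Sequence[int], seed: int
) -> list[CorePartition]:
    """Nested random cores: the largest drawn uniformly from all genotyped
    animals, each smaller core drawn uniformly from the next larger one, so
    the smallest core's animals belong to every larger core."""
    genotyped_ids = np.asarray(genotyped_ids)
    sizes = [int(s) for s in sizes]
    if len(sizes) == 0:
        raise ValueError("need at least one core size")
    if any(s2 >= s1 for s1, s2 in zip(sizes, sizes[1:])):
        raise ValueError("core sizes must be strictly descending")
    if sizes[0] > len(genotyped_ids):
        raise ValueError("largest core exceeds the number of genotyped animals")
    if sizes[-1] < 1:
        raise ValueError("core sizes must be >= 1")

    rng = np.random.default_rng([int(seed), 101])
    all_set = genotyped_ids
    current = np.sort(rng.choice(len(all_set), size=sizes[0], replace=False))
    core = all_set[current]
    partitions = []
    for s in sizes:
        if s < len(core):
            keep = np.sort(rng.choice(len(core), size=s, replace=False))
            core = core[keep]
        mask = np.isin(all_set, core)
        partitions.append(
            CorePartition(
                core_ids=all_set[mask],
                noncore_ids=all_set[~mask],
                scenario_label=f"core{s}",
            )
        )
    return partitions


def build_apy_inverse(
    grm: GRM,
    partition: CorePartition,
    rcond_cap: float = 1e-12,
    mnn_tol: float = 1e-10,
) -> APYInverse:
    """Construct the APY inverse blocks for a given core/noncore partition.

    Fails loudly when the core block is numerically singular (reciprocal
    condition below ``rcond_cap``) or when a noncore conditional variance
    m_ii falls below ``mnn_tol`` — both indicate a core that cannot support
    the conditioning.
    """
    cidx = grm.index_of(partition.core_ids)
    nidx = grm.index_of(partition.noncore_ids)
    Gcc = grm.G[np.ix_(cidx, cidx)]
    Gcn = grm.G[np.ix_(cidx, nidx)]
    gnn = grm.G[nidx, nidx]

    sv = sla.svdvals(Gcc)
    rcond = sv[-1] / sv[0] if sv[0] > 0 else 0.0
    if rcond < rcond_cap:
        raise APYError(
            f"core block numerically singular (rcond={rcond:.2e}); "
            "choose a different or larger core"
        )
    try:
        cho = sla.cho_factor(Gcc, lower=True)
    except sla.LinAlgError as exc:
        raise APYError(f"core block not positive definite: {exc}") from None

    if len(nidx):
        X = sla.cho_solve(cho, Gcn)
        Mnn = gnn - np.einsum("ij,ij->j", Gcn, X)
    else:
        Mnn = np.zeros(0)
    bad = np.nonzero(Mnn <= mnn_tol)[0]
    if bad.size:
        animal = partition.noncore_ids[bad[0]]
        raise APYError(
            f"noncore conditional variance non-positive for animal {animal!r}"
        )
    return APYInverse(partition=partition, Gcc=Gcc, Gcn=Gcn, Mnn=Mnn, _cho=cho)
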