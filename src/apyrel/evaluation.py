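"""Single-trait ssGBLUP mixed model equations and exact reliabilities.

The combined relationship inverse is

    H^-1 = A^-1 + [0, 0; 0, tau*G^-1 - omega*A22^-1]

added on the genotyped block.  Henderson's equations for the animal model
y = Xb + Wu + e (W the 0/1 incidence of records on animal equations) are

    [ X'X      X'W          ] [b]   [X'y]
    [ W'X  W'W + lambda H^-1] [u] = [W'y],   lambda = sigma_e^2 / sigma_a^2.

At desk scale the coefficient matrix C is inverted directly; the prediction
error variance of animal i is PEV_i = sigma_e^2 [C^-1]_ii on its equation and
its exact reliability is 1 - PEV_i / (sigma_a^2 (1 + F_i)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .relationships import APYInverse, NumeratorRelationship
from .simulate import PhenotypeSet

__all__ = [
    "ModelParams",
    "MMESystem",
    "MMESolution",
    "ReliabilityTable",
    "build_H_inverse",
    "assemble_mme",
    "solve_mme",
    "exact_reliabilities",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelParams:
    """Variance components of the single-trait animal model."""

    heritability: float
    sigma_a2: float
    sigma_e2: float
    tau: float = 1.0
    omega: float = 1.0

    @classmethod
    def from_heritability(
        cls, h2: float, total_variance: float = 1.0, tau: float = 1.0, omega: float = 1.0
    ) -> "ModelParams":
        if not (0.0 < h2 < 1.0):
            raise ValueError("heritability must be in (0, 1)")
        return cls(
            heritability=h2,
            sigma_a2=h2 * total_variance,
            sigma_e2=(1.0 - h2) * total_variance,
            tau=tau,
            omega=omega,
        )

    @property
    def lam(self) -> float:
        """Variance ratio lambda = sigma_e^2 / sigma_a^2."""
        return self.sigma_e2 / self.sigma_a2


@dataclass
class MMESystem:
    """Assembled mixed model equations (fixed effects first, then animals)."""

    coefficient_matrix: sp.csc_matrix
    rhs: np.ndarray
    H_inverse: sp.spmatrix
    animal_ids: np.ndarray
    n_fixed: int
    _cinv: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_equations(self) -> int:
        return self.coefficient_matrix.shape[0]

    def animal_index(self, animal_ids) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.animal_ids.tolist())}
        return self.n_fixed + np.array([index[a] for a in animal_ids], dtype=np.int64)

    def inverse(self) -> np.ndarray:
        """Dense inverse of the coefficient matrix (cached; desk scale only)."""
        if self._cinv is None:
            C = self.coefficient_matrix.toarray()
            try:
                cho = sla.cho_factor(C)
                self._cinv = sla.cho_solve(cho, np.eye(C.shape[0]))
            except sla.LinAlgError:
                # rank-deficient fixed block: generalized inverse semantics
                warnings.warn(
                    "coefficient matrix singular; using pseudo-inverse",
                    RuntimeWarning,
                )
                self._cinv = sla.pinvh(C)
        return self._cinv


@dataclass
class MMESolution:
    fixed: np.ndarray
    breeding_values: pd.Series


@dataclass
class ReliabilityTable:
    """Per-animal PEV and reliability, tagged exact vs approximated."""

    ids: np.ndarray
    pev: np.ndarray
    reliability: np.ndarray
    flavor: str
    scenario_label: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.pev = np.asarray(self.pev, dtype=np.float64)
        self.reliability = np.asarray(self.reliability, dtype=np.float64)

    def series(self) -> pd.Series:
        return pd.Series(self.reliability, index=self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.ids,
                "pev": self.pev,
                "reliability": self.reliability,
                "flavor": self.flavor,
                "scenario": self.scenario_label,
            }
        )


def build_H_inverse(
    numrel: NumeratorRelationship,
    g_inverse,
    genotyped_ids,
    params: ModelParams,
    A22: Optional[np.ndarray] = None,
) -> sp.csr_matrix:
    """H^-1 = A^-1 plus (tau G^-1 - omega A22^-1) scattered on the genotyped block.

    ``g_inverse`` may be a dense G^-1 (in ``genotyped_ids`` order), a sparse
    matrix, or an :class:`APYInverse` whose assembled blocks are permuted to
    that order.  With no genotyped animals H^-1 is simply A^-1.
    """
    genotyped_ids = np.asarray(genotyped_ids)
    if len(genotyped_ids) == 0:
        return numrel.A_inverse.tocsr(copy=True)
    gidx = {a: i for i, a in enumerate(numrel.ids.tolist())}
    try:
        rows = np.array([gidx[a] for a in genotyped_ids], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"genotyped animal {exc.args[0]!r} not in pedigree") from None

    if isinstance(g_inverse, APYInverse):
        Ginv = g_inverse.to_sparse(order_ids=genotyped_ids)
    elif sp.issparse(g_inverse):
        Ginv = g_inverse.tocsr()
    else:
        Ginv = sp.csr_matrix(np.asarray(g_inverse, dtype=np.float64))
    if Ginv.shape[0] != len(genotyped_ids):
        raise ValueError("G inverse dimension does not match genotyped ids")

    if A22 is None:
        A22 = numrel.A22
        if A22 is None:
            raise ValueError("A22 required (pass it or set numrel.A22)")
        if numrel.A22_ids is not None and not np.array_equal(
            np.asarray(numrel.A22_ids), genotyped_ids
        ):
            raise ValueError("numrel.A22 is in a different id order")
    A22inv = sla.inv(np.asarray(A22, dtype=np.float64))

    delta = (params.tau * Ginv - params.omega * sp.csr_matrix(A22inv)).tocoo()
    n = len(numrel.ids)
    scatter = sp.coo_matrix(
        (delta.data, (rows[delta.row], rows[delta.col])), shape=(n, n)
    )
    H = (numrel.A_inverse + scatter).tocsr()
    return H


def assemble_mme(
    phenotypes: PhenotypeSet,
    H_inverse: sp.spmatrix,
    animal_ids,
    params: ModelParams,
    fixed_design: Union[str, np.ndarray, None] = "auto",
) -> MMESystem:
    """Henderson's MME for the single-trait animal model.

    ``fixed_design`` is "auto" (one-hot levels from the phenotype set when a
    categorical effect is present, otherwise an intercept), "intercept",
    "none" (no fixed effects), or an explicit record-by-covariate array.
    """
    animal_ids = np.asarray(animal_ids)
    index = {a: i for i, a in enumerate(animal_ids.tolist())}
    rec_ids = phenotypes.records.index.to_numpy()
    missing = [a for a in rec_ids if a not in index]
    if missing:
        raise KeyError(f"phenotype for unknown animal {missing[0]!r}")
    y = phenotypes.records.to_numpy(dtype=np.float64)
    n_rec = len(y)
    n_anim = len(animal_ids)

    if isinstance(fixed_design, str):
        if fixed_design == "none":
            X = np.zeros((n_rec, 0))
        elif fixed_design == "intercept":
            X = np.ones((n_rec, 1))
        elif fixed_design == "auto":
            levels = phenotypes.fixed_level.reindex(rec_ids).to_numpy()
            n_lev = int(levels.max()) + 1 if n_rec else 1
            if n_lev > 1:
                X = np.zeros((n_rec, n_lev))
                X[np.arange(n_rec), levels.astype(int)] = 1.0
            else:
                X = np.ones((n_rec, 1))
        else:
            raise ValueError(f"unknown fixed_design {fixed_design!r}")
    elif fixed_design is None:
        X = np.zeros((n_rec, 0))
    else:
        X = np.asarray(fixed_design, dtype=np.float64)
        if X.shape[0] != n_rec:
            raise ValueError("fixed design rows must match the number of records")
    n_fixed = X.shape[1]
    if n_fixed and np.linalg.matrix_rank(X.T @ X) < n_fixed:
        warnings.warn("rank-deficient fixed-effect block", RuntimeWarning)

    rec_rows = np.array([index[a] for a in rec_ids], dtype=np.int64)
    Wn = sp.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), rec_rows)), shape=(n_rec, n_anim)
    )
    Xs = sp.csr_matrix(X)
    lam = params.lam
    C = sp.bmat(
        [
            [Xs.T @ Xs, Xs.T @ Wn],
            [Wn.T @ Xs, (Wn.T @ Wn + lam * H_inverse)],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, np.asarray((Wn.T @ y)).ravel()])
    return MMESystem(
        coefficient_matrix=C,
        rhs=rhs,
        H_inverse=H_inverse,
        animal_ids=animal_ids,
        n_fixed=n_fixed,
    )


def solve_mme(system: MMESystem) -> MMESolution:
    """Solve the MME by sparse factorization (dense least squares fallback
    for rank-deficient fixed blocks)."""
    C = system.coefficient_matrix
    scale = max(np.linalg.norm(system.rhs), 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", spla.MatrixRankWarning)
            sol = spla.splu(C.tocsc()).solve(system.rhs)
        if not np.isfinite(sol).all() or np.linalg.norm(C @ sol - system.rhs) > 1e-8 * scale:
            raise RuntimeError("sparse solve inaccurate")
    except (RuntimeError, spla.MatrixRankWarning):
        sol, *_ = np.linalg.lstsq(C.toarray(), system.rhs, rcond=None)
        if np.linalg.norm(C @ sol - system.rhs) > 1e-6 * scale:
            raise sla.LinAlgError(
                "mixed model equations singular beyond the fixed block"
            ) from None
    nf = system.n_fixed
    return MMESolution(
        fixed=sol[:nf],
        breeding_values=pd.Series(sol[nf:], index=system.animal_ids),
    )


def exact_reliabilities(
    system: MMESystem,
    params: ModelParams,
    inbreeding: pd.Series,
    scenario_label: str = "exact",
) -> ReliabilityTable:
    """Exact PEV and reliabilities from the inverse of the coefficient matrix.

    PEV_i = sigma_e^2 [C^-1]_ii on animal i's equation; reliability is
    1 - PEV_i / (sigma_a^2 (1 + F_i)), clipped to [0, 1].
    """
    Cinv = system.inverse()
    diag = np.diag(Cinv)[system.n_fixed :]
    pev = params.sigma_e2 * diag
    if np.any(pev < -1e-8 * params.sigma_e2):
        raise RuntimeError("negative prediction error variance: assembly bug")
    pev = np.maximum(pev, 0.0)
    F = inbreeding.reindex(system.animal_ids)
    if F.isna().any():
        raise KeyError("inbreeding missing for some animals in the system")
    denom = params.sigma_a2 * (1.0 + F.to_numpy())
    rel = 1.0 - pev / denom
    if np.any(rel < -1e-6) :
        logger.info("reliabilities below 0 before clipping (max violation %.2e)",
                    float(-rel.min()))
    rel = np.clip(rel, 0.0, 1.0)
    return ReliabilityTable(
        ids=system.animal_ids.copy(),
        pev=pev,
        reliability=rel,
        flavor="exact",
        scenario_label=scenario_label,
    )
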