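"""Multi-trait GBLUP comparator: genomic relationship matrix (VanRaden
method 1), bivariate AI-REML with record-specific residual weights, and
BLUP breeding values at the converged estimates.

Each animal carries a record for exactly one of the two traits (its
population defines the trait), so the residual covariance between traits
is structurally zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .genome_data import GenotypePanel, align_phenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRelationshipMatrix",
    "VarianceComponents",
    "build_grm",
    "reml_bivariate",
    "gebv_from_components",
    "grm_to_hdf5",
    "grm_from_hdf5",
]


@dataclass
class GenomicRelationshipMatrix:
    """Symmetric animals x animals relationship matrix G = ZZ'/(2 sum p q)."""

    values: np.ndarray
    animal_id: np.ndarray
    n_pop1: int
    allele_freq: np.ndarray
    scaling: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("G must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        self.values = v

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    def blocks(self) -> tuple:
        """(G11, G12, G22) population sub-blocks."""
        n1 = self.n_pop1
        return (self.values[:n1, :n1], self.values[:n1, n1:],
                self.values[n1:, n1:])


def build_grm(panels, freq_base: str = "combined",
              stabilize: bool = False) -> GenomicRelationshipMatrix:
    """VanRaden method-1 G across both populations' animals.

    ``freq_base`` selects the allele frequencies used for centering and
    scaling: "combined" (default, observed in the pooled genotype set) or
    "per_panel" (each panel centered by its own frequencies; scaling from
    the pooled set).  ``stabilize`` adds 1e-6 to the diagonal only when a
    Cholesky factorization of G fails.
    """
    panel1, panel2 = panels
    if not np.array_equal(panel1.map.marker_id, panel2.map.marker_id):
        raise ValueError("panels must share one harmonized marker map")
    g_all = np.vstack(
        [panel1.genotypes.astype(np.float64), panel2.genotypes.astype(np.float64)]
    )
    p_comb = g_all.mean(axis=0) / 2.0
    scaling = float(np.sum(2.0 * p_comb * (1.0 - p_comb)))
    if scaling <= 0.0:
        raise ValueError("all markers monomorphic in the combined set; "
                         "G scaling constant is zero")
    if freq_base == "combined":
        Z = g_all - 2.0 * p_comb[np.newaxis, :]
    elif freq_base == "per_panel":
        Z = np.vstack(
            [
                panel1.genotypes - 2.0 * panel1.allele_freq[np.newaxis, :],
                panel2.genotypes - 2.0 * panel2.allele_freq[np.newaxis, :],
            ]
        )
    else:
        raise ValueError(f"unknown freq_base {freq_base!r}")
    G = (Z @ Z.T) / scaling
    if stabilize:
        try:
            np.linalg.cholesky(G)
        except np.linalg.LinAlgError:
            G = G + 1e-6 * np.eye(G.shape[0])
    ids = np.concatenate([panel1.animal_id, panel2.animal_id])
    return GenomicRelationshipMatrix(G, ids, panel1.n_animals, p_comb, scaling)


def grm_to_hdf5(path, grm: GenomicRelationshipMatrix) -> None:
    """Persist G with its animal-id index (HDF5)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("G", data=grm.values)
        f.create_dataset(
            "animal_id",
            data=np.array([str(a) for a in grm.animal_id], dtype="S"),
        )
        f.create_dataset("allele_freq", data=grm.allele_freq)
        f.attrs["n_pop1"] = grm.n_pop1
        f.attrs["scaling"] = grm.scaling


def grm_from_hdf5(path) -> GenomicRelationshipMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        return GenomicRelationshipMatrix(
            values=f["G"][()],
            animal_id=np.array([a.decode() for a in f["animal_id"][()]],
                               dtype=object),
            n_pop1=int(f.attrs["n_pop1"]),
            allele_freq=f["allele_freq"][()],
            scaling=float(f.attrs["scaling"]),
        )


@dataclass
class VarianceComponents:
    """Bivariate REML estimates and their asymptotic standard errors."""

    g0: np.ndarray                      # 2x2 additive (co)variance matrix
    residual_var: np.ndarray            # (ve1, ve2)
    se: np.ndarray                      # SEs of (va1, cov, va2, ve1, ve2)
    corr: float
    corr_se: float
    loglik: float
    loglik_path: list
    n_iter: int
    converged: bool
    ai_inverse: np.ndarray
    boundary: bool = False              # G0 pinned at the PSD boundary

    @property
    def va(self) -> np.ndarray:
        return np.array([self.g0[0, 0], self.g0[1, 1]])

    @property
    def cov(self) -> float:
        return float(self.g0[0, 1])


def _build_v(theta, G11, G12, G22, d1, d2):
    va1, cov, va2, ve1, ve2 = theta
    n1, n2 = len(d1), len(d2)
    V = np.empty((n1 + n2, n1 + n2))
    V[:n1, :n1] = va1 * G11
    V[:n1, n1:] = cov * G12
    V[n1:, :n1] = cov * G12.T
    V[n1:, n1:] = va2 * G22
    V[np.arange(n1), np.arange(n1)] += ve1 * d1
    V[np.arange(n1, n1 + n2), np.arange(n1, n1 + n2)] += ve2 * d2
    return V


def _reml_pieces(theta, G11, G12, G22, X, y, d1, d2):
    """Restricted log-likelihood, P matrix and Py for current theta."""
    V = _build_v(theta, G11, G12, G22, d1, d2)
    c, low = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = cho_solve((c, low), np.eye(V.shape[0]))
    XtVinv = X.T @ Vinv
    XtVinvX = XtVinv @ X
    cx = np.linalg.cholesky(XtVinvX)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cx)))
    P = Vinv - XtVinv.T @ np.linalg.solve(XtVinvX, XtVinv)
    Py = P @ y
    loglik = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return loglik, P, Py


def _derivative_mats(G11, G12, G22, d1, d2):
    """dV/dtheta_i applied as (matrix multiply, trace) closures."""
    n1, n2 = len(d1), len(d2)
    n = n1 + n2

    def mk(apply_fn, trace_fn):
        return {"apply": apply_fn, "trace": trace_fn}

    def a_va1(v):
        out = np.zeros_like(v)
        out[:n1] = G11 @ v[:n1]
        return out

    def t_va1(P):
        return float(np.sum(P[:n1, :n1] * G11))

    def a_cov(v):
        out = np.zeros_like(v)
        out[:n1] = G12 @ v[n1:]
        out[n1:] = G12.T @ v[:n1]
        return out

    def t_cov(P):
        return 2.0 * float(np.sum(P[:n1, n1:] * G12))

    def a_va2(v):
        out = np.zeros_like(v)
        out[n1:] = G22 @ v[n1:]
        return out

    def t_va2(P):
        return float(np.sum(P[n1:, n1:] * G22))

    def a_ve1(v):
        out = np.zeros_like(v)
        out[:n1] = d1 * v[:n1]
        return out

    def t_ve1(P):
        return float(np.sum(np.diag(P)[:n1] * d1))

    def a_ve2(v):
        out = np.zeros_like(v)
        out[n1:] = d2 * v[n1:]
        return out

    def t_ve2(P):
        return float(np.sum(np.diag(P)[n1:] * d2))

    return [mk(a_va1, t_va1), mk(a_cov, t_cov), mk(a_va2, t_va2),
            mk(a_ve1, t_ve1), mk(a_ve2, t_ve2)]


def _in_bounds(theta, floor):
    va1, cov, va2, ve1, ve2 = theta
    if min(va1, va2, ve1, ve2) <= floor:
        return False
    return cov * cov < 0.9999 * va1 * va2


def reml_bivariate(
    grm: GenomicRelationshipMatrix,
    drp_tables,
    max_iter: int = 100,
    tol: float = 1e-6,
    theta0=None,
) -> VarianceComponents:
    """Average-information REML for the bivariate weighted mixed model.

    AI (Newton) proposals are guarded by a step-halving line search on the
    restricted likelihood; when a full AI step leaves the parameter space
    or cannot improve, an EM-flavoured gradient step (Harville form) is
    taken instead.  Accepted iterations never decrease the restricted
    likelihood.  Raises on non-convergence, carrying the trajectory.
    """
    table1, table2 = drp_tables
    n1 = grm.n_pop1
    id1 = grm.animal_id[:n1]
    id2 = grm.animal_id[n1:]
    y1, d1 = _align(table1, id1)
    y2, d2 = _align(table2, id2)
    G11, G12, G22 = grm.blocks()
    n2 = len(y2)
    y = np.concatenate([y1, y2])
    X = np.zeros((n1 + n2, 2))
    X[:n1, 0] = 1.0
    X[n1:, 1] = 1.0

    vary = np.array([np.var(y1), np.var(y2)])
    floor = 1e-8 * float(vary.mean())
    if theta0 is None:
        theta = np.array([0.5 * vary[0], 0.25 * np.sqrt(vary[0] * vary[1]),
                          0.5 * vary[1], 0.5 * vary[0], 0.5 * vary[1]])
    else:
        theta = np.asarray(theta0, dtype=np.float64).copy()
    derivs = _derivative_mats(G11, G12, G22, d1, d2)
    q = grm.n_animals
    em_dims = np.array([q, q, q, n1, n2], dtype=np.float64)

    loglik, P, Py = _reml_pieces(theta, G11, G12, G22, X, y, d1, d2)
    path = [loglik]
    ai = np.eye(5)
    converged = False
    n_done = 0
    for it in range(1, max_iter + 1):
        n_done = it
        # score and average-information matrix at current theta
        APy = [dv["apply"](Py) for dv in derivs]
        score = np.array(
            [-0.5 * (dv["trace"](P) - float(Py @ APy[i]))
             for i, dv in enumerate(derivs)]
        )
        PAPy = [P @ v for v in APy]
        ai = 0.5 * np.array(
            [[float(APy[i] @ PAPy[j]) for j in range(5)] for i in range(5)]
        )
        ai = 0.5 * (ai + ai.T)
        try:
            delta = np.linalg.solve(ai + 1e-10 * np.eye(5), score)
        except np.linalg.LinAlgError:
            delta = score / np.diag(ai).clip(min=1e-12)

        accepted = False
        step = 1.0
        for _ in range(20):
            cand = theta + step * delta
            if _in_bounds(cand, floor):
                ll, P_c, Py_c = _reml_pieces(cand, G11, G12, G22, X, y, d1, d2)
                if ll >= loglik - 1e-10:
                    accepted, theta, loglik, P, Py = True, cand, ll, P_c, Py_c
                    break
            step *= 0.5
        if not accepted:
            # EM-flavoured fallback: theta_i + 2 theta_ref^2 / t_i * score_i
            ref = theta.copy()
            ref[1] = np.sqrt(max(theta[0] * theta[2], floor))
            em = theta + 2.0 * ref**2 / em_dims * score
            em[0] = max(em[0], floor)
            em[2] = max(em[2], floor)
            em[3] = max(em[3], floor)
            em[4] = max(em[4], floor)
            lim = 0.999 * np.sqrt(em[0] * em[2])
            em[1] = np.clip(em[1], -lim, lim)
            step = 1.0
            for _ in range(20):
                cand = theta + step * (em - theta)
                if _in_bounds(cand, floor):
                    ll, P_c, Py_c = _reml_pieces(cand, G11, G12, G22, X, y, d1, d2)
                    if ll >= loglik - 1e-10:
                        accepted, theta, loglik, P, Py = True, cand, ll, P_c, Py_c
                        break
                step *= 0.5
        path.append(loglik)
        rel_change = np.max(np.abs(step * delta) / (np.abs(theta) + 1e-8)) \
            if accepted else 0.0
        grad_small = np.linalg.norm(score) < tol * (1.0 + abs(loglik))
        ll_stalled = (path[-1] - path[-2]) < 1e-9 * (1.0 + abs(loglik))
        if (accepted and (rel_change < tol or ll_stalled)) or grad_small:
            converged = True
            break
        if not accepted:
            # no uphill direction found: treat as converged at a boundary
            converged = True
            break
    if not converged:
        err = RuntimeError(
            f"AI-REML did not converge in {max_iter} iterations; "
            f"last restricted logL {loglik:.6f}"
        )
        err.trajectory = path
        raise err

    ai_inv = np.linalg.inv(ai + 1e-12 * np.eye(5))
    se = np.sqrt(np.clip(np.diag(ai_inv), 0.0, None))
    va1, cov, va2, ve1, ve2 = theta
    corr = cov / np.sqrt(va1 * va2)
    # delta-method SE of the correlation
    grad = np.array([-0.5 * corr / va1, 1.0 / np.sqrt(va1 * va2),
                     -0.5 * corr / va2, 0.0, 0.0])
    corr_var = float(grad @ ai_inv @ grad)
    boundary = bool(cov * cov >= 0.998 * va1 * va2)
    if boundary:
        logger.warning("G0 estimate pinned near the PSD boundary")
    g0 = np.array([[va1, cov], [cov, va2]])
    return VarianceComponents(
        g0=g0,
        residual_var=np.array([ve1, ve2]),
        se=se,
        corr=float(corr),
        corr_se=float(np.sqrt(max(corr_var, 0.0))),
        loglik=float(loglik),
        loglik_path=path,
        n_iter=n_done,
        converged=converged,
        ai_inverse=ai_inv,
        boundary=boundary,
    )


def _align(table, ids):
    pos = {a: i for i, a in enumerate(table.animal_id)}
    missing = [a for a in ids if a not in pos]
    if missing:
        raise ValueError(f"{len(missing)} animals in G lack DRP records")
    order = np.array([pos[a] for a in ids], dtype=np.int64)
    return table.drp[order], table.weight[order]


def gebv_from_components(
    grm: GenomicRelationshipMatrix,
    components: VarianceComponents,
    drp_tables,
):
    """BLUP breeding values for both traits for every genotyped animal.

    Solves a_hat = Cov(a, y) V^-1 (y - X b_hat) at the REML estimates;
    animals without a record for a trait get a prediction through G.
    Returns an (n_animals, 2) array in G's animal order.
    """
    table1, table2 = drp_tables
    n1 = grm.n_pop1
    y1, d1 = _align(table1, grm.animal_id[:n1])
    y2, d2 = _align(table2, grm.animal_id[n1:])
    y = np.concatenate([y1, y2])
    n = len(y)
    X = np.zeros((n, 2))
    X[:n1, 0] = 1.0
    X[n1:, 1] = 1.0
    G11, G12, G22 = grm.blocks()
    va1, cov = components.g0[0, 0], components.g0[0, 1]
    va2 = components.g0[1, 1]
    ve1, ve2 = components.residual_var

    V = _build_v((va1, cov, va2, ve1, ve2), G11, G12, G22, d1, d2)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular coefficient matrix in BLUP system"
        ) from exc
    Vinv_y = cho_solve((c, low), y)
    Vinv_X = cho_solve((c, low), X)
    bhat = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
    resid = cho_solve((c, low), y - X @ bhat)

    G = grm.values
    # Cov(a_trait, record) = G0[trait, trait_of_record] * G[:, animal_of_record]
    cov_t1 = np.hstack([va1 * G[:, :n1], cov * G[:, n1:]])
    cov_t2 = np.hstack([cov * G[:, :n1], va2 * G[:, n1:]])
    gebv = np.column_stack([cov_t1 @ resid, cov_t2 @ resid])
    return gebv
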