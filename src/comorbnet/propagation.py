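"""Comorbidity scoring by label propagation on a signed graph.

Given a signed disease-disease network and a single labeled index disease
(unary label y = +1), comorbidity scores f for all diseases minimize

    (f - y)^T (f - y)  +  mu * f^T Lbar f,

where Lbar = Dbar - W is the *signed* graph Laplacian with absolute-value
degrees dbar_i = sum_j |w_ij|.  The smoothness term expands to

    sum_{i~j} |w_ij| (f_i - sign(w_ij) f_j)^2,

so scores agree across synergistic edges and oppose across antagonistic ones;
Lbar is positive semidefinite, making the problem strictly convex with closed
form f = (I + mu Lbar)^{-1} y.  Scores on unlabeled nodes may be negative:
a negative score marks inverse comorbidity (co-occurrence less likely than
baseline given the index disease).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.linalg import solve
from scipy.sparse.linalg import LinearOperator, cg
from sklearn.base import BaseEstimator

from .network import SignedGraph

#: dense direct solve below this many nodes, preconditioned CG above
DEFAULT_DIRECT_CUTOFF = 2000


@dataclass
class ScoreVector:
    """Propagated comorbidity scores relative to one index disease."""

    nodes: list[str]
    values: np.ndarray
    index_disease: str
    mu: float
    rescaled: bool = False

    def __getitem__(self, phenotype_id: str) -> float:
        return float(self.values[self.nodes.index(phenotype_id)])

    def unlabeled(self) -> dict[str, float]:
        return {
            n: float(v)
            for n, v in zip(self.nodes, self.values)
            if n != self.index_disease
        }


def _check_symmetric(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    return W


def signed_degree(W: np.ndarray) -> np.ndarray:
    """Signed degrees dbar_i = sum_j |w_ij| (absolute values)."""
    W = _check_symmetric(W)
    return np.abs(W).sum(axis=1)


def signed_laplacian(W: np.ndarray) -> np.ndarray:
    """Signed graph Laplacian Lbar = diag(dbar) - W; positive semidefinite."""
    W = _check_symmetric(W)
    return np.diag(signed_degree(W)) - W


def smoothness_energy(f: np.ndarray, W: np.ndarray) -> float:
    """Edge-sum smoothness sum_{i~j} |w_ij| (f_i - sign(w_ij) f_j)^2.

    Each undirected edge counted once; equals f^T Lbar f.
    """
    W = _check_symmetric(W)
    f = np.asarray(f, dtype=float)
    if f.shape != (W.shape[0],):
        raise ValueError("f length must match W")
    iu = np.triu_indices(W.shape[0], k=1)
    w = W[iu]
    return float(np.sum(np.abs(w) * (f[iu[0]] - np.sign(w) * f[iu[1]]) ** 2))


class SignedLabelPropagation(BaseEstimator):
    """Transductive comorbidity scoring on a signed graph.

    Solves (I + mu * Lbar) f = y for the unary label vector y of the index
    disease.  scikit-learn estimator: ``fit(W, y)`` stores the solution in
    fitted attributes; the graph itself is the "X" of the transductive problem.

    Parameters
    ----------
    mu : float
        Smoothness/loss trade-off (mu >= 0).  mu = 0 returns f = y.
    solver : {"auto", "direct", "iterative"}
        "direct" is a dense symmetric solve; "iterative" is conjugate gradients
        with Jacobi preconditioning.  "auto" switches at ``direct_cutoff``
        nodes.
    tol : float
        CG convergence tolerance (relative residual).
    max_iter : int or None
        CG iteration cap (None lets scipy choose).

    Attributes
    ----------
    scores_ : ndarray of shape (n_nodes,)
        Raw comorbidity scores f.
    label_index_ : int
        Position of the index disease (the +1 label).
    n_iter_ : int
        CG iterations used (0 for the direct solver).
    """

    def __init__(
        self,
        mu: float = 1.0,
        solver: str = "auto",
        direct_cutoff: int = DEFAULT_DIRECT_CUTOFF,
        tol: float = 1e-8,
        max_iter: int | None = None,
    ):
        self.mu = mu
        self.solver = solver
        self.direct_cutoff = direct_cutoff
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        """Solve the propagation system.

        Parameters
        ----------
        X : array-like of shape (n, n)
            Symmetric signed weight matrix W.
        y : array-like of shape (n,)
            Unary label vector: exactly one entry +1, the rest 0.
        """
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.solver not in ("auto", "direct", "iterative"):
            raise ValueError(f"unknown solver {self.solver!r}")
        W = _check_symmetric(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (W.shape[0],):
            raise ValueError("y length must match W")
        labeled = np.flatnonzero(y)
        if labeled.size != 1 or y[labeled[0]] != 1.0:
            raise ValueError("y must be unary: exactly one entry equal to +1")
        self.label_index_ = int(labeled[0])
        n = W.shape[0]
        self.n_features_in_ = n

        if self.mu == 0:
            self.scores_ = y.copy()
            self.n_iter_ = 0
            return self

        dbar = np.abs(W).sum(axis=1)
        solver = self.solver
        if solver == "auto":
            solver = "direct" if n <= self.direct_cutoff else "iterative"
        if solver == "direct":
            A = np.diag(1.0 + self.mu * dbar) - self.mu * W
            f = solve(A, y, assume_a="pos")
            self.n_iter_ = 0
        else:
            Ws = sparse.csr_matrix(W)
            diag = 1.0 + self.mu * dbar

            def matvec(v):
                return diag * v - self.mu * (Ws @ v)

            A_op = LinearOperator((n, n), matvec=matvec, dtype=float)
            M = LinearOperator((n, n), matvec=lambda v: v / diag, dtype=float)
            it_count = [0]

            def cb(_):
                it_count[0] += 1

            f, info = cg(A_op, y, rtol=self.tol, atol=0.0, M=M,
                         maxiter=self.max_iter, callback=cb)
            if info != 0:
                resid = float(np.linalg.norm(matvec(f) - y))
                raise RuntimeError(
                    f"conjugate-gradient solver did not converge (info={info}, "
                    f"residual={resid:.3e})"
                )
            self.n_iter_ = it_count[0]
        # unlabeled isolated nodes carry no information: exactly 0
        isolated = (dbar == 0) & (y == 0)
        f[isolated] = 0.0
        self.scores_ = f
        return self

    def fit_predict(self, X, y) -> np.ndarray:
        return self.fit(X, y).scores_


def make_label_vector(nodes: list[str], index_disease: str) -> np.ndarray:
    """Unary label vector: +1 on the index disease, 0 elsewhere."""
    y = np.zeros(len(nodes))
    try:
        y[nodes.index(index_disease)] = 1.0
    except ValueError:
        raise KeyError(f"index disease {index_disease!r} not in graph") from None
    return y


def propagate_scores(
    G: SignedGraph,
    index_disease: str,
    mu: float = 1.0,
    solver: str = "auto",
    **solver_kwargs,
) -> ScoreVector:
    """Propagate the index-disease label over the signed graph; see
    :class:`SignedLabelPropagation`."""
    y = make_label_vector(G.nodes, index_disease)
    est = SignedLabelPropagation(mu=mu, solver=solver, **solver_kwargs).fit(G.weights, y)
    return ScoreVector(list(G.nodes), est.scores_, index_disease, mu)


def rescale_scores(scores: ScoreVector) -> ScoreVector:
    """Rescale unlabeled scores into [-1, 1] by their maximum absolute value.

    The index disease is excluded from the maximum and keeps its raw score
    (reported separately from the ranking).  Rescaling is strictly monotone on
    the unlabeled scores, so ranks, ROC curves and rank correlations are
    unchanged.  All-zero input is returned unchanged.
    """
    idx = scores.nodes.index(scores.index_disease)
    values = scores.values.copy()
    mask = np.ones(len(values), dtype=bool)
    mask[idx] = False
    scale = np.max(np.abs(values[mask])) if mask.any() else 0.0
    if scale > 0:
        values[mask] = values[mask] / scale
    return replace(scores, values=values, rescaled=True)


def mu_sweep(
    G: SignedGraph,
    index_disease: str,
    mus: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 10.0),
    **kwargs,
) -> dict[float, ScoreVector]:
    """Sensitivity sweep over the smoothness trade-off mu."""
    return {mu: propagate_scores(G, index_disease, mu=mu, **kwargs) for mu in mus}
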