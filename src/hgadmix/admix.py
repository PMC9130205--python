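"""Admixture modeling: a frequency vector as a weighted sum of central vectors.

A population's haplogroup distribution ``h`` (a D-vector) is approximated as
a linear combination of N central vectors ``v_1 ... v_N``:

    h = a_1 v_1 + ... + a_N v_N + eps

The weights minimize the error power ``H = sum_k eps_k**2``; the quality of a
fit is the normalized error ``J = H / sum_k h_k**2``, which is 0 for a
perfect reconstruction and 1 for the null model with all weights zero.  The
central vectors are generally *not* orthogonal, so the weights are not
independent coordinates; they are not normalized to sum to one and may
exceed one.

The reference solver is steepest descent on H from the all-zero weight
vector (which anchors J <= 1), with analytic gradient

    dH/da_m = -2 sum_k eps_k v_{m,k}

and backtracking step control: the step is halved until H decreases and
grown by 1.2 after each accepted step, starting from ``learning_rate``
scaled by the spectral norm of the Gram matrix.  An exact normal-equations
solver (``solver="exact"``; least squares via ``numpy.linalg.lstsq``) is
shipped as a fast path and as the independent oracle used in the tests.  An
optional non-negativity constraint projects the weights onto a_i >= 0 after
each step, supporting the strict admixture-proportion reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .freqmatrix import FrequencyMatrix
from .soc import SelfOrganizingCloud

__all__ = [
    "AdmixtureFit",
    "AdmixtureModel",
    "model_distribution",
    "error_terms",
    "gradient",
    "solve_weights",
    "fit_all",
]


def _central_vectors(cvset) -> np.ndarray:
    if isinstance(cvset, SelfOrganizingCloud):
        check_is_fitted(cvset, "cluster_centers_")
        return np.asarray(cvset.cluster_centers_, dtype=float)
    V = np.asarray(cvset, dtype=float)
    if V.ndim != 2:
        raise ValueError("central vectors must form an N x D matrix")
    return V


@dataclass
class AdmixtureFit:
    """Result of fitting one distribution: weights, error vector, error
    power H, normalized error J, iteration count and convergence flag."""

    weights: np.ndarray
    error_vector: np.ndarray
    error_power: float
    normalized_error: float
    iterations: int
    converged: bool
    history: Optional[np.ndarray] = field(default=None, repr=False)


def model_distribution(cvset, weights) -> np.ndarray:
    """The modeled distribution ``sum_i a_i v_i``."""
    V = _central_vectors(cvset)
    a = np.asarray(weights, dtype=float)
    if a.shape != (V.shape[0],):
        raise ValueError(
            f"expected {V.shape[0]} weights, got shape {a.shape}"
        )
    return a @ V


def error_terms(h, cvset, weights) -> tuple[np.ndarray, float, float]:
    """Error vector eps = h - sum a_i v_i, its power H and normalized J."""
    h = np.asarray(h, dtype=float)
    eps = h - model_distribution(cvset, weights)
    H = float(eps @ eps)
    hh = float(h @ h)
    if hh == 0.0:
        raise ValueError("normalized error J undefined for an all-zero target")
    return eps, H, H / hh


def gradient(h, cvset, weights) -> np.ndarray:
    """Analytic gradient of H: component m is ``-2 sum_k eps_k v_{m,k}``."""
    V = _central_vectors(cvset)
    h = np.asarray(h, dtype=float)
    eps = h - np.asarray(weights, dtype=float) @ V
    return -2.0 * (V @ eps)


def _solve_exact(V: np.ndarray, h: np.ndarray, nonneg: bool) -> np.ndarray:
    if nonneg:
        from scipy.optimize import nnls

        w, _ = nnls(V.T, h)
        return w
    w, *_ = np.linalg.lstsq(V.T, h, rcond=None)
    return w


def solve_weights(
    h,
    cvset,
    learning_rate: float = 0.1,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    nonneg: bool = False,
    solver: str = "gradient",
    record_history: bool = False,
) -> AdmixtureFit:
    """Find the weights minimizing the error power H for one distribution.

    Steepest descent starts at the all-zero weights, so J decreases from 1
    and never exceeds it.  H is non-increasing across accepted steps.  For a
    positive-definite Gram matrix the search stops once the certified
    optimality gap ``|grad|^2 / (4 lambda_min)`` falls below
    ``max(tol, 1e-9) * H``; otherwise (rank-deficient or constrained) it
    stops when the relative improvement of H drops below ``tol``.
    ``max_iter`` bounds the iterations either way and ``converged`` records
    which exit was taken.  With ``nonneg=True`` the weights are clipped at
    zero after every step (projected gradient; the exact path uses NNLS).
    """
    V = _central_vectors(cvset)
    h = np.asarray(h, dtype=float)
    if h.shape != (V.shape[1],):
        raise ValueError(f"h must have length D={V.shape[1]}")
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(h))):
        raise ValueError("non-finite values in inputs")

    hh = float(h @ h)
    if solver == "exact":
        a = _solve_exact(V, h, nonneg)
        eps, H, J = error_terms(h, V, a)
        return AdmixtureFit(a, eps, H, J, iterations=0, converged=True)
    if solver != "gradient":
        raise ValueError(f"unknown solver: {solver!r}")

    G = V @ V.T
    b = V @ h
    scale = float(np.linalg.norm(G, 2))
    lr = learning_rate / scale if scale > 0 else learning_rate
    # smallest Gram eigenvalue certifies the optimality gap of a quadratic:
    # H - H_opt <= |grad|^2 / (4 lambda_min)
    lam_min = float(np.linalg.eigvalsh(G)[0]) if scale > 0 else 0.0
    gap_rtol = max(tol, 1e-9)
    certifiable = lam_min > 1e-12 * scale and not nonneg
    a = np.zeros(V.shape[0])
    H = hh  # H at the all-zero start
    hist = [H] if record_history else None
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        g = 2.0 * (G @ a - b)
        if H <= 1e-14 * hh:  # numerically exact representation
            converged = True
            break
        if certifiable and (g @ g) / (4.0 * lam_min) < gap_rtol * H:
            converged = True
            break
        accepted = False
        while lr > 1e-300:
            a_new = a - lr * g
            if nonneg:
                np.clip(a_new, 0.0, None, out=a_new)
            H_new = hh - 2.0 * (a_new @ b) + a_new @ (G @ a_new)
            if H_new <= H:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            converged = True
            break
        improvement = H - H_new
        a, H = a_new, H_new
        if hist is not None:
            hist.append(H)
        lr *= 1.2
        if not certifiable and improvement < tol * max(H, np.finfo(float).tiny):
            converged = True
            break
    H = max(H, 0.0)
    eps = h - a @ V
    J = H / hh if hh > 0 else np.nan
    if hh == 0:
        raise ValueError("normalized error J undefined for an all-zero target")
    return AdmixtureFit(
        weights=a,
        error_vector=eps,
        error_power=H,
        normalized_error=float(J),
        iterations=it,
        converged=converged,
        history=np.asarray(hist) if hist is not None else None,
    )


def fit_all(
    freq: Union[FrequencyMatrix, pd.DataFrame, np.ndarray],
    cvset,
    **solver_kwargs,
) -> tuple[pd.DataFrame, float]:
    """Fit every usable population and tabulate weights, H and J.

    Returns a DataFrame (one row per population: the N weights, ``H``,
    ``J``, ``iterations``, ``converged``) and the mean J over successful
    fits.  A failing population is marked rather than aborting the batch.
    """
    V = _central_vectors(cvset)
    if isinstance(freq, FrequencyMatrix):
        values = freq.usable_values()
    elif isinstance(freq, pd.DataFrame):
        values = freq
    else:
        arr = np.asarray(freq, dtype=float)
        values = pd.DataFrame(arr, index=[f"pop{i}" for i in range(len(arr))])
    rows = {}
    for pop, h in values.iterrows():
        try:
            fit = solve_weights(h.to_numpy(dtype=float), V, **solver_kwargs)
            rows[pop] = np.concatenate(
                [
                    fit.weights,
                    [
                        fit.error_power,
                        fit.normalized_error,
                        fit.iterations,
                        float(fit.converged),
                    ],
                ]
            )
        except ValueError:
            rows[pop] = np.full(V.shape[0] + 4, np.nan)
    cols = [f"cv{i + 1}" for i in range(V.shape[0])] + [
        "H",
        "J",
        "iterations",
        "converged",
    ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.index.name = "population_id"
    mean_j = float(table["J"].mean())
    return table, mean_j


class AdmixtureModel(TransformerMixin, BaseEstimator):
    """scikit-learn transformer mapping frequency vectors to CV weights.

    The central vectors act like the components of a decomposition: ``fit``
    stores them (either given directly or taken from a fitted
    :class:`~hgadmix.soc.SelfOrganizingCloud`), ``transform`` returns the
    optimal weight matrix for the rows of X, and ``inverse_transform``
    rebuilds the modeled distributions.

    Parameters
    ----------
    central_vectors : array-like of shape (N, D), SelfOrganizingCloud, or None
        If None, an internal SelfOrganizingCloud is fit on the training data
        and its centers are used.
    solver : {"gradient", "exact"}, default="gradient"
    learning_rate, tol, max_iter, nonneg
        Passed to :func:`solve_weights`.
    random_state : int or None
        Seed for the internal clusterer when ``central_vectors`` is None.

    Attributes
    ----------
    components_ : ndarray of shape (N, D)
        The central vectors.
    weights_, error_power_, normalized_error_ : training-set fit results.
    mean_normalized_error_ : float
    """

    def __init__(
        self,
        central_vectors=None,
        solver: str = "gradient",
        learning_rate: float = 0.1,
        tol: float = 1e-10,
        max_iter: int = 100_000,
        nonneg: bool = False,
        random_state: Optional[int] = None,
    ):
        self.central_vectors = central_vectors
        self.solver = solver
        self.learning_rate = learning_rate
        self.tol = tol
        self.max_iter = max_iter
        self.nonneg = nonneg
        self.random_state = random_state

    def _solver_kwargs(self) -> dict:
        return dict(
            solver=self.solver,
            learning_rate=self.learning_rate,
            tol=self.tol,
            max_iter=self.max_iter,
            nonneg=self.nonneg,
        )

    def fit(self, X, y=None):
        if self.central_vectors is None:
            soc = SelfOrganizingCloud(random_state=self.random_state).fit(X)
            self.components_ = np.asarray(soc.cluster_centers_, dtype=float)
            self.soc_ = soc
        else:
            self.components_ = _central_vectors(self.central_vectors)
        table, mean_j = fit_all(X, self.components_, **self._solver_kwargs())
        self.weights_ = table.iloc[:, : self.components_.shape[0]].to_numpy()
        self.error_power_ = table["H"].to_numpy()
        self.normalized_error_ = table["J"].to_numpy()
        self.fit_table_ = table
        self.mean_normalized_error_ = mean_j
        self.n_features_in_ = self.components_.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        table, _ = fit_all(X, self.components_, **self._solver_kwargs())
        return table.iloc[:, : self.components_.shape[0]].to_numpy()

    def inverse_transform(self, W) -> np.ndarray:
        check_is_fitted(self, "components_")
        return np.asarray(W, dtype=float) @ self.components_
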