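"""Soft-margin SVM dual solver over a precomputed Gram matrix.

The classifier is trained by solving the dual quadratic program

    min_a  1/2 sum_ij y_i y_j K(x_i, x_j) a_i a_j  -  sum_j a_j
    s.t.   sum_i y_i a_i = 0,   0 <= a_i <= C,

with an SMO-style working-set method: at each step a maximal-violating
pair is chosen (first index by steepest feasible gradient, second by the
second-order gain heuristic), the two multipliers are updated analytically
and the cached gradient is refreshed with the two affected Gram rows.
Convergence is declared when the maximal KKT violation drops below
``kkt_tol``.

The offset b is recovered by averaging ``y_j - sum_i y_i a_i K_ij`` over
the unbounded support vectors (0 < a_j < C); if none exist it falls back
to the midpoint of the feasible interval implied by the bounded points.

Decisions are ``g(x) = sum_i a_i y_i K(x_i, x) + b`` and labels
``sign(g(x))`` with the exact tie g(x) = 0 mapped to +1 (the positive,
nodule class — the recall-favoring choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelParams

__all__ = [
    "SVMModel",
    "ConvergenceError",
    "train_svm",
    "compute_offset",
    "decision_values",
    "predict",
]

_TAU = 1e-12
# fraction of C below which a multiplier counts as zero / above C*(1-...) as bounded
_SUPPORT_EPS = 1e-8


class ConvergenceError(RuntimeError):
    """SMO did not reach ``kkt_tol`` within ``max_iter``; carries the best iterate."""

    def __init__(self, message: str, model: "SVMModel | None" = None):
        super().__init__(message)
        self.model = model


@dataclass
class SVMModel:
    """Dual solution of the soft-margin SVM.

    ``alpha`` are the Lagrange multipliers (length l), ``b`` the offset,
    ``support_indices`` the indices with alpha > 1e-8*C.  ``y`` is kept so
    the decision function can be evaluated from a training-vs-test Gram
    matrix alone.
    """

    alpha: np.ndarray
    b: float
    support_indices: np.ndarray
    C: float
    y: np.ndarray
    dual_objective: float
    n_iter: int
    converged: bool = True
    kernel_params: KernelParams | None = None
    X_train: np.ndarray | None = None


def train_svm(
    K,
    y,
    C: float,
    kkt_tol: float = 1e-3,
    max_iter: int | None = None,
    kernel_params: KernelParams | None = None,
) -> SVMModel:
    """Solve the dual SVM on a precomputed self-Gram matrix.

    Parameters
    ----------
    K : (l, l) array
        Symmetric PSD kernel matrix of the training points.
    y : (l,) array of -1/+1
        Class labels; both classes must be present.
    C : float
        Regularization (box) constant, > 0.
    kkt_tol : float
        Stop when the maximal KKT violation is below this.
    max_iter : int, optional
        Cap on pair updates; defaults to max(10 * l**2, 2000).

    Raises
    ------
    ConvergenceError
        If ``max_iter`` is exhausted; the exception carries the best
        iterate as ``.model``.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    l = y.shape[0]
    if K.shape != (l, l):
        raise ValueError(f"Gram matrix shape {K.shape} does not match {l} labels")
    if not C > 0:
        raise ValueError(f"C must be > 0, got {C}")
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be -1 or +1")
    if np.all(y == y[0]):
        raise ValueError("training data contains a single class")
    if max_iter is None:
        max_iter = max(10 * l * l, 2000)

    yf = y.astype(float)
    Q = np.outer(yf, yf) * K
    QD = np.diag(K).copy()
    alpha = np.zeros(l)
    G = -np.ones(l)  # gradient of the dual objective at alpha
    pos = yf > 0

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        up = np.where(pos, alpha < C, alpha > 0)
        low = np.where(pos, alpha > 0, alpha < C)
        if not up.any() or not low.any():
            converged = True
            break
        f = -yf * G  # -y_t * grad_t; max over I_up vs min over I_low
        f_up = np.where(up, f, -np.inf)
        i = int(np.argmax(f_up))
        Gmax = f_up[i]
        Gmin = np.min(np.where(low, f, np.inf))
        if Gmax - Gmin < kkt_tol:
            converged = True
            break

        # second-order heuristic for j among violating members of I_low
        bvec = Gmax - f
        valid = low & (bvec > 0)
        Ki = K[i]
        avec = QD[i] + QD - 2.0 * Ki
        avec = np.where(avec > 0, avec, _TAU)
        gain = np.where(valid, bvec * bvec / avec, -np.inf)
        j = int(np.argmax(gain))
        if not valid[j]:
            converged = True
            break

        ai_old, aj_old = alpha[i], alpha[j]
        if yf[i] != yf[j]:
            quad = QD[i] + QD[j] + 2.0 * Q[i, j]
            if quad <= 0:
                quad = _TAU
            delta = (-G[i] - G[j]) / quad
            diff = ai_old - aj_old
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = diff
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            quad = QD[i] + QD[j] - 2.0 * Q[i, j]
            if quad <= 0:
                quad = _TAU
            delta = (G[i] - G[j]) / quad
            s = ai_old + aj_old
            alpha[i] -= delta
            alpha[j] += delta
            if s > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = s - C
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = s - C
            else:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = s
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = s

        d_i = alpha[i] - ai_old
        d_j = alpha[j] - aj_old
        if d_i == 0.0 and d_j == 0.0:
            converged = True  # numerically stuck at the optimum
            break
        G += Q[:, i] * d_i + Q[:, j] * d_j

    np.clip(alpha, 0.0, C, out=alpha)
    b = compute_offset(alpha, y, K, C)
    support = np.flatnonzero(alpha > _SUPPORT_EPS * C)
    dual_obj = float(0.5 * alpha @ (Q @ alpha) - alpha.sum())
    model = SVMModel(
        alpha=alpha,
        b=b,
        support_indices=support,
        C=C,
        y=y,
        dual_objective=dual_obj,
        n_iter=it,
        converged=converged,
        kernel_params=kernel_params,
    )
    if not converged:
        raise ConvergenceError(
            f"SMO did not converge within {max_iter} pair updates "
            f"(kkt_tol={kkt_tol})",
            model=model,
        )
    return model


def compute_offset(alpha, y, K, C: float) -> float:
    """Recover the decision-function offset b from a dual solution.

    Averages ``y_j - sum_i y_i a_i K_ij`` over unbounded support vectors;
    with none available, returns the midpoint of the feasible interval for
    b implied by the KKT conditions of the bounded points.
    """
    alpha = np.asarray(alpha, dtype=float).ravel()
    y = np.asarray(y).astype(float).ravel()
    K = np.asarray(K, dtype=float)
    s = (alpha * y) @ K  # margin contributions without offset
    lo_a = _SUPPORT_EPS * C
    hi_a = C * (1.0 - _SUPPORT_EPS)
    free = (alpha > lo_a) & (alpha < hi_a)
    if free.any():
        return float(np.mean(y[free] - s[free]))
    # bounded-only fallback: y_j (s_j + b) >= 1 at alpha=0, <= 1 at alpha=C
    at_zero = alpha <= lo_a
    at_C = alpha >= hi_a
    pos = y > 0
    lower = np.concatenate([(1.0 - s)[pos & at_zero], (-1.0 - s)[~pos & at_C]])
    upper = np.concatenate([(1.0 - s)[pos & at_C], (-1.0 - s)[~pos & at_zero]])
    if lower.size == 0 and upper.size == 0:
        raise ValueError("cannot determine offset: no support-vector constraints")
    if lower.size == 0:
        return float(np.min(upper))
    if upper.size == 0:
        return float(np.max(lower))
    return float(0.5 * (np.max(lower) + np.min(upper)))


def decision_values(model: SVMModel, K_test) -> np.ndarray:
    """Decision values g(x) = sum_i a_i y_i K(x_i, x) + b for each test column.

    ``K_test`` has shape (l_train, n_test): rows are training points,
    columns the points to score.
    """
    K_test = np.atleast_2d(np.asarray(K_test, dtype=float))
    l = model.alpha.shape[0]
    if K_test.shape[0] != l:
        raise ValueError(
            f"K_test has {K_test.shape[0]} rows but the model was trained on {l} points"
        )
    return (model.alpha * model.y) @ K_test + model.b


def predict(model: SVMModel, K_test) -> np.ndarray:
    """Class labels sign(g(x)), with the exact tie g(x)=0 mapped to +1."""
    g = decision_values(model, K_test)
    return np.where(g >= 0, 1, -1)
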