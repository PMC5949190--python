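"""Basic and mixed (multiple) kernels for SVM classification.

The working kernel throughout the package is the two-kernel convex mix

    K(x, x') = m * K_poly(x, x'; d) + (1 - m) * K_rbf(x, x'; g),

with polynomial kernel ``(x . x' + 1)**d`` and Gaussian RBF kernel
``exp(-||x - x'||**2 / (2 g**2))``.  A convex combination of kernels is
itself a kernel (every Gram matrix it produces is positive semidefinite),
which :func:`check_psd` makes executable.

Two conventions exist in the wild for the RBF parameter: a *width* ``g``
appearing as ``1 / (2 g**2)``, and a libsvm-style *gamma* multiplying the
squared distance directly.  Both are supported via
``KernelParams.rbf_param_convention``; the conversion is
``gamma = 1 / (2 g**2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "poly_kernel",
    "rbf_kernel",
    "mixed_kernel",
    "combine_kernels",
    "gram_matrix",
    "check_psd",
]

_CONVENTIONS = ("width", "gamma")


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the mixed polynomial + RBF kernel.

    Parameters
    ----------
    m : float
        Mixing weight of the polynomial kernel, in [0, 1].  The optimizer
        searches the open interval; the boundary values 0 and 1 collapse
        the mix onto a single kernel and are allowed when requested
        explicitly.
    d : int
        Polynomial order, >= 1 (the hyperparameter search enumerates
        d in {2, 3}).
    g : float
        RBF width (or gamma, depending on ``rbf_param_convention``), > 0.
    rbf_param_convention : {"width", "gamma"}
        Interpretation of ``g``: ``"width"`` uses exp(-r^2 / (2 g^2)),
        ``"gamma"`` uses exp(-g * r^2).
    """

    m: float
    d: int
    g: float
    rbf_param_convention: str = "width"

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0):
            raise ValueError(f"mixing weight m must be in [0, 1], got {self.m}")
        if int(self.d) != self.d or self.d < 1:
            raise ValueError(f"polynomial order d must be an integer >= 1, got {self.d}")
        if not self.g > 0:
            raise ValueError(f"RBF parameter g must be > 0, got {self.g}")
        if self.rbf_param_convention not in _CONVENTIONS:
            raise ValueError(
                f"rbf_param_convention must be one of {_CONVENTIONS}, "
                f"got {self.rbf_param_convention!r}"
            )

    @property
    def gamma(self) -> float:
        """RBF coefficient on the squared distance, whatever the convention."""
        if self.rbf_param_convention == "gamma":
            return self.g
        return 1.0 / (2.0 * self.g**2)


def _as_vectors(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"vectors have mismatched dimensions {x.shape} vs {y.shape}")
    return x, y


def poly_kernel(x, y, d: int) -> float:
    """Polynomial kernel (x . y + 1)**d."""
    if int(d) != d or d < 1:
        raise ValueError(f"polynomial order d must be an integer >= 1, got {d}")
    x, y = _as_vectors(x, y)
    return float((x @ y + 1.0) ** d)


def rbf_kernel(x, y, g: float, convention: str = "width") -> float:
    """Gaussian RBF kernel; value in (0, 1], equal to 1 iff x == y."""
    if not g > 0:
        raise ValueError(f"RBF parameter g must be > 0, got {g}")
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown RBF convention {convention!r}")
    x, y = _as_vectors(x, y)
    sq = float(np.sum((x - y) ** 2))
    gamma = g if convention == "gamma" else 1.0 / (2.0 * g**2)
    return float(np.exp(-gamma * sq))


def mixed_kernel(x, y, p: KernelParams) -> float:
    """Convex mix m*K_poly + (1-m)*K_rbf; linear in m by construction."""
    kp = poly_kernel(x, y, p.d)
    kr = rbf_kernel(x, y, p.g, convention=p.rbf_param_convention)
    return p.m * kp + (1.0 - p.m) * kr


def combine_kernels(values, weights, tol: float = 1e-9) -> float:
    """Convex combination of U kernel evaluations.

    ``weights`` must lie in (0, 1] and sum to 1 within ``tol``; the result
    is then a valid kernel evaluation whenever the inputs are.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape or values.ndim != 1:
        raise ValueError("values and weights must be 1-D sequences of equal length")
    if values.size == 0:
        raise ValueError("at least one kernel evaluation is required")
    if np.any(weights <= 0) or np.any(weights > 1):
        raise ValueError("each mixing weight must lie in (0, 1]")
    total = float(weights.sum())
    if abs(total - 1.0) > tol:
        raise ValueError(f"mixing weights must sum to 1 (got {total})")
    return float(values @ weights)


def gram_matrix(A, B, p: KernelParams) -> np.ndarray:
    """Mixed-kernel Gram matrix between row sets A (n x N) and B (m x N).

    Entry (i, j) is ``mixed_kernel(A[i], B[j], p)``.  When ``A is B`` the
    result is symmetric and positive semidefinite up to floating point.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature dimensions differ: A has {A.shape[1]}, B has {B.shape[1]}"
        )
    dot = A @ B.T
    poly = (dot + 1.0) ** p.d
    sq = (
        np.sum(A * A, axis=1)[:, None]
        - 2.0 * dot
        + np.sum(B * B, axis=1)[None, :]
    )
    np.maximum(sq, 0.0, out=sq)
    rbf = np.exp(-p.gamma * sq)
    return p.m * poly + (1.0 - p.m) * rbf


def check_psd(K, tol: float = 1e-8) -> tuple[bool, float]:
    """Check positive semidefiniteness of a symmetric matrix.

    Returns ``(is_psd, min_eigenvalue)`` where ``is_psd`` is true iff the
    smallest eigenvalue is >= -tol.  ``tol`` absorbs the slightly negative
    eigenvalues that floating-point Gram matrices legitimately produce.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K must be square, got shape {K.shape}")
    if K.size and np.max(np.abs(K - K.T)) > max(tol, 1e-10) * max(1.0, np.max(np.abs(K))):
        raise ValueError("K must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (K + K.T))
    min_eig = float(w[0])
    return min_eig >= -tol, min_eig
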