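"""Exhaustive grid search baseline over (C, g, m, d).

Evaluates the same cross-validated fitness the swarm uses at every grid
point and returns the maximum.  Ties are broken toward the smaller C,
then g, then m, then d.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .data import FeatureDataset
from .fitness import HyperParams, cv_fitness
from .kernels import KernelParams
from .svm import ConvergenceError

__all__ = ["GridResult", "default_grid", "grid_search"]


def default_grid() -> dict[str, list[float]]:
    """Powers-of-two axes for C and g, 0.1-step weights, d in {2, 3}."""
    return {
        "C": [float(2.0**e) for e in range(-1, 8)],
        "g": [float(2.0**e) for e in range(-3, 6)],
        "m": [round(0.1 * i, 1) for i in range(1, 10)],
        "d": [2, 3],
    }


@dataclass
class GridResult:
    best_params: HyperParams
    best_fitness: float
    table: pd.DataFrame

    @property
    def best_d(self) -> int:
        return self.best_params.kernel_params.d


def grid_search(
    data: FeatureDataset,
    grids: dict | None = None,
    k: int = 5,
    seed: int = 0,
    rbf_param_convention: str = "width",
) -> GridResult:
    """Evaluate cv_fitness at every grid point and return the maximum.

    ``grids`` maps 'C', 'g', 'm', 'd' to value lists (defaults from
    :func:`default_grid`); the d grid must be a subset of {2, 3}.  The
    returned table has one row per grid point in evaluation order.
    """
    grids = dict(default_grid() if grids is None else grids)
    for key in ("C", "g", "m", "d"):
        if key not in grids or len(grids[key]) == 0:
            raise ValueError(f"grid for {key!r} must be a nonempty value list")
    d_vals = sorted(int(d) for d in grids["d"])
    if not set(d_vals) <= {2, 3}:
        raise ValueError(f"d grid must be a subset of {{2, 3}}, got {d_vals}")

    rows = []
    best_hp: HyperParams | None = None
    best_fit = -np.inf
    # ascending iteration + strict improvement implements the tie-break
    # (smaller C, then g, then m, then d)
    for C, g, m, d in product(
        sorted(float(c) for c in grids["C"]),
        sorted(float(v) for v in grids["g"]),
        sorted(float(v) for v in grids["m"]),
        d_vals,
    ):
        hp = HyperParams(
            C=C,
            kernel_params=KernelParams(
                m=m, d=d, g=g, rbf_param_convention=rbf_param_convention
            ),
        )
        try:
            fit = cv_fitness(data, hp, k, seed)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"solver failed at grid point C={C}, g={g}, m={m}, d={d}: {err}",
                model=err.model,
            ) from err
        rows.append({"C": C, "g": g, "m": m, "d": d, "fitness": fit})
        if fit > best_fit:
            best_fit = fit
            best_hp = hp
    table = pd.DataFrame(rows)
    assert best_hp is not None
    return GridResult(best_params=best_hp, best_fitness=float(best_fit), table=table)
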