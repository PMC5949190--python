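"""Synthetic imbalanced two-class feature tables.

The clinical study this package targets classifies 270 candidate lung-CT
regions (80 true nodules vs 190 false positives, split 170 train / 100
test); that feature table is not public, so these generators emulate its
shape: a minority positive class, a majority negative class, controllable
separability and — for the ring generator — class structure no linear or
low-order polynomial boundary can capture, which is exactly the regime
where the RBF-dominant mixed kernel earns its keep.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import numpy as np

from .data import FeatureDataset

__all__ = [
    "generate_gaussian_classes",
    "generate_ring_classes",
    "split_train_test",
]

# study-protocol constants: 80 nodules vs 190 false positives, 170/100 split
DEFAULT_N_POS = 80
DEFAULT_N_NEG = 190
DEFAULT_N_TRAIN = 170


def generate_gaussian_classes(
    n_pos: int = DEFAULT_N_POS,
    n_neg: int = DEFAULT_N_NEG,
    dims: int = 10,
    separation: float = 2.5,
    seed: int = 0,
) -> FeatureDataset:
    """Two spherical unit-variance Gaussians split along the first axis.

    Class means sit at +/- separation/2 on axis 0 (separation measured in
    pooled-standard-deviation units), so ``separation=0`` gives chance-
    level structure and ``separation >> 1`` a nearly separable problem.
    Positives (+1) are the minority class by default.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one sample")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_pos + n_neg, dims))
    X[:n_pos, 0] += separation / 2.0
    X[n_pos:, 0] -= separation / 2.0
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    return FeatureDataset(X, y)


def generate_ring_classes(
    n_pos: int = DEFAULT_N_POS,
    n_neg: int = DEFAULT_N_NEG,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> FeatureDataset:
    """Inner disc (+1) versus surrounding annulus (-1) in 2-D.

    Positives fill the unit disc, negatives an annulus with radii in
    [1.4, 2.2]; Gaussian noise with standard deviation ``noise_sd`` is
    added to each radius.  With ``noise_sd=0`` the classes are radially
    disjoint (0.4 gap); the default 0.2 leaves a small overlap.  The
    boundary is a circle, so the fixture is linearly inseparable by
    construction.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one sample")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # sqrt for uniform areal density in the disc / annulus
    u = rng.uniform(0.0, 1.0, size=n)
    r = np.empty(n)
    r[:n_pos] = np.sqrt(u[:n_pos])  # disc of radius 1
    r[n_pos:] = np.sqrt(1.4**2 + u[n_pos:] * (2.2**2 - 1.4**2))
    r = r + noise_sd * rng.standard_normal(n)
    X = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    return FeatureDataset(X, y)


def split_train_test(
    data: FeatureDataset,
    n_train: int = DEFAULT_N_TRAIN,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[FeatureDataset, FeatureDataset]:
    """Disjoint, exhaustive, seeded train/test split.

    With ``stratify`` the class proportions of the training set match the
    full table within one sample (largest-remainder allocation).
    """
    total = len(data)
    if not 0 < n_train < total:
        raise ValueError(f"n_train must be in (0, {total}), got {n_train}")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[np.ndarray] = []
        labels = (1, -1)
        quotas = {}
        exact = {lab: n_train * np.sum(data.y == lab) / total for lab in labels}
        for lab in labels:
            quotas[lab] = int(np.floor(exact[lab]))
        # distribute the remainder by largest fractional part
        short = n_train - sum(quotas.values())
        for lab in sorted(labels, key=lambda L: exact[L] - quotas[L], reverse=True):
            if short <= 0:
                break
            quotas[lab] += 1
            short -= 1
        for lab in labels:
            idx = rng.permutation(np.flatnonzero(data.y == lab))
            train_idx.append(idx[: quotas[lab]])
        tr = np.sort(np.concatenate(train_idx))
    else:
        tr = np.sort(rng.permutation(total)[:n_train])
    te = np.setdiff1d(np.arange(total), tr)
    return data.subset(tr), data.subset(te)
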