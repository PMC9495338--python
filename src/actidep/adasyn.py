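"""ADASYN adaptive synthetic oversampling for binary class imbalance.

ADASYN generates synthetic minority examples by interpolating each minority
point toward one of its minority K-neighbors, with the number of synthetics
per point weighted by how many *majority* points surround it — harder border
regions receive more synthetic support.  The procedure:

  d  = ms / ml                       imbalance degree (minority / majority)
  G  = (ml - ms) * beta              total synthetics (beta=1: full balance)
  r_i = Delta_i / K                  majority share of x_i's K neighborhood
  r^_i = r_i / sum(r)                density distribution (sums to 1)
  g_i = r^_i * G                     per-point synthetic budget
  s  = x_i + (x_z - x_i) * lambda    lambda ~ U[0,1], x_z a minority
                                     member of x_i's K neighborhood

If the imbalance degree already meets the tolerated threshold ``d_th``, the
data is returned unchanged.  Edge conventions (documented, seed-stable):
per-point budgets are integerized by largest-remainder apportionment so they
sum exactly to G; when every minority neighborhood is purely minority
(sum r = 0, making r^ a 0/0), the budget is spread uniformly; a minority
point whose neighborhood holds no minority partner interpolates toward the
globally nearest minority point instead.

Original rows are preserved unchanged and in order, followed by synthetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass(frozen=True)
class AdasynConfig:
    """K neighbors, desired balance level beta, tolerated imbalance d_th."""

    K: int = 5
    beta: float = 1.0
    d_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.d_threshold <= 1.0:
            raise ValueError("d_threshold must be in (0, 1]")


@dataclass(frozen=True)
class AdasynDiagnostics:
    """Intermediate quantities of one resampling run, for auditability."""

    d: float
    G: int
    r: np.ndarray = field(repr=False)
    r_hat: np.ndarray = field(repr=False)
    g: np.ndarray = field(repr=False)
    minority_label: int = 1

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "G": self.G,
            "r": self.r.tolist(),
            "r_hat": self.r_hat.tolist(),
            "g": self.g.tolist(),
            "minority_label": self.minority_label,
        }


def _class_split(y: np.ndarray) -> tuple[int, int]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"ADASYN requires exactly two classes, got {classes.tolist()}")
    order = np.argsort(counts, kind="stable")  # minority first; ties -> smaller label
    return int(classes[order[0]]), int(classes[order[1]])


def imbalance_degree(y: np.ndarray) -> float:
    """d = minority count / majority count, in (0, 1]."""
    y = np.asarray(y)
    minority, majority = _class_split(y)
    return float(np.sum(y == minority) / np.sum(y == majority))


def neighbor_ratios(X: np.ndarray, y: np.ndarray, K: int) -> np.ndarray:
    """Per-minority-point majority share r_i = Delta_i / K of the K nearest
    neighbors (Euclidean, query point excluded)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if K >= len(X):
        raise ValueError(f"K={K} must be < number of rows {len(X)}")
    minority, _ = _class_split(y)
    nn = NearestNeighbors(n_neighbors=K + 1).fit(X)
    minority_idx = np.flatnonzero(y == minority)
    _, idx = nn.kneighbors(X[minority_idx])
    r = np.empty(len(minority_idx))
    for row, (qi, neigh) in enumerate(zip(minority_idx, idx)):
        neigh = neigh[neigh != qi][:K]
        r[row] = np.sum(y[neigh] != minority) / K
    return r


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integerize ``weights * total`` (weights sum to 1) so the result sums to
    ``total`` exactly; remainders are granted largest-first, ties by index."""
    quota = np.asarray(weights, dtype=np.float64) * total
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def fit_resample(
    X: np.ndarray, y: np.ndarray, config: AdasynConfig = AdasynConfig()
) -> tuple[np.ndarray, np.ndarray, AdasynDiagnostics]:
    """Oversample the minority class; returns (X', y', diagnostics).

    With ``beta=1`` the minority count after resampling equals the majority
    count.  Already-tolerable imbalance (d >= d_threshold) short-circuits to
    the unchanged input with G = 0.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    minority, majority = _class_split(y)
    ms, ml = int(np.sum(y == minority)), int(np.sum(y == majority))
    d = ms / ml
    if d >= config.d_threshold:
        diag = AdasynDiagnostics(
            d=d,
            G=0,
            r=np.zeros(ms),
            r_hat=np.zeros(ms),
            g=np.zeros(ms, dtype=np.int64),
            minority_label=minority,
        )
        return X.copy(), y.copy(), diag

    # Sign-corrected total: the printed form (ms - ml) * beta would be negative.
    G = int(round((ml - ms) * config.beta))
    r = neighbor_ratios(X, y, config.K)
    if r.sum() > 0:
        r_hat = r / r.sum()
    else:  # all minority neighborhoods purely minority: spread G uniformly
        r_hat = np.full(ms, 1.0 / ms)
    g = largest_remainder(r_hat, G)

    minority_idx = np.flatnonzero(y == minority)
    Xmin = X[minority_idx]
    nn_all = NearestNeighbors(n_neighbors=config.K + 1).fit(X)
    _, neigh_all = nn_all.kneighbors(Xmin)
    # Global minority fallback partner for isolated points.
    nn_min = NearestNeighbors(n_neighbors=min(2, ms)).fit(Xmin)
    _, neigh_min = nn_min.kneighbors(Xmin)

    rng = np.random.default_rng(config.seed)
    synthetics: list[np.ndarray] = []
    for i, (qi, budget) in enumerate(zip(minority_idx, g)):
        if budget == 0:
            continue
        neigh = neigh_all[i][neigh_all[i] != qi][: config.K]
        partners = neigh[y[neigh] == minority]
        if len(partners) == 0:
            # nearest minority point other than x_i itself
            fallback = [j for j in neigh_min[i] if minority_idx[j] != qi]
            if not fallback:
                raise ValueError("cannot generate synthetics from a single minority point")
            partners = minority_idx[np.asarray(fallback[:1])]
        for _ in range(int(budget)):
            xz = X[rng.choice(partners)]
            lam = rng.random()
            synthetics.append(X[qi] + (xz - X[qi]) * lam)

    if synthetics:
        X_out = np.vstack([X, np.asarray(synthetics)])
        y_out = np.concatenate([y, np.full(len(synthetics), minority, dtype=y.dtype)])
    else:
        X_out, y_out = X.copy(), y.copy()
    diag = AdasynDiagnostics(d=d, G=G, r=r, r_hat=r_hat, g=g, minority_label=minority)
    return X_out, y_out, diag
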