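"""RBC subpopulation typing by PCA-guided robust clustering.

The chain mirrors the multi-step procedure used for the ovine panel:

1. z-score the 11 morphometric variables and eigen-decompose their
   correlation matrix; retain factors by the Kaiser rule (eigenvalue >= 1);
2. pick one representative variable per retained factor (largest absolute
   loading) — on well-structured data these are outline, roundness and
   elongation;
3. choose the cluster count k by a gap-type statistic whose reference is
   uniform draws from the data's axis-aligned bounding box (a published
   stand-in for the proprietary "aligned box criterion");
4. cluster the standardized representative variables by robust k-medians:
   L1 distances with coordinate-wise median centers, holding out points far
   from their cluster during iterations so outliers do not drag centers;
5. assign the held-out points to their nearest center without further
   iterations, dissolve clusters holding under a minimum share of cells
   into the nearest cluster, and name the final clusters ES1 (smallest mean
   outline), ES2 (largest) and ES3 (the rest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic import FEATURE_COLUMNS

__all__ = [
    "FactorModel",
    "SubpopulationModel",
    "standardize",
    "pca_kaiser",
    "select_representatives",
    "select_k",
    "robust_kmeans",
    "assign_outliers",
    "merge_small_clusters",
    "label_subpopulations",
    "type_cells",
]


class DegenerateFeatureError(ValueError):
    """A feature column is constant and cannot be standardized."""


def standardize(
    table: pd.DataFrame, columns: tuple[str, ...] = FEATURE_COLUMNS
) -> pd.DataFrame:
    """z-score the given columns (ddof=1); other columns pass through."""
    out = table.copy()
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not sd > 0:
            raise DegenerateFeatureError(f"column {col!r} is constant")
        out[col] = (x - x.mean()) / sd
    return out


@dataclass(frozen=True)
class FactorModel:
    """Correlation-matrix PCA summary with Kaiser retention."""

    eigenvalues: np.ndarray  # all p, descending
    loadings: pd.DataFrame  # p x retained, loadings = eigvec * sqrt(lambda)
    explained_pct: np.ndarray  # per retained factor
    cumulative_pct: np.ndarray
    n_retained: int
    representatives: tuple[str, ...]
    columns: tuple[str, ...]


#: Loadings within this distance of a factor's maximum |loading| are
#: practically equivalent anchors (such variables track the factor nearly
#: interchangeably); the earliest column in the fixed order wins.
REPRESENTATIVE_TIE_TOL = 0.05


def representatives_from_loadings(
    loadings: np.ndarray,
    columns: tuple[str, ...],
    tie_tol: float = REPRESENTATIVE_TIE_TOL,
) -> tuple[str, ...]:
    """One representative variable per factor column of a loadings matrix.

    The representative is the variable with the largest |loading|; loadings
    within ``tie_tol`` of that maximum count as tied, and ties resolve to
    the earliest variable in ``columns``.
    """
    load = np.asarray(loadings, dtype=float)
    return tuple(
        columns[int(np.argmax(np.abs(load[:, j]) >= np.abs(load[:, j]).max() - tie_tol))]
        for j in range(load.shape[1])
    )


def pca_kaiser(
    table: pd.DataFrame,
    columns: tuple[str, ...] = FEATURE_COLUMNS,
    tie_tol: float = REPRESENTATIVE_TIE_TOL,
) -> FactorModel:
    """PCA of the correlation matrix with inclusive Kaiser retention.

    Implemented as an SVD of the z-scored data matrix (eigenvalues are
    squared singular values over n-1).  Loadings are eigenvectors scaled by
    sqrt(eigenvalue), signs fixed so each factor's largest-magnitude loading
    is positive.  All factors with eigenvalue >= 1 are retained.

    Each factor's representative variable is the largest |loading|, with
    loadings within ``tie_tol`` of the maximum treated as tied and the tie
    broken by the fixed column order (``tie_tol=0`` gives a strict argmax).
    """
    Z = standardize(table, columns)[list(columns)].to_numpy(dtype=float)
    n, p = Z.shape
    if n <= p:
        raise ValueError(f"need more observations than variables ({n} <= {p})")
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    if eigenvalues[-1] < 1e-10:
        warnings.warn(
            "correlation matrix is rank deficient; proceeding with the "
            "pseudo-decomposition",
            RuntimeWarning,
            stacklevel=2,
        )
    n_retained = int((eigenvalues >= 1.0 - 1e-12).sum())
    load = Vt[:n_retained].T * np.sqrt(eigenvalues[:n_retained])
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    explained = eigenvalues[:n_retained] / p * 100.0
    loadings = pd.DataFrame(
        load,
        index=list(columns),
        columns=[f"factor{j + 1}" for j in range(n_retained)],
    )
    reps = representatives_from_loadings(load, columns, tie_tol)
    return FactorModel(
        eigenvalues=eigenvalues,
        loadings=loadings,
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
        n_retained=n_retained,
        representatives=reps,
        columns=tuple(columns),
    )


def select_representatives(fm: FactorModel) -> tuple[str, ...]:
    """One variable per retained factor: the largest |loading|, with
    near-ties (within :data:`REPRESENTATIVE_TIE_TOL`) broken by the fixed
    column order."""
    if fm.n_retained < 1:
        raise ValueError("no retained factors")
    return fm.representatives


@dataclass(frozen=True)
class SubpopulationModel:
    """Result of robust clustering in the representative-variable space."""

    k: int
    centers: np.ndarray  # k x d, in the clustering space
    labels: np.ndarray  # per point, 1..k; 0 = held out (strict pass)
    outlier_flags: np.ndarray  # bool, points held out by the strict pass
    objective: float  # summed L1 distance of labeled points to centers
    feature_names: tuple[str, ...] = ()
    es_names: tuple[str, ...] | None = None  # per cluster, after labeling

    @property
    def sizes(self) -> np.ndarray:
        return np.array([(self.labels == j + 1).sum() for j in range(self.k)])

    def es_labels(self) -> np.ndarray:
        if self.es_names is None:
            raise ValueError("run label_subpopulations first")
        names = np.array(self.es_names)
        if (self.labels == 0).any():
            raise ValueError("unassigned points; run assign_outliers first")
        return names[self.labels - 1]


def _l1_dists(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return np.abs(X[:, None, :] - centers[None, :, :]).sum(axis=2)


def _init_spread(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding under L1: subsequent seeds drawn with
    probability proportional to distance from the nearest existing seed."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d = _l1_dists(X, np.array(centers)).min(axis=1)
        total = d.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d / total)])
    return np.array(centers)


def _kmedians_once(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    strict_multiplier: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    centers = _init_spread(X, k, rng)
    labels = np.full(n, -1)
    held = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        dists = _l1_dists(X, centers)
        new_labels = dists.argmin(axis=1)
        own = dists[np.arange(n), new_labels]
        new_held = np.zeros(n, dtype=bool)
        if np.isfinite(strict_multiplier):
            for j in range(k):
                in_j = new_labels == j
                if not in_j.any():
                    continue
                med = np.median(own[in_j])
                if med > 0:
                    new_held[in_j] = own[in_j] > strict_multiplier * med
        for j in range(k):
            use = (new_labels == j) & ~new_held
            if use.any():
                centers[j] = np.median(X[use], axis=0)
            else:
                # re-seed a dead cluster from the farthest held-out point,
                # or the globally farthest point if none is held out
                pool = np.where(new_held)[0]
                if pool.size == 0:
                    pool = np.arange(n)
                centers[j] = X[pool[np.argmax(own[pool])]]
        if (new_labels == labels).all() and (new_held == held).all():
            break
        labels, held = new_labels, new_held
    dists = _l1_dists(X, centers)
    labels = dists.argmin(axis=1)
    own = dists[np.arange(n), labels]
    objective = float(own[~held].sum())
    return centers, labels, held, objective


def robust_kmeans(
    data: np.ndarray,
    k: int,
    seed: int,
    strict_multiplier: float = 3.0,
    n_init: int = 10,
    max_iter: int = 100,
    feature_names: tuple[str, ...] = (),
) -> SubpopulationModel:
    """Robust k-medians clustering under L1 distance.

    Centers are coordinate-wise medians (the L1 analogue of the mean).
    During iterations, points farther than ``strict_multiplier`` times the
    median within-cluster distance are held out so that tails do not drag
    the centers; they remain unlabeled (label 0) until
    :func:`assign_outliers`.  The best of ``n_init`` spread-seeded restarts
    (lowest retained-point objective) is returned.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("data must be finite")
    if k < 1 or k > X.shape[0]:
        raise ValueError("need 1 <= k <= n points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        result = _kmedians_once(X, k, rng, strict_multiplier, max_iter)
        if best is None or result[3] < best[3]:
            best = result
    centers, labels, held, objective = best
    out_labels = np.where(held, 0, labels + 1)
    return SubpopulationModel(
        k=k,
        centers=centers,
        labels=out_labels,
        outlier_flags=held,
        objective=objective,
        feature_names=tuple(feature_names),
    )


def assign_outliers(model: SubpopulationModel, data: np.ndarray) -> SubpopulationModel:
    """Zero-iteration pass: label every held-out point with its nearest
    center (L1); centers are not updated."""
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not model.outlier_flags.any():
        return model
    dists = _l1_dists(X, model.centers)
    nearest = dists.argmin(axis=1) + 1
    labels = np.where(model.labels == 0, nearest, model.labels)
    own = dists[np.arange(X.shape[0]), labels - 1]
    return replace(model, labels=labels, objective=float(own.sum()))


def merge_small_clusters(
    model: SubpopulationModel,
    data: np.ndarray,
    min_proportion: float = 0.05,
) -> SubpopulationModel:
    """Dissolve clusters holding fewer than ``min_proportion`` of the cells
    into the cluster with the nearest center, repeatedly, recomputing the
    absorbing cluster's median center after each merge."""
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if (model.labels == 0).any():
        raise ValueError("unassigned points; run assign_outliers first")
    labels0 = model.labels - 1
    centers = [c.copy() for c in model.centers]
    members = [list(np.where(labels0 == j)[0]) for j in range(model.k)]
    n = len(labels0)
    while len(members) > 1:
        sizes = np.array([len(m) for m in members])
        small = np.where(sizes < min_proportion * n)[0]
        if small.size == 0:
            break
        if small.size == len(members):
            raise ValueError("all clusters fall below the minimum proportion")
        j = small[np.argmin(sizes[small])]
        others = [i for i in range(len(members)) if i != j]
        cj = np.array(centers[j])
        target = min(
            others, key=lambda i: float(np.abs(np.array(centers[i]) - cj).sum())
        )
        members[target].extend(members[j])
        centers[target] = np.median(X[members[target]], axis=0)
        del members[j], centers[j]
    k = len(members)
    new_labels = np.empty(n, dtype=int)
    for j, idx in enumerate(members):
        new_labels[idx] = j + 1
    centers_arr = np.array(centers)
    own = _l1_dists(X, centers_arr)[np.arange(n), new_labels - 1]
    return replace(
        model,
        k=k,
        centers=centers_arr,
        labels=new_labels,
        objective=float(own.sum()),
        es_names=None,
    )


def select_k(
    data: np.ndarray,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    seed: int = 0,
    n_ref: int = 10,
    n_init: int = 4,
    strict_multiplier: float = np.inf,
) -> int:
    """Cluster-count selection by a gap-type statistic.

    For each candidate k the data are clustered by k-medians and the
    within-cluster dispersion W_k (canonical form: summed squared Euclidean
    distance about each cluster centroid) is compared to its expectation
    under ``n_ref`` uniform reference draws from the data's axis-aligned
    bounding box:

        gap(k) = mean_b log W_k(reference_b) - log W_k(data)

    and the k maximizing the gap is returned.  Deterministic given ``seed``.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    k_range = tuple(sorted(k_range))
    if not all(2 <= k <= 10 for k in k_range):
        raise ValueError("k_range must lie within [2, 10]")
    if X.shape[0] < 10 * max(k_range):
        raise ValueError("need at least 10 * max(k_range) points")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(n_ref)]

    def dispersion(Y: np.ndarray, k: int, s: int) -> float:
        m = robust_kmeans(
            Y, k, seed=s, strict_multiplier=strict_multiplier, n_init=n_init
        )
        m = assign_outliers(m, Y)
        w = 0.0
        for j in range(k):
            pts = Y[m.labels == j + 1]
            if len(pts):
                w += float(((pts - pts.mean(axis=0)) ** 2).sum())
        return w

    gaps = []
    for k in k_range:
        w = dispersion(X, k, int(rng.integers(2**31)))
        w_ref = [dispersion(R, k, int(rng.integers(2**31))) for R in refs]
        gaps.append(float(np.mean(np.log(w_ref)) - np.log(w)))
    return k_range[int(np.argmax(gaps))]


def label_subpopulations(
    model: SubpopulationModel, table: pd.DataFrame
) -> tuple[SubpopulationModel, pd.DataFrame]:
    """Name the clusters ES1/ES2/ES3 by mean cell outline.

    ES1 is the cluster with the smallest mean outline (smallest cells), ES2
    the largest, ES3 the remainder.  For k != 3 the clusters are named
    ES1..ESk by ascending mean outline, with a warning.  Also returns a
    cluster summary (size, share, and mean +- SD of outline, roundness and
    elongation) for consistency checking against the size/shape ordering.
    """
    if (model.labels == 0).any():
        raise ValueError("unassigned points; run assign_outliers first")
    if len(table) != len(model.labels):
        raise ValueError("table and model cover different cell sets")
    mean_outline = np.array(
        [
            table["outline"].to_numpy()[model.labels == j + 1].mean()
            for j in range(model.k)
        ]
    )
    order = np.argsort(mean_outline)  # ascending
    es_names = [""] * model.k
    if model.k == 3:
        es_names[order[0]] = "ES1"
        es_names[order[2]] = "ES2"
        es_names[order[1]] = "ES3"
    else:
        warnings.warn(
            f"k={model.k} != 3; naming clusters ES1..ES{model.k} by "
            "ascending mean outline",
            RuntimeWarning,
            stacklevel=2,
        )
        for rank, j in enumerate(order):
            es_names[j] = f"ES{rank + 1}"
    labeled = replace(model, es_names=tuple(es_names))

    rows = []
    n = len(table)
    for j in range(model.k):
        sel = model.labels == j + 1
        row = {"es": es_names[j], "n": int(sel.sum()),
               "pct": 100.0 * sel.sum() / n}
        for var in ("outline", "roundness", "elongation"):
            if var in table.columns:
                x = table[var].to_numpy()[sel]
                row[f"{var}_mean"] = float(x.mean())
                row[f"{var}_sd"] = float(x.std(ddof=1))
        rows.append(row)
    summary = (
        pd.DataFrame(rows).sort_values("es").reset_index(drop=True)
    )
    return labeled, summary


def type_cells(
    table: pd.DataFrame,
    seed: int,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    strict_multiplier: float = 3.0,
    min_proportion: float = 0.05,
    columns: tuple[str, ...] = FEATURE_COLUMNS,
    standardize_clustering: bool = False,
) -> tuple[SubpopulationModel, pd.DataFrame, FactorModel]:
    """Full typing chain on a per-cell feature table.

    standardize -> PCA/Kaiser -> representative variables -> gap-based k ->
    robust k-medians -> zero-iteration outlier assignment -> small-cluster
    merging -> ES naming.  Returns the final model, the cluster summary and
    the factor model.

    Clustering runs on the *raw* representative variables by default,
    matching the behaviour of classical k-means procedures that do not
    rescale inputs: the size representative then dominates the distance,
    which is exactly the axis separating the subpopulations.
    ``standardize_clustering=True`` switches to z-scored representatives.
    """
    fm = pca_kaiser(table, columns)
    reps = select_representatives(fm)
    source = standardize(table, columns) if standardize_clustering else table
    Z = source[list(reps)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    k = select_k(Z, k_range, seed=int(rng.integers(2**31)))
    model = robust_kmeans(
        Z,
        k,
        seed=int(rng.integers(2**31)),
        strict_multiplier=strict_multiplier,
        feature_names=reps,
    )
    model = assign_outliers(model, Z)
    model = merge_small_clusters(model, Z, min_proportion)
    model, summary = label_subpopulations(model, table)
    return model, summary, fm
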