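"""Subtype discovery on SUI profiles and classification of new samples.

Discovery uses non-smooth NMF (nsNMF): ``X ~ W S H`` with the smoothing
matrix ``S = (1 - theta) I + (theta / k) J`` interposed to promote sparse
factors, fit by multiplicative Kullback-Leibler updates.  Rank selection
surveys consensus matrices over a range of ranks via the cophenetic and
dispersion coefficients and mean silhouette widths.  Robustness is checked
with consensus k-means over resampled sample subsets.  New samples are
assigned with a nearest-shrunken-centroid (PAM) classifier after quantile
normalization onto the training distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold

from .normalize import pooled_reference_quantiles, quantile_normalize_to_reference

_EPS = 1e-12


# ---------------------------------------------------------------- nsNMF ----

@dataclass
class SubtypeSolution:
    rank: int
    W: np.ndarray  # features x k
    H: np.ndarray  # k x samples
    theta: float
    consensus: np.ndarray  # samples x samples, run-average connectivity
    labels: np.ndarray  # argmax of H per sample, 0-based
    divergence: float
    divergence_trace: np.ndarray = field(default=None, repr=False)
    converged: bool = True
    sample_ids: list[str] | None = None


def scale_features(sui: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature min-max scaling of SUI to [0, 1] for NMF.

    Constant features carry no clustering signal and are dropped (logged via
    warning).  Returns (scaled matrix, scaler table with min/max per kept
    feature) so the transform can be inverted.
    """
    lo = sui.min(axis=1)
    hi = sui.max(axis=1)
    keep = hi > lo
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} constant features before NMF")
    sub = sui.loc[keep]
    scaled = sub.sub(lo[keep], axis=0).div((hi - lo)[keep], axis=0)
    scaler = pd.DataFrame({"min": lo[keep], "max": hi[keep]})
    return scaled, scaler


def unscale_features(scaled: pd.DataFrame, scaler: pd.DataFrame) -> pd.DataFrame:
    rng = scaler["max"] - scaler["min"]
    return scaled.mul(rng, axis=0).add(scaler["min"], axis=0)


def _kl_divergence(X: np.ndarray, Y: np.ndarray) -> float:
    Y = np.maximum(Y, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(X > 0, X * np.log(X / Y), 0.0)
    return float((term - X + Y).sum())


def _smoothing_matrix(k: int, theta: float) -> np.ndarray:
    return (1.0 - theta) * np.eye(k) + (theta / k) * np.ones((k, k))


def _nsnmf_single(
    X: np.ndarray, k: int, theta: float, max_iter: int, tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    n_feat, n_samp = X.shape
    W = rng.uniform(0.1, 1.0, (n_feat, k))
    H = rng.uniform(0.1, 1.0, (k, n_samp))
    S = _smoothing_matrix(k, theta)
    trace = []
    prev = np.inf
    converged = False
    for it in range(max_iter):
        # update H with smoothing absorbed into W
        A = np.maximum(W @ S, _EPS)
        AH = np.maximum(A @ H, _EPS)
        H *= (A.T @ (X / AH)) / np.maximum(A.sum(axis=0)[:, None], _EPS)
        # update W with smoothing absorbed into H
        Bm = np.maximum(S @ H, _EPS)
        WB = np.maximum(W @ Bm, _EPS)
        W *= ((X / WB) @ Bm.T) / np.maximum(Bm.sum(axis=1)[None, :], _EPS)
        if it % 10 == 0 or it == max_iter - 1:
            div = _kl_divergence(X, W @ S @ H)
            trace.append(div)
            if prev - div < tol * max(prev, 1.0):
                converged = True
                break
            prev = div
    div = _kl_divergence(X, W @ S @ H)
    return W, H, div, np.asarray(trace), converged


def _connectivity(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


def nsnmf(
    X: pd.DataFrame | np.ndarray,
    k: int,
    theta: float = 0.5,
    n_runs: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> SubtypeSolution:
    """Best-of-``n_runs`` nsNMF factorization with a consensus matrix.

    Each run starts from a seeded random uniform initialization; the run
    with the lowest KL divergence is kept.  The consensus matrix is the
    run-average of sample connectivity matrices (samples co-assigned by the
    argmax of H).  Non-convergence at ``max_iter`` is accepted with a
    warning flag on the solution.
    """
    sample_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    if (Xa < 0).any():
        raise ValueError("NMF input must be nonnegative")
    if not (2 <= k < min(Xa.shape)):
        raise ValueError(f"rank {k} out of range for shape {Xa.shape}")
    rng = np.random.default_rng(seed)
    best = None
    consensus = np.zeros((Xa.shape[1], Xa.shape[1]))
    for _ in range(n_runs):
        W, H, div, trace, conv = _nsnmf_single(Xa, k, theta, max_iter, tol, rng)
        consensus += _connectivity(np.argmax(H, axis=0))
        if best is None or div < best[2]:
            best = (W, H, div, trace, conv)
    W, H, div, trace, conv = best
    if not conv:
        warnings.warn(f"nsNMF best run did not converge in {max_iter} iterations")
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    return SubtypeSolution(
        rank=k, W=W, H=H, theta=theta, consensus=consensus,
        labels=np.argmax(H, axis=0), divergence=div, divergence_trace=trace,
        converged=conv, sample_ids=sample_ids,
    )


# -------------------------------------------------------- rank selection ----

def _consensus_labels(C: np.ndarray, k: int) -> np.ndarray:
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def consensus_metrics(C: np.ndarray, k: int) -> dict[str, float]:
    """Cophenetic, dispersion and mean-silhouette metrics of a consensus matrix."""
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    Z = linkage(d, method="average")
    coph = cophenet(Z)
    if np.std(d) == 0 or np.std(coph) == 0:
        cophenetic = 1.0
    else:
        cophenetic = float(np.corrcoef(d, coph)[0, 1])
    dispersion = float(np.mean(4.0 * (C - 0.5) ** 2))
    labels = _consensus_labels(C, k)
    if len(set(labels)) < 2:
        sil = -1.0
    else:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    return {"cophenetic": cophenetic, "dispersion": dispersion, "silhouette": sil}


def rank_survey(
    X: pd.DataFrame | np.ndarray,
    ranks: range | list[int] = range(2, 11),
    n_runs: int = 50,
    theta: float = 0.5,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> pd.DataFrame:
    """Consensus metrics of nsNMF solutions over a range of ranks."""
    rows = []
    for i, k in enumerate(ranks):
        sol = nsnmf(
            X, k, theta=theta, n_runs=n_runs, max_iter=max_iter, tol=tol,
            seed=seed + 1000 * i,
        )
        m = consensus_metrics(sol.consensus, k)
        rows.append({"rank": k, **m, "divergence": sol.divergence})
    return pd.DataFrame(rows).set_index("rank")


def select_rank(survey: pd.DataFrame) -> int:
    """Pick the rank with maximal mean silhouette.

    Ties resolve to the largest cophenetic coefficient and then to the
    smallest rank (the most parsimonious equally-stable solution).
    """
    best = survey.sort_values(
        ["silhouette", "cophenetic"], ascending=False, kind="mergesort"
    )
    return int(best.index[0])


# ---------------------------------------------------- consensus k-means ----

def consensus_kmeans(
    X: pd.DataFrame | np.ndarray,
    k: int,
    n_iter: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus matrix from resampled k-means over sample subsets.

    ``X`` is features x samples.  Each iteration subsamples
    ``floor(subsample_frac * n)`` samples without replacement, runs k-means
    (k-means++ init), and records co-clustering; ``C_ij`` is the fraction of
    co-sampled iterations in which i and j co-clustered.  Pairs never
    co-sampled are imputed at 0.5 with a warning.  Final labels come from
    average-linkage clustering of ``1 - C`` cut at ``k``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    Xs = np.asarray(X, dtype=float).T  # samples x features
    n = Xs.shape[0]
    size = max(int(subsample_frac * n), k)
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    tog = np.zeros((n, n))
    for it in range(n_iter):
        idx = rng.choice(n, size=size, replace=False)
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=1,
            random_state=int(rng.integers(2**31)),
        ).fit(Xs[idx])
        tog[np.ix_(idx, idx)] += 1.0
        same = km.labels_[:, None] == km.labels_[None, :]
        co[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        C = co / tog
    never = ~np.isfinite(C)
    if never.any():
        warnings.warn(
            f"{int(never.sum() // 2)} sample pairs never co-sampled; "
            "consensus imputed at 0.5"
        )
        C[never] = 0.5
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    return C, _consensus_labels(C, k)


# ----------------------------------------------------------------- PCA ----

def pca_coords(sui: pd.DataFrame, n_components: int = 3) -> pd.DataFrame:
    """Feature-centered SVD sample scores with a deterministic sign.

    The sign of each component is fixed so the loading of largest absolute
    value is positive.
    """
    if sui.shape[1] < n_components:
        raise ValueError("more components than samples")
    Xc = sui.to_numpy(dtype=float) - sui.to_numpy(dtype=float).mean(
        axis=1, keepdims=True
    )
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)  # samples x features
    scores = U[:, :n_components] * s[:n_components]
    for j in range(n_components):
        load = Vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=sui.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )


# -------------------------------------------- nearest shrunken centroids ----

@dataclass
class ShrunkenCentroidModel:
    """PAM-style nearest-shrunken-centroid classifier.

    Shrunken deviations obey the soft-threshold identity
    ``d'_ik = sign(d_ik) * max(|d_ik| - delta, 0)``.
    """

    classes: list[str]
    feature_ids: list[str]
    overall_centroid: np.ndarray  # per feature
    shrunken_centroids: np.ndarray  # features x classes
    pooled_sd: np.ndarray  # s_i per feature
    s0: float
    delta: float
    priors: np.ndarray
    reference_quantiles: np.ndarray  # training pooled quantiles

    def to_json(self, path) -> None:
        obj = {
            "classes": self.classes,
            "feature_ids": self.feature_ids,
            "overall_centroid": self.overall_centroid.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "delta": self.delta,
            "priors": self.priors.tolist(),
            "reference_quantiles": self.reference_quantiles.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "ShrunkenCentroidModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            classes=obj["classes"],
            feature_ids=obj["feature_ids"],
            overall_centroid=np.asarray(obj["overall_centroid"]),
            shrunken_centroids=np.asarray(obj["shrunken_centroids"]),
            pooled_sd=np.asarray(obj["pooled_sd"]),
            s0=float(obj["s0"]),
            delta=float(obj["delta"]),
            priors=np.asarray(obj["priors"]),
            reference_quantiles=np.asarray(obj["reference_quantiles"]),
        )


def _shrunken_fit(
    X: np.ndarray, y: np.ndarray, classes: list, delta: float
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Centroids, pooled sd and shrunken class centroids at one delta."""
    n = X.shape[1]
    K = len(classes)
    overall = X.mean(axis=1)
    cents = np.stack([X[:, y == c].mean(axis=1) for c in classes], axis=1)
    ss = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        sub = X[:, y == c]
        ss += ((sub - cents[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    nk = np.array([(y == c).sum() for c in classes])
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    denom = (mk[None, :] * (s + s0)[:, None])
    d = (cents - overall[:, None]) / denom
    d_shr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[:, None] + denom * d_shr
    return overall, shrunken, s0, s


def _discriminant(
    Xnew: np.ndarray, model_centroids: np.ndarray, s: np.ndarray, s0: float,
    priors: np.ndarray,
) -> np.ndarray:
    """delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k."""
    denom2 = ((s + s0) ** 2)[:, None]
    scores = np.empty((Xnew.shape[1], model_centroids.shape[1]))
    for k in range(model_centroids.shape[1]):
        diff2 = (Xnew - model_centroids[:, [k]]) ** 2 / denom2
        scores[:, k] = diff2.sum(axis=0) - 2.0 * np.log(priors[k])
    return scores


def train_shrunken_centroids(
    sui: pd.DataFrame,
    labels: pd.Series,
    delta_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> ShrunkenCentroidModel:
    """Train the PAM classifier, choosing delta by cross-validated error.

    ``d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0))`` with
    ``m_k = sqrt(1/n_k - 1/n)`` and fudge ``s0 = median(s_i)``; deviations
    are soft-thresholded by delta.  Ties in CV error resolve to the largest
    delta (most parsimonious model).
    """
    X = sui.to_numpy(dtype=float)
    y = labels.loc[list(sui.columns)].to_numpy()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"class with a single sample: {counts}")

    if delta_grid is None:
        _, _, s0_full, s_full = _shrunken_fit(X, y, classes, 0.0)
        overall = X.mean(axis=1)
        cents = np.stack([X[:, y == c].mean(axis=1) for c in classes], axis=1)
        nk = np.array([counts[c] for c in classes])
        mk = np.sqrt(1.0 / nk - 1.0 / X.shape[1])
        dmax = np.abs(
            (cents - overall[:, None]) / (mk[None, :] * (s_full + s0_full)[:, None])
        ).max()
        delta_grid = np.linspace(0.0, float(dmax), 30)

    folds = min(cv_folds, min(counts.values()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(delta_grid))
    for train_idx, test_idx in skf.split(X.T, y):
        Xtr, ytr = X[:, train_idx], y[train_idx]
        Xte, yte = X[:, test_idx], y[test_idx]
        pri = np.array([(ytr == c).mean() for c in classes])
        for gi, delta in enumerate(delta_grid):
            _, shr, s0, s = _shrunken_fit(Xtr, ytr, classes, delta)
            scores = _discriminant(Xte, shr, s, s0, pri)
            pred = np.asarray(classes)[np.argmin(scores, axis=1)]
            errors[gi] += (pred != yte).sum()
    # ties -> largest delta
    best = len(delta_grid) - 1 - int(np.argmin(errors[::-1]))
    delta = float(delta_grid[best])

    overall, shrunken, s0, s = _shrunken_fit(X, y, classes, delta)
    priors = np.array([counts[c] / len(y) for c in classes])
    return ShrunkenCentroidModel(
        classes=[str(c) for c in classes],
        feature_ids=list(sui.index.astype(str)),
        overall_centroid=overall,
        shrunken_centroids=shrunken,
        pooled_sd=s,
        s0=s0,
        delta=delta,
        priors=priors,
        reference_quantiles=pooled_reference_quantiles(sui),
    )


def classify_samples(
    model: ShrunkenCentroidModel,
    new_sui: pd.DataFrame,
    quantile_normalize: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign subtypes to new samples (cell lines) with the trained model.

    New columns are first quantile-normalized onto the training pooled
    quantiles, then scored with the standardized discriminant; the class of
    minimal score is assigned.  Returns (labels, score matrix).
    """
    missing = [f for f in model.feature_ids if f not in new_sui.index]
    if missing:
        raise ValueError(f"missing features: {missing[:5]} (+{len(missing) - 5 if len(missing) > 5 else 0} more)")
    sub = new_sui.loc[model.feature_ids]
    if quantile_normalize:
        sub = quantile_normalize_to_reference(sub, model.reference_quantiles)
    scores = _discriminant(
        sub.to_numpy(dtype=float),
        model.shrunken_centroids,
        model.pooled_sd,
        model.s0,
        model.priors,
    )
    score_df = pd.DataFrame(scores, index=new_sui.columns, columns=model.classes)
    labels = pd.Series(
        np.asarray(model.classes)[np.argmin(scores, axis=1)], index=new_sui.columns
    )
    return labels, score_df
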