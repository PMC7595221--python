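"""Gaussian-mixture clustering of temporal abundance profiles.

Significantly altered proteins are represented by their mean z-scored log10
abundance per (condition, day) cell, and clustered with a diagonal-covariance
Gaussian mixture fitted by EM (best of several restarts).  The number of
clusters is chosen by minimising

    BIC = -2 ln(L) + ln(n) * k

where ln(L) is the model log-likelihood, n the number of clustered proteins
and k the number of clusters.  This penalty counts clusters rather than free
parameters; the conventional free-parameter BIC is available as a non-default
mode.  The EM implementation records the log-likelihood trace and asserts its
monotonicity on every fit.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, derive_seed

_VAR_FLOOR = 1e-6


def build_profile_matrix(
    m: AbundanceMatrix, protein_ids: Sequence[str], log_transform: bool = True
) -> pd.DataFrame:
    """Mean z-scored log10 abundance per (condition, day) for the given proteins.

    Rows are re-standardised (mean 0, sd 1) so clustering sees profile shape,
    not scale.
    """
    ids = [p for p in protein_ids if p in m.values.index]
    if not ids:
        raise ValueError("none of the requested proteins are in the matrix")
    arr = m.values.loc[ids].to_numpy(dtype=float)
    if log_transform:
        if (arr <= 0).any():
            raise ValueError("log transform requires strictly positive abundances")
        arr = np.log10(arr)
    cells = m.meta.reset_index().groupby(["condition", "day"], sort=True)
    cols, data = [], []
    for (cond, day), grp in cells:
        cols.append(f"{cond}_{int(day):02d}")
        data.append(arr[:, [m.values.columns.get_loc(s) for s in grp["sample_id"]]].mean(axis=1))
    profiles = np.column_stack(data)
    mean = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((profiles - mean) / sd, index=ids, columns=cols)


@dataclasses.dataclass
class GMMFit:
    """A fitted diagonal-covariance Gaussian mixture."""

    k: int
    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, d)
    variances: np.ndarray  # (k, d)
    log_likelihood: float
    responsibilities: np.ndarray  # (n, k)
    loglik_trace: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("non-finite log-likelihood")


def _log_gaussian_diag(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, k) log densities of diagonal Gaussians."""
    n, d = X.shape
    out = np.empty((n, means.shape[0]))
    for j in range(means.shape[0]):
        v = variances[j]
        out[:, j] = -0.5 * (np.log(2 * np.pi * v).sum() + (((X - means[j]) ** 2) / v).sum(axis=1))
    return out


def _em_once(X: np.ndarray, k: int, rng: np.random.Generator,
             max_iter: int = 300, tol: float = 1e-8) -> tuple:
    n, d = X.shape
    # k-means++-style spread of initial means over data points
    means = np.empty((k, d))
    first = rng.integers(n)
    means[0] = X[first]
    for j in range(1, k):
        d2 = np.min(((X[:, None, :] - means[None, :j, :]) ** 2).sum(axis=2), axis=1)
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        means[j] = X[rng.choice(n, p=probs)]
    variances = np.tile(np.maximum(X.var(axis=0), _VAR_FLOOR), (k, 1))
    weights = np.full(k, 1.0 / k)

    trace = []
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        log_dens = _log_gaussian_diag(X, means, variances) + np.log(weights)
        mx = log_dens.max(axis=1, keepdims=True)
        log_norm = mx + np.log(np.exp(log_dens - mx).sum(axis=1, keepdims=True))
        ll = float(log_norm.sum())
        if trace and ll < trace[-1] - 1e-8:
            raise RuntimeError("EM log-likelihood decreased")  # pragma: no cover
        converged = bool(trace) and abs(ll - trace[-1]) < tol
        trace.append(ll)
        resp = np.exp(log_dens - log_norm)
        if converged:
            break
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for j in range(k):
            diff2 = (X - means[j]) ** 2
            variances[j] = np.maximum((resp[:, j] @ diff2) / nk[j], _VAR_FLOOR)
    weights = weights / weights.sum()
    return weights, means, variances, trace[-1], resp, np.asarray(trace)


def fit_gmm(profiles: pd.DataFrame, k: int, seeds: Sequence[int] = (0, 1, 2, 3, 4)) -> GMMFit:
    """EM fit with diagonal covariances; best of the seed restarts by ln(L)."""
    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of proteins ({n})")
    best: GMMFit | None = None
    for s in seeds:
        rng = np.random.default_rng(int(s) % (2**31))
        weights, means, variances, ll, resp, trace = _em_once(X, k, rng)
        fit = GMMFit(k, weights, means, variances, ll, resp, trace, int(s))
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def bic_score(fit: GMMFit, n: int, mode: str = "clusters") -> float:
    """BIC = -2 ln(L) + ln(n) * penalty.

    ``mode='clusters'`` (default) penalises the number of clusters k;
    ``mode='parameters'`` uses the conventional free-parameter count
    k*(2d + 1) - 1 for a diagonal mixture in d dimensions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == "clusters":
        penalty = fit.k
    elif mode == "parameters":
        d = fit.means.shape[1]
        penalty = fit.k * (2 * d + 1) - 1
    else:
        raise ValueError("mode must be 'clusters' or 'parameters'")
    return -2.0 * fit.log_likelihood + np.log(n) * penalty


@dataclasses.dataclass
class BICTrace:
    """BIC per candidate cluster count and the argmin selection."""

    bic: dict[int, float]
    fits: dict[int, GMMFit]
    n: int
    selected_k: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": list(self.bic), "bic": list(self.bic.values())}
        ).set_index("k")


def select_cluster_count(
    profiles: pd.DataFrame,
    k_max: int | None = None,
    root_seed: int = 0,
    n_restarts: int = 5,
    mode: str = "clusters",
) -> BICTrace:
    """Fit k = 1..k_max mixtures and pick the k with the smallest BIC.

    Ties break toward smaller k.  k_max defaults to min(n, 30): fits with k
    near n are degenerate under any criterion.
    """
    n = profiles.shape[0]
    if k_max is None:
        k_max = min(n, 30)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_max = min(k_max, n)
    bic: dict[int, float] = {}
    fits: dict[int, GMMFit] = {}
    for k in range(1, k_max + 1):
        seeds = [
            int(derive_seed(root_seed, "gmm", index=k * 1000 + r).integers(2**31))
            for r in range(n_restarts)
        ]
        fit = fit_gmm(profiles, k, seeds=seeds)
        fits[k] = fit
        bic[k] = bic_score(fit, n, mode=mode)
    selected = min(bic, key=lambda k: (round(bic[k], 12), k))
    return BICTrace(bic, fits, n, selected)


def assign_profiles(fit: GMMFit, profiles: pd.DataFrame) -> pd.DataFrame:
    """Label each protein by argmax responsibility (ties -> lower cluster index)."""
    labels = fit.responsibilities.argmax(axis=1) + 1  # 1-based cluster ids
    return pd.DataFrame(
        {
            "cluster": labels,
            "max_responsibility": fit.responsibilities.max(axis=1),
        },
        index=profiles.index,
    )


def cluster_mean_profiles(assignment: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean profile per cluster, for reporting."""
    joined = profiles.join(assignment["cluster"])
    return joined.groupby("cluster").mean()
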