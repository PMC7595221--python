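"""Preprocessing of label-free protein abundance tables.

Stage order used by the pipeline: Hi3 peptide-to-protein rollup, detection-floor
imputation (per-run minimum), quantile normalisation across all runs, then
either log10 + per-protein z-standardisation (for PCA / profile clustering) or
normalisation relative to the healthy day-5 baseline (for biclustering).
Every step appends to the matrix provenance log.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .containers import AbundanceMatrix, PeptideTable


def hi3_rollup(peptides: PeptideTable) -> AbundanceMatrix:
    """Protein abundance = mean intensity of the 3 most intense peptides.

    Proteins observed with fewer than 3 peptides in a sample use the mean of
    all available peptides and are flagged ``n_peptides<3``.
    """
    if peptides.records.empty:
        raise ValueError("empty peptide table")

    def top3_mean(x: pd.Series) -> float:
        return float(x.nlargest(3).mean())

    grouped = peptides.records.groupby(["protein_id", "sample_id"])["intensity"]
    values = grouped.apply(top3_mean).unstack("sample_id")
    counts = grouped.size().unstack("sample_id")
    few = sorted(counts.index[(counts < 3).any(axis=1)])
    matrix = AbundanceMatrix(values, peptides.meta, log=["hi3_rollup"])
    if few:
        matrix.flags["n_peptides<3"] = few
    return matrix


def impute_missing(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace missing entries by the minimum observed abundance of the same run."""
    out = m.copy()
    n_imputed = 0
    for col in out.values.columns:
        column = out.values[col]
        observed = column[~out.mask[col]]
        if observed.empty:
            raise ValueError(f"sample {col!r} has no observed values to impute from")
        n = int(out.mask[col].sum())
        if n:
            out.values.loc[out.mask[col], col] = observed.min()
            n_imputed += n
    out.mask = pd.DataFrame(False, index=out.values.index, columns=out.values.columns)
    out.log.append(f"impute_missing:{n_imputed}")
    return out


def quantile_normalise(m: AbundanceMatrix) -> AbundanceMatrix:
    """Force every sample column onto the mean of the column-sorted distributions.

    Ties within a column receive the mean of the reference values at their
    tied ranks, so within-column rank order (with ties) is preserved.
    """
    if m.n_missing():
        raise ValueError("matrix has missing entries; run impute_missing first")
    arr = m.values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    reference = np.sort(arr, axis=0).mean(axis=1)

    out_arr = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = np.empty(arr.shape[0], dtype=int)
        ranks[order[:, j]] = np.arange(arr.shape[0])
        col = reference[ranks]
        # average reference values over tied blocks
        vals, inv, counts = np.unique(arr[:, j], return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inv, weights=col)
            col = (sums / counts)[inv]
        out_arr[:, j] = col

    out = m.copy()
    out.values = pd.DataFrame(out_arr, index=m.values.index, columns=m.values.columns)
    out.log.append("quantile_normalise")
    return out


def standardise(m: AbundanceMatrix) -> AbundanceMatrix:
    """log10-transform, then z-score each protein row (sample sd, ddof=1).

    Constant rows become all-zeros and are flagged ``constant_row``.
    """
    arr = m.values.to_numpy(dtype=float)
    if (arr <= 0).any() or np.isnan(arr).any():
        raise ValueError("standardise requires strictly positive, complete abundances")
    logged = np.log10(arr)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    constant = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    sd[constant[:, None]] = 1.0
    z = (logged - mean) / sd
    z[constant] = 0.0
    out = m.copy()
    out.values = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    out.log.append("standardise:log10+z")
    if constant.any():
        out.flags["constant_row"] = sorted(m.values.index[constant])
    return out


def baseline_relative(m: AbundanceMatrix, condition: str = "healthy", day: int = 5) -> AbundanceMatrix:
    """Divide each protein by its mean abundance over the baseline samples."""
    base_ids = m.meta.index[(m.meta["condition"] == condition) & (m.meta["day"] == day)]
    if len(base_ids) == 0:
        raise ValueError(f"no baseline samples for condition={condition!r}, day={day}")
    base_mean = m.values[list(base_ids)].mean(axis=1)
    if (base_mean == 0).any() or base_mean.isna().any():
        raise ValueError("zero or undefined baseline mean for some proteins")
    out = m.copy()
    out.values = m.values.div(base_mean, axis=0)
    out.log.append(f"baseline_relative:{condition}@{day}")
    return out


@dataclasses.dataclass
class PCASummary:
    variance_explained_pct: np.ndarray  # per component, non-increasing
    scores: pd.DataFrame  # samples x components

    def to_dict(self) -> dict:
        return {
            "variance_explained_pct": self.variance_explained_pct.tolist(),
            "scores": {s: row.tolist() for s, row in self.scores.iterrows()},
        }


def pca_summary(m: AbundanceMatrix, n_components: int | None = None) -> PCASummary:
    """PCA with samples as observations on a standardised matrix."""
    if m.values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = m.values.to_numpy(dtype=float).T  # samples x proteins
    k = n_components or min(X.shape)
    pca = PCA(n_components=min(k, min(X.shape)))
    scores = pca.fit_transform(X)
    pct = pca.explained_variance_ratio_ * 100.0
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return PCASummary(pct, pd.DataFrame(scores, index=m.values.columns, columns=cols))


@dataclasses.dataclass
class BiclusterResult:
    row_linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    col_linkage: np.ndarray
    reordered: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "row_merges": self.row_linkage.tolist(),
            "col_merges": self.col_linkage.tolist(),
            "row_order": self.reordered.index.tolist(),
            "col_order": self.reordered.columns.tolist(),
        }


def hierarchical_bicluster(m: AbundanceMatrix) -> BiclusterResult:
    """Agglomerative biclustering: Euclidean distance, complete linkage."""
    if m.values.shape[0] < 2 or m.values.shape[1] < 2:
        raise ValueError("biclustering requires at least a 2x2 matrix")
    arr = m.values.to_numpy(dtype=float)
    row_link = hierarchy.linkage(arr, method="complete", metric="euclidean")
    col_link = hierarchy.linkage(arr.T, method="complete", metric="euclidean")
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    reordered = m.values.iloc[row_order, col_order]
    return BiclusterResult(row_link, col_link, reordered)


def collapse_technical(m: AbundanceMatrix) -> AbundanceMatrix:
    """Average technical repeats into their biological repeat.

    Returns a matrix with one sample per (condition, day, bio_rep); avoids
    pseudo-replication in downstream model fitting.
    """
    meta = m.meta.reset_index()
    groups = meta.groupby(["condition", "day", "bio_rep"], sort=True)
    cols, rows = [], []
    data = {}
    for (cond, day, bio), grp in groups:
        sid = f"{cond[0].upper()}{int(day):02d}b{bio}"
        data[sid] = m.values[grp["sample_id"].tolist()].mean(axis=1)
        rows.append((sid, cond, int(day), int(bio), 1))
        cols.append(sid)
    values = pd.DataFrame(data)[cols]
    new_meta = pd.DataFrame(rows, columns=["sample_id", "condition", "day", "bio_rep", "tech_rep"])
    return AbundanceMatrix(values, new_meta, log=list(m.log) + ["collapse_technical"])
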