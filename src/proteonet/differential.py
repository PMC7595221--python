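"""Consensus time-course differential abundance.

Three detectors spanning the statistical families commonly applied to
longitudinal expression data:

* ``moderated_f``   — per-protein linear model over (condition, day) cells with
  empirical-Bayes variance shrinkage and a moderated F-test (limma-style);
* ``nb_lrt``        — negative-binomial likelihood-ratio test on size-factor
  scaled pseudo-counts with a common method-of-moments dispersion
  (DESeq2/edgeR-style);
* ``poly_lrt``      — Gaussian log-likelihood-ratio test of a polynomial-in-day
  model with versus without condition terms (maSigPro/EDGE-style).

Each detector returns per-protein p values, BH-adjusted per detector, and a
protein is declared significantly altered when at least ``threshold`` (default
2) detectors call it at FDR ``alpha`` (default 5%).  The framework accepts any
number of detectors.  Technical repeats are averaged into their biological
repeat before fitting by default, to avoid pseudo-replication.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix
from .preprocess import collapse_technical


# ---------------------------------------------------------------------------
# multiple-testing correction (shared with the enrichment module)
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# detector scaffolding
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DetectorResult:
    """Per-protein statistics of one detector."""

    name: str
    table: pd.DataFrame  # index protein_id; columns statistic, p, q
    df_full: int
    df_test: int
    flags: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> set[str]:
        return set(self.table.index[self.table["q"] < alpha])


def _prepare(m: AbundanceMatrix, mode: str, collapse: bool) -> tuple[np.ndarray, pd.DataFrame]:
    """Collapse technical repeats and, for condition tests, restrict to shared days."""
    if mode not in ("condition", "time"):
        raise ValueError("mode must be 'condition' or 'time'")
    if collapse and (m.meta["tech_rep"].nunique() > 1):
        m = collapse_technical(m)
    meta = m.meta.copy()
    if mode == "condition":
        shared = sorted(
            set(meta.loc[meta.condition == "healthy", "day"])
            & set(meta.loc[meta.condition == "disease", "day"])
        )
        if not shared:
            raise ValueError("no days shared between conditions")
        keep = meta.index[meta["day"].isin(shared)]
        m = m.select_samples(keep)
        meta = m.meta
    return m.values.to_numpy(dtype=float), meta


def _group_codes(meta: pd.DataFrame, by: list[str]) -> np.ndarray:
    keys = meta[by].apply(tuple, axis=1)
    _, codes = np.unique(keys, return_inverse=True)
    return codes


def _group_rss(Y: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares of the per-group-mean fit, per protein row."""
    n_groups = codes.max() + 1
    rss = np.zeros(Y.shape[0])
    for g in range(n_groups):
        cols = codes == g
        block = Y[:, cols]
        rss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return rss, n_groups


def _full_reduced_codes(meta: pd.DataFrame, mode: str) -> tuple[np.ndarray, np.ndarray]:
    if mode == "condition":
        full = _group_codes(meta, ["condition", "day"])
        reduced = _group_codes(meta, ["day"])
    else:  # time effect (e.g. ageing analysis on healthy samples only)
        full = _group_codes(meta, ["day"])
        reduced = np.zeros(len(meta), dtype=int)
    return full, reduced


# ---------------------------------------------------------------------------
# detector 1: moderated F (empirical-Bayes shrunk variances)
# ---------------------------------------------------------------------------

def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Marginally s2/s0^2 ~ F(df, d0); solving the F-distribution mean and
    variance for (d0, s0^2) gives closed-form estimates.  Returns
    (prior_df, prior_scale); prior_df = inf when the variances are
    underdispersed relative to pure chi-square sampling noise.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    m1 = s2.mean()
    c = s2.var(ddof=1) / m1**2  # squared coefficient of variation
    denom = c * df - 2.0
    if denom <= 0:
        return np.inf, m1
    d0 = (2.0 * df - 4.0 + 4.0 * c * df) / denom
    if d0 <= 4.0 or not np.isfinite(d0):
        d0 = 4.001  # heavy-tailed variances: keep a weak, proper prior
    s0_2 = m1 * (d0 - 2.0) / d0
    return float(d0), float(s0_2)


def detect_moderated_f(
    m: AbundanceMatrix,
    mode: str = "condition",
    collapse_tech: bool = True,
    log_transform: bool = True,
    prior_df: float | None = None,
) -> DetectorResult:
    """Moderated F-test for the condition + condition:time terms.

    Fits the saturated per-(condition, day)-cell means model against the
    day-only model; residual variances are shrunk toward a common prior whose
    df and scale are moment-matched to the observed variance distribution.
    ``prior_df=inf`` recovers the ordinary F-test with the pooled variance.
    """
    Y, meta = _prepare(m, mode, collapse_tech)
    if log_transform:
        if (Y <= 0).any():
            raise ValueError("log transform requires strictly positive abundances")
        Y = np.log10(Y)
    full, reduced = _full_reduced_codes(meta, mode)
    counts = np.bincount(full)
    if (counts < 2).any():
        raise ValueError("every (condition, day) cell needs at least 2 replicates")

    rss_full, g_full = _group_rss(Y, full)
    rss_red, g_red = _group_rss(Y, reduced)
    n = Y.shape[1]
    df_res = n - g_full
    df_test = g_full - g_red
    s2 = rss_full / df_res

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df_res)
    else:
        d0 = float(prior_df)
        s0_2 = float(np.mean(s2))
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_mod = (d0 * s0_2 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    s2_mod = np.maximum(s2_mod, 1e-300)

    fstat = ((rss_red - rss_full) / df_test) / s2_mod
    fstat = np.maximum(fstat, 0.0)
    if np.isinf(df_total):
        p = stats.chi2.sf(fstat * df_test, df_test)
    else:
        p = stats.f.sf(fstat, df_test, df_total)
    table = pd.DataFrame(
        {"statistic": fstat, "p": p, "q": bh_adjust(p)}, index=m.values.index
    )
    return DetectorResult("moderated_f", table, g_full, df_test,
                          flags={"prior": [f"d0={d0:.4g}", f"s0_2={s0_2:.4g}"]})


# ---------------------------------------------------------------------------
# detector 2: negative-binomial likelihood ratio test
# ---------------------------------------------------------------------------

def median_of_ratios_size_factors(values: np.ndarray) -> np.ndarray:
    """DESeq-style size factors: median ratio to the geometric-mean reference."""
    logged = np.log(np.where(values > 0, values, np.nan))
    ref = np.nanmean(logged, axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError("no protein observed in all samples; cannot form reference")
    ratios = logged[usable] - ref[usable, None]
    return np.exp(np.nanmedian(ratios, axis=0))


def _nb_loglik(y: np.ndarray, mu: float, alpha: float) -> float:
    mu = max(mu, 1e-8)
    if alpha < 1e-8:
        return float(stats.poisson.logpmf(y, mu).sum())
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(stats.nbinom.logpmf(y, r, p).sum())


def _common_dispersion(counts: np.ndarray, codes: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across proteins and cells."""
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for g in range(codes.max() + 1):
        block = counts[:, codes == g]
        if block.shape[1] < 2:
            continue
        mu = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        num += v - mu
        den += mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / den
    alpha = alpha[np.isfinite(alpha)]
    if alpha.size == 0:
        return 1e-8
    return float(max(np.median(alpha), 1e-8))


def detect_nb_lrt(
    m: AbundanceMatrix,
    mode: str = "condition",
    collapse_tech: bool = True,
) -> DetectorResult:
    """Negative-binomial LRT of the condition x time model vs time only.

    Abundances are scaled by median-of-ratios size factors and rounded
    (half-to-even) to pseudo-counts; a common dispersion is estimated by the
    method of moments; the LRT statistic is referred to chi-square with df =
    the difference in cell counts.  All-zero proteins get p = 1, flagged.
    """
    Y, meta = _prepare(m, mode, collapse_tech)
    if (Y < 0).any():
        raise ValueError("negative abundances cannot be scaled to counts")
    sf = median_of_ratios_size_factors(Y)
    counts = np.rint(Y / sf)
    counts = np.maximum(counts, 0.0)

    full, reduced = _full_reduced_codes(meta, mode)
    alpha = _common_dispersion(counts, full)
    df_test = (full.max() + 1) - (reduced.max() + 1)

    # with a fixed dispersion and a log link, the per-cell NB MLE mean is the
    # sample mean, so both model fits are analytic
    stat = np.zeros(counts.shape[0])
    allzero = counts.sum(axis=1) == 0
    for i in range(counts.shape[0]):
        if allzero[i]:
            continue
        y = counts[i]
        ll_full = sum(
            _nb_loglik(y[full == g], y[full == g].mean(), alpha) for g in range(full.max() + 1)
        )
        ll_red = sum(
            _nb_loglik(y[reduced == g], y[reduced == g].mean(), alpha)
            for g in range(reduced.max() + 1)
        )
        stat[i] = max(2.0 * (ll_full - ll_red), 0.0)
    p = stats.chi2.sf(stat, df_test)
    p[allzero] = 1.0
    table = pd.DataFrame({"statistic": stat, "p": p, "q": bh_adjust(p)}, index=m.values.index)
    flags = {}
    if allzero.any():
        flags["all_zero"] = sorted(m.values.index[allzero])
    flags["dispersion"] = [f"alpha={alpha:.4g}"]
    return DetectorResult("nb_lrt", table, full.max() + 1, df_test, flags=flags)


# ---------------------------------------------------------------------------
# detector 3: polynomial-in-time Gaussian LRT
# ---------------------------------------------------------------------------

def _poly_design(day: np.ndarray, degree: int) -> np.ndarray:
    x = (day - day.mean()) / (day.std() if day.std() > 0 else 1.0)
    return np.column_stack([x**d for d in range(degree + 1)])


def _proj_rss(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-row residual sum of squares after projecting onto col(X)."""
    q, r = np.linalg.qr(X)
    rank = int((np.abs(np.diag(r)) > 1e-10).sum())
    q = q[:, :rank] if rank < q.shape[1] else q
    resid = Y.T - q @ (q.T @ Y.T)
    return (resid**2).sum(axis=0), rank


def detect_polynomial_lrt(
    m: AbundanceMatrix,
    mode: str = "condition",
    degree: int = 2,
    collapse_tech: bool = True,
    log_transform: bool = True,
) -> DetectorResult:
    """Gaussian LRT of a degree-d polynomial-in-day model with condition terms.

    Full model: polynomial in day, condition main effect and condition x
    polynomial interaction; reduced: polynomial only.  With degree 0 this is a
    two-group mean comparison pooled over days.  Statistic n*ln(RSS0/RSS1)
    referred to chi-square with df = difference in model rank.
    """
    Y, meta = _prepare(m, mode, collapse_tech)
    if log_transform:
        if (Y <= 0).any():
            raise ValueError("log transform requires strictly positive abundances")
        Y = np.log10(Y)
    day = meta["day"].to_numpy(dtype=float)
    max_distinct = (
        meta.groupby("condition")["day"].nunique().max() if mode == "condition"
        else meta["day"].nunique()
    )
    if max_distinct < degree + 2:
        raise ValueError(
            f"degree {degree} needs at least {degree + 2} distinct time points in one condition"
        )
    base = _poly_design(day, degree)
    if mode == "condition":
        is_disease = (meta["condition"] == "disease").to_numpy(dtype=float)
        X_full = np.column_stack([base, base * is_disease[:, None]])
        X_red = base
    else:
        X_full = base
        X_red = base[:, :1]
    rss_full, rank_full = _proj_rss(Y, X_full)
    rss_red, rank_red = _proj_rss(Y, X_red)
    n = Y.shape[1]
    df_test = rank_full - rank_red
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(rss_red / np.maximum(rss_full, 1e-300))
    stat = np.where(rss_red <= 0, 0.0, np.maximum(stat, 0.0))
    p = stats.chi2.sf(stat, df_test)
    table = pd.DataFrame({"statistic": stat, "p": p, "q": bh_adjust(p)}, index=m.values.index)
    return DetectorResult("poly_lrt", table, rank_full, df_test)


DEFAULT_DETECTORS: dict[str, Callable[..., DetectorResult]] = {
    "moderated_f": detect_moderated_f,
    "nb_lrt": detect_nb_lrt,
    "poly_lrt": detect_polynomial_lrt,
}


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConsensusResult:
    """Vote table across detectors with the significance flag per protein."""

    table: pd.DataFrame  # index protein; q_<detector> columns, votes, significant
    alpha: float
    threshold: int

    @property
    def significant_ids(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def consensus_vote(
    results: Sequence[DetectorResult], alpha: float = 0.05, threshold: int = 2
) -> ConsensusResult:
    """Declare a protein altered when >= threshold detectors call it at FDR alpha."""
    if len(results) < 2:
        raise ValueError("consensus needs at least 2 detectors")
    universe = list(results[0].table.index)
    for r in results[1:]:
        if list(r.table.index) != universe:
            raise ValueError("detectors tested different protein universes")
    table = pd.DataFrame(index=pd.Index(universe, name="protein_id"))
    for r in results:
        table[f"q_{r.name}"] = r.table["q"]
    calls = pd.DataFrame({r.name: r.table["q"] < alpha for r in results})
    table["votes"] = calls.sum(axis=1).astype(int)
    table["significant"] = table["votes"] >= threshold
    return ConsensusResult(table, alpha, threshold)


def run_consensus(
    m: AbundanceMatrix,
    mode: str = "condition",
    detectors: Sequence[str] = ("moderated_f", "nb_lrt", "poly_lrt"),
    alpha: float = 0.05,
    threshold: int = 2,
    **kwargs,
) -> tuple[ConsensusResult, list[DetectorResult]]:
    """Run the named detectors and combine them by vote."""
    results = [DEFAULT_DETECTORS[name](m, mode=mode, **kwargs) for name in detectors]
    return consensus_vote(results, alpha=alpha, threshold=threshold), results


def compare_condition_sets(ad: ConsensusResult, ageing: ConsensusResult) -> pd.DataFrame:
    """Partition the universe into AD-only / ageing-only / shared / neither."""
    if list(ad.table.index) != list(ageing.table.index):
        raise ValueError("consensus results cover different protein universes")
    in_ad = ad.table["significant"]
    in_age = ageing.table["significant"]
    label = pd.Series("neither", index=ad.table.index, name="set_label")
    label[in_ad & ~in_age] = "AD-only"
    label[~in_ad & in_age] = "ageing-only"
    label[in_ad & in_age] = "shared"
    return label.to_frame()


def set_sizes(labels: pd.DataFrame) -> dict[str, int]:
    counts = labels["set_label"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ("AD-only", "ageing-only", "shared", "neither")}
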