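"""Overrepresentation analysis against a custom background.

Fisher/hypergeometric one-sided tests per annotation term with BH correction
(FDR 5% by convention), restricted to a supplied background universe before
testing, plus an optional minimum-hypergeometric (mHG) statistic over a ranked
protein list with label-permutation significance.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationCollection
from .differential import bh_adjust

MIN_TERM_SIZE = 3  # terms smaller than this after background restriction are untestable


def fisher_overrepresentation(
    query: Iterable[str],
    annotations: AnnotationCollection,
    min_term_size: int = MIN_TERM_SIZE,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of each term in the query.

    Term sets are intersected with the background universe first; query ids
    outside the universe are dropped (counted in the ``n_dropped`` attribute of
    the returned frame).  Terms with zero overlap report p = 1.
    """
    universe = set(annotations.universe)
    if not universe:
        raise ValueError("empty background universe")
    query = set(query)
    dropped = len(query - universe)
    query &= universe
    N = len(universe)
    n = len(query)
    rows = []
    for term in sorted(annotations.terms):
        members = annotations.terms[term] & universe
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        a, b = k, K - k
        c, d = n - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append((term, annotations.names.get(term, term), k, K, n, N, odds, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "name", "k", "K", "n", "N", "odds_ratio", "p"]
    ).set_index("term")
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out.attrs["n_dropped"] = dropped
    return out


@dataclasses.dataclass
class MHGResult:
    score: float
    cutoff: int  # minimising prefix length
    p_permutation: float | None = None


def ranked_mhg(
    ranked_ids: Sequence[str],
    term_set: Iterable[str],
    n_permutations: int = 0,
    seed: int = 0,
) -> MHGResult:
    """Minimum hypergeometric statistic over prefixes of a ranked list.

    Scans prefixes 1..N-1 and takes the smallest hypergeometric upper-tail
    probability of the observed prefix overlap; significance (optional) by
    permuting the ranking.  Duplicate ids in the ranking are an error.
    """
    ranked = list(ranked_ids)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked list contains duplicates")
    term = set(term_set)
    unknown = term - set(ranked)
    if unknown:
        raise ValueError(f"term members missing from the ranking: {sorted(unknown)[:5]}")
    score, cutoff = _mhg_scan(np.array([1 if x in term else 0 for x in ranked]), len(term))
    result = MHGResult(score, cutoff)
    if n_permutations > 0:
        rng = np.random.default_rng(int(seed) % (2**31))
        member = np.array([1 if x in term else 0 for x in ranked])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(member)
            s, _ = _mhg_scan(perm, len(term))
            if s <= score:
                hits += 1
        result.p_permutation = (1 + hits) / (1 + n_permutations)
    return result


def _mhg_scan(membership: np.ndarray, B: int) -> tuple[float, int]:
    N = membership.size
    overlap = np.cumsum(membership)
    best_p, best_cut = 1.0, 1
    for i in range(1, N):  # prefixes 1..N-1
        p = float(stats.hypergeom.sf(overlap[i - 1] - 1, N, B, i)) if overlap[i - 1] > 0 else 1.0
        if p < best_p - 1e-15:
            best_p, best_cut = p, i
    return best_p, best_cut


def enrich_modules(
    modules: Sequence, annotations: AnnotationCollection, alpha: float = 0.05
) -> dict[int, pd.DataFrame]:
    """Fisher overrepresentation for every module's node set; keyed by module id."""
    out = {}
    for i, mod in enumerate(modules, start=1):
        table = fisher_overrepresentation(mod.nodes, annotations)
        out[i] = table[table["q"] < alpha] if len(table) else table
    return out
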