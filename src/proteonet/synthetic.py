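"""Synthetic data generators emulating a longitudinal brain-proteome study.

Emulated design: two conditions (healthy controls and amyloid-beta-expressing
animals) sampled at fixed days post-eclosion — the disease arm at 5, 19, 31
and 46 days, the healthy arm additionally at 54 and 80 days — with three
biological repeats, each measured by at least two technical repeats.
Abundances are log10-normal; a planted subset of proteins follows one of four
temporal archetypes:

1. constitutively elevated in disease at every time point,
2. constitutively reduced in disease at every time point,
3. ageing-coupled increase with day in both conditions,
4. disease-specific decline with day (flat in healthy animals).

Missing values are intensity-dependent (low-abundance entries are more likely
to fall below the detection floor), mimicking label-free detection limits.
Network fixtures are random graphs (Erdos-Renyi or preferential-attachment)
with an optional planted high-confidence clique and an optional set of
degree-boosted nodes for centrality tests.  All generators are pure functions
of the config: identical seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, AnnotationCollection, PeptideTable, derive_seed

DISEASE_DAYS = (5, 19, 31, 46)
HEALTHY_DAYS = (5, 19, 31, 46, 54, 80)


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults mirror the emulated design."""

    n_proteins: int = 500
    n_altered: int = 60
    archetype_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    timepoints_disease: tuple[int, ...] = DISEASE_DAYS
    timepoints_healthy: tuple[int, ...] = HEALTHY_DAYS
    n_bio: int = 3
    n_tech: int = 2
    baseline_log_mean: float = 4.0  # log10 units
    baseline_log_sd: float = 0.6
    effect_size: float = 4.0  # multiplicative fold change >= 1
    noise_cv: float = 0.2
    missing_rate: float = 0.05
    network_model: str = "erdos_renyi"  # or "scale_free"
    n_nodes: int = 300
    edge_param: float = 0.03
    planted_clique: int = 0
    planted_central: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.archetype_fractions, dtype=float)
        if fr.shape != (4,) or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("archetype_fractions must be 4 non-negative proportions summing to 1")
        if self.n_altered > self.n_proteins:
            raise ValueError("n_altered cannot exceed n_proteins")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be at least 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1 (multiplicative fold change)")
        if self.network_model not in ("erdos_renyi", "scale_free"):
            raise ValueError(f"unknown network_model {self.network_model!r}")
        if self.planted_clique > self.n_nodes:
            raise ValueError("planted_clique cannot exceed n_nodes")
        if min(self.n_proteins, self.n_nodes) < 0 or self.planted_clique < 0:
            raise ValueError("counts must be non-negative")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure for recovery tests."""

    altered_ids: set[str] = dataclasses.field(default_factory=set)
    archetype_of: dict[str, int] = dataclasses.field(default_factory=dict)
    planted_module: set[str] = dataclasses.field(default_factory=set)
    planted_central_set: set[str] = dataclasses.field(default_factory=set)


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _archetype_assignment(cfg: SyntheticConfig) -> dict[str, int]:
    """Deterministically partition the first n_altered proteins into archetypes 1-4."""
    ids = _protein_ids(cfg.n_proteins)[: cfg.n_altered]
    counts = np.floor(np.asarray(cfg.archetype_fractions) * cfg.n_altered).astype(int)
    # distribute the rounding remainder to the largest fractions
    rem = cfg.n_altered - counts.sum()
    order = np.argsort(-np.asarray(cfg.archetype_fractions))
    for i in range(rem):
        counts[order[i % 4]] += 1
    out: dict[str, int] = {}
    pos = 0
    for arch, c in enumerate(counts, start=1):
        for pid in ids[pos : pos + c]:
            out[pid] = arch
        pos += c
    return out


def _sample_frame(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for condition, days in (("healthy", cfg.timepoints_healthy), ("disease", cfg.timepoints_disease)):
        for day in days:
            for b in range(1, cfg.n_bio + 1):
                for t in range(1, cfg.n_tech + 1):
                    sid = f"{condition[0].upper()}{day:02d}b{b}t{t}"
                    rows.append((sid, condition, int(day), b, t))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "day", "bio_rep", "tech_rep"])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def expected_abundance(cfg: SyntheticConfig, base: np.ndarray, archetypes: np.ndarray,
                       condition: str, day: float) -> np.ndarray:
    """Noise-free expected abundance of every protein in one (condition, day) cell."""
    all_days = set(cfg.timepoints_healthy) | set(cfg.timepoints_disease)
    dmin, dmax = min(all_days), max(all_days)
    ramp = (day - dmin) / (dmax - dmin) if dmax > dmin else 0.0
    # archetype 4 attains the full planted fold change within the disease
    # window, which ends earlier than the healthy follow-up
    ddays = cfg.timepoints_disease
    dspan = max(ddays) - min(ddays)
    ramp_d = (min(day, max(ddays)) - min(ddays)) / dspan if dspan > 0 else 0.0
    mu = base.copy()
    es = cfg.effect_size
    disease = condition == "disease"
    mu[(archetypes == 1)] *= es if disease else 1.0
    mu[(archetypes == 2)] /= es if disease else 1.0
    mu[(archetypes == 3)] *= es**ramp  # ageing-coupled in both conditions
    if disease:
        mu[(archetypes == 4)] /= es**ramp_d  # disease-specific decline
    return mu


def generate_abundance_dataset(cfg: SyntheticConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Simulate a proteins x samples abundance table with planted alterations."""
    rng = derive_seed(cfg.seed, "abundance")
    ids = _protein_ids(cfg.n_proteins)
    meta = _sample_frame(cfg)

    base = 10.0 ** rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_proteins)
    arch_map = _archetype_assignment(cfg)
    archetypes = np.array([arch_map.get(pid, 0) for pid in ids])

    n_samples = len(meta)
    values = np.empty((cfg.n_proteins, n_samples))
    # biological noise shared across technical repeats of the same repeat
    bio_keys = meta[["condition", "day", "bio_rep"]].apply(tuple, axis=1)
    bio_factors = {
        key: _lognormal_factor(rng, cfg.noise_cv, cfg.n_proteins) for key in dict.fromkeys(bio_keys)
    }
    for j, row in meta.iterrows():
        mu = expected_abundance(cfg, base, archetypes, row.condition, row.day)
        tech = _lognormal_factor(rng, cfg.noise_cv / 2.0, cfg.n_proteins)
        values[:, j] = mu * bio_factors[(row.condition, row.day, row.bio_rep)] * tech

    frame = pd.DataFrame(values, index=ids, columns=meta["sample_id"])

    # intensity-dependent missingness: weight proportional to low-abundance rank
    n_total = frame.size
    n_missing = int(round(cfg.missing_rate * n_total))
    if n_missing:
        flat = frame.to_numpy().ravel()
        ranks = np.empty(n_total, dtype=float)
        ranks[np.argsort(flat, kind="stable")] = np.arange(n_total, dtype=float)
        weights = n_total - ranks  # lowest abundance -> largest weight
        weights /= weights.sum()
        idx = rng.choice(n_total, size=n_missing, replace=False, p=weights)
        arr = frame.to_numpy()
        arr.ravel()[idx] = np.nan
        frame = pd.DataFrame(arr, index=ids, columns=meta["sample_id"])

    truth = GroundTruth(altered_ids=set(arch_map), archetype_of=arch_map)
    matrix = AbundanceMatrix(frame, meta, log=[f"synthetic:seed={cfg.seed}"])
    return matrix, truth


def generate_peptide_table(cfg: SyntheticConfig) -> PeptideTable:
    """Simulate peptide intensities whose top-3 mean targets the protein abundance.

    Each protein carries 1-8 peptides with fixed relative propensities scaled
    so the mean of the three most intense equals 1; per-sample intensities are
    the protein's noise-free target abundance times these propensities, times
    multiplicative noise at noise_cv (zero noise gives exact Hi3 recovery).
    """
    rng = derive_seed(cfg.seed, "peptides")
    ids = _protein_ids(cfg.n_proteins)
    meta = _sample_frame(cfg)
    base = 10.0 ** derive_seed(cfg.seed, "abundance").normal(
        cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_proteins
    )
    arch_map = _archetype_assignment(cfg)
    archetypes = np.array([arch_map.get(pid, 0) for pid in ids])

    n_pep = rng.integers(1, 9, size=cfg.n_proteins)
    propensities = []
    for npep in n_pep:
        f = np.sort(10.0 ** rng.normal(0.0, 0.4, size=int(npep)))[::-1]
        top = f[: min(3, len(f))]
        propensities.append(f / top.mean())  # top-3 mean scaled to exactly 1

    records = []
    for _, row in meta.iterrows():
        mu = expected_abundance(cfg, base, archetypes, row.condition, row.day)
        for i, pid in enumerate(ids):
            noise = _lognormal_factor(rng, cfg.noise_cv, len(propensities[i]))
            for k, (f, eps) in enumerate(zip(propensities[i], noise), start=1):
                records.append((pid, f"{pid}_pep{k}", row.sample_id, mu[i] * f * eps))
    table = pd.DataFrame(records, columns=["protein_id", "peptide_id", "sample_id", "intensity"])
    return PeptideTable(table, meta)


def generate_network(cfg: SyntheticConfig) -> tuple[nx.Graph, GroundTruth]:
    """Random interaction network with optional planted clique and central set.

    Edge confidence scores are uniform in [0, 1]; planted-clique edges get
    scores >= 0.9 so they survive any confidence threshold below that.
    Central-set nodes receive extra random edges (a degree boost).
    """
    rng = derive_seed(cfg.seed, "network")
    n = cfg.n_nodes
    # nodes share the protein-id namespace so abundance and network fixtures
    # overlap when their sizes agree
    names = dict(enumerate(_protein_ids(n)))

    if cfg.network_model == "erdos_renyi":
        g = nx.gnp_random_graph(n, cfg.edge_param, seed=int(rng.integers(2**31)))
    else:
        m = max(1, int(round(cfg.edge_param)))
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, names)

    truth = GroundTruth()
    if cfg.planted_clique > 0:
        clique = [names[i] for i in rng.choice(n, size=cfg.planted_clique, replace=False)]
        for i, u in enumerate(clique):
            for v in clique[i + 1 :]:
                g.add_edge(u, v)
        truth.planted_module = set(clique)

    if cfg.planted_central > 0:
        avail = sorted(set(g.nodes) - truth.planted_module)
        central = [avail[i] for i in rng.choice(len(avail), size=cfg.planted_central, replace=False)]
        mean_deg = max(2, int(np.ceil(2 * g.number_of_edges() / max(1, n))))
        others = np.array(sorted(g.nodes))
        for u in central:
            targets = rng.choice(others, size=3 * mean_deg, replace=False)
            for v in targets:
                if v != u:
                    g.add_edge(u, str(v))
        truth.planted_central_set = set(central)

    g.remove_edges_from(nx.selfloop_edges(g))
    for u, v in g.edges:
        in_clique = u in truth.planted_module and v in truth.planted_module
        lo = 0.9 if in_clique else 0.0
        g.edges[u, v]["combined_score"] = float(lo + (1 - lo) * rng.uniform())
    return g, truth


def generate_annotations(cfg: SyntheticConfig, n_terms: int | None = None) -> AnnotationCollection:
    """Random GMT-style term sets over the generated protein universe.

    One term, ``PLANTED``, exactly covers the first min(20, n) altered proteins
    (or the first proteins if none are altered) for enrichment recovery tests.
    """
    rng = derive_seed(cfg.seed, "annotations")
    ids = _protein_ids(cfg.n_proteins)
    if n_terms is None:
        n_terms = max(10, cfg.n_proteins // 20)
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for t in range(1, n_terms + 1):
        size = int(rng.integers(5, min(51, max(6, cfg.n_proteins))))
        members = rng.choice(ids, size=min(size, cfg.n_proteins), replace=False)
        term = f"T{t:04d}"
        terms[term] = set(members.tolist())
        names[term] = f"random term {t}"
    planted_pool = _protein_ids(cfg.n_proteins)[: cfg.n_altered] or ids
    planted = planted_pool[: min(20, len(planted_pool))]
    terms["PLANTED"] = set(planted)
    names["PLANTED"] = "planted coherent term"
    return AnnotationCollection(terms, names, set(ids))


def write_network_tsv(g: nx.Graph, path: str | Path) -> None:
    """Write a 3-column edge list in the STRING links dialect (0-1 scores)."""
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u} {v} {g.edges[u, v].get('combined_score', 1.0):.3f}\n")


def write_dataset(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture set (matrix, meta, network, GMT)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_abundance_dataset(cfg)
    net, net_truth = generate_network(cfg)
    ann = generate_annotations(cfg)
    paths = {
        "matrix": outdir / "abundance.tsv",
        "meta": outdir / "samples.tsv",
        "links": outdir / "links.txt",
        "gmt": outdir / "annotations.gmt",
        "truth": outdir / "ground_truth.tsv",
    }
    matrix.to_tsv(paths["matrix"], paths["meta"])
    write_network_tsv(net, paths["links"])
    ann.write_gmt(paths["gmt"])
    rows = [(pid, truth.archetype_of[pid]) for pid in sorted(truth.altered_ids)]
    pd.DataFrame(rows, columns=["protein_id", "archetype"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths
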