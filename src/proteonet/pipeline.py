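"""End-to-end orchestration of the analysis from a single config.

Stage order: preprocessing (Hi3 rollup if peptides are supplied, detection-
floor imputation, quantile normalisation) -> consensus differential abundance
under the condition design (disease vs healthy over shared days) and under the
time-only design on healthy samples (normal-ageing alterations) -> set
comparison -> Gaussian-mixture profile clustering with BIC selection ->
permutation network statistics of the altered set -> MCODE dense modules on
the altered-plus-neighbours subgraph -> overrepresentation analysis.  Every
stochastic component derives its seed from the single root seed; re-running an
identical config reproduces an identical report content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import yaml

from . import clustering, differential, enrichment, modules, network, preprocess, synthetic
from .containers import AbundanceMatrix, AnnotationCollection, PeptideTable


@dataclasses.dataclass
class PipelineConfig:
    """Inputs, stage toggles and stage parameters for one run."""

    # inputs: either a synthetic block or file paths
    synthetic: synthetic.SyntheticConfig | None = None
    peptides_path: str | None = None
    matrix_path: str | None = None
    meta_path: str | None = None
    links_path: str | None = None
    gmt_path: str | None = None
    # stage parameters
    score_threshold: float = 0.5
    detectors: tuple[str, ...] = ("moderated_f", "nb_lrt", "poly_lrt")
    alpha: float = 0.05
    votes: int = 2
    k_max: int | None = 10
    permutations: int = 10_000
    mcode_score_cutoff: float | None = None
    seed: int = 0
    # stage toggles
    run_clustering: bool = True
    run_network: bool = True
    run_modules: bool = True
    run_enrichment: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "archetype_fractions" in syn:
                syn["archetype_fractions"] = tuple(syn["archetype_fractions"])
            for key in ("timepoints_disease", "timepoints_healthy"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        if isinstance(cfg.detectors, list):
            cfg.detectors = tuple(cfg.detectors)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def validate_config(config: PipelineConfig) -> list[tuple[str, str]]:
    """Return (level, message) findings; errors do not raise here."""
    findings: list[tuple[str, str]] = []
    if config.votes > len(config.detectors):
        findings.append(("error", f"votes={config.votes} exceeds the {len(config.detectors)} detectors"))
    if not 0 < config.alpha < 1:
        findings.append(("error", f"alpha={config.alpha} outside (0, 1)"))
    if config.permutations < 1000:
        findings.append(("warning", f"permutations={config.permutations} < 1000: P values will be coarse"))
    if config.synthetic is None and config.matrix_path is None and config.peptides_path is None:
        findings.append(("error", "no input: provide a synthetic block, a matrix or a peptide table"))
    for label in ("peptides_path", "matrix_path", "meta_path", "links_path", "gmt_path"):
        p = getattr(config, label)
        if p is not None and not Path(p).exists():
            findings.append(("error", f"{label} does not exist: {p}"))
    if not 0 <= config.score_threshold <= 1:
        findings.append(("error", f"score_threshold={config.score_threshold} outside [0, 1]"))
    return findings


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _canonical(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        return [_canonical(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(np.round(float(obj), 12))
    if isinstance(obj, np.ndarray):
        return [_canonical(v) for v in obj.tolist()]
    return obj


def report_hash(report: dict) -> str:
    body = {k: v for k, v in report.items() if k != "content_hash"}
    payload = json.dumps(_canonical(body), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _load_inputs(config: PipelineConfig):
    truth = None
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.synthetic.seed or config.seed)
        matrix, truth = synthetic.generate_abundance_dataset(syn)
        net, net_truth = synthetic.generate_network(syn)
        truth.planted_module = net_truth.planted_module
        truth.planted_central_set = net_truth.planted_central_set
        annotations = synthetic.generate_annotations(syn)
        return matrix, net, annotations, truth
    if config.peptides_path is not None:
        table = PeptideTable.from_tsv(config.peptides_path, config.meta_path)
        matrix = preprocess.hi3_rollup(table)
    elif config.matrix_path is not None:
        matrix = AbundanceMatrix.from_tsv(config.matrix_path, config.meta_path)
    else:
        raise StageError("input", "no abundance input configured")
    net = None
    if config.links_path is not None:
        net = network.read_string_links(config.links_path, config.score_threshold)
    annotations = None
    if config.gmt_path is not None:
        annotations = AnnotationCollection.read_gmt(config.gmt_path)
    return matrix, net, annotations, truth


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all configured stages and return the run report."""
    errors = [msg for lvl, msg in validate_config(config) if lvl == "error"]
    if errors:
        raise StageError("config", "; ".join(errors))
    report: dict[str, Any] = {"config": config.to_dict(), "seed": config.seed}

    try:
        matrix, net, annotations, truth = _load_inputs(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", str(exc)) from exc

    # ---- preprocess -------------------------------------------------------
    try:
        imputed = preprocess.impute_missing(matrix)
        norm = preprocess.quantile_normalise(imputed)
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc
    report["preprocess"] = {
        "n_proteins": int(norm.values.shape[0]),
        "n_samples": int(norm.values.shape[1]),
        "n_imputed": matrix.n_missing(),
        "provenance": norm.log,
    }

    # ---- differential: disease design and ageing (time-only) design -------
    try:
        consensus_ad, detectors_ad = differential.run_consensus(
            norm, mode="condition", detectors=config.detectors,
            alpha=config.alpha, threshold=config.votes,
        )
        healthy_ids = norm.meta.index[norm.meta["condition"] == "healthy"]
        healthy = norm.select_samples(healthy_ids)
        consensus_age, _ = differential.run_consensus(
            healthy, mode="time", detectors=config.detectors,
            alpha=config.alpha, threshold=config.votes,
        )
        labels = differential.compare_condition_sets(consensus_ad, consensus_age)
        sizes = differential.set_sizes(labels)
    except Exception as exc:
        raise StageError("differential", str(exc)) from exc
    sig_ids = sorted(consensus_ad.significant_ids)
    report["differential"] = {
        "n_significant_ad": len(sig_ids),
        "n_significant_ageing": len(consensus_age.significant_ids),
        "set_sizes": sizes,
        "detectors": {r.name: int((r.table["q"] < config.alpha).sum()) for r in detectors_ad},
    }

    # ---- profile clustering ------------------------------------------------
    if config.run_clustering and len(sig_ids) >= 2:
        try:
            profiles = clustering.build_profile_matrix(norm, sig_ids)
            trace = clustering.select_cluster_count(
                profiles, k_max=config.k_max, root_seed=config.seed
            )
            assignment = clustering.assign_profiles(trace.fits[trace.selected_k], profiles)
        except Exception as exc:
            raise StageError("profile_clustering", str(exc)) from exc
        report["profile_clustering"] = {
            "selected_k": trace.selected_k,
            "bic": {str(k): float(v) for k, v in trace.bic.items()},
            "cluster_sizes": assignment["cluster"].value_counts().sort_index().to_dict(),
        }
    else:
        report["profile_clustering"] = {"skipped": True, "n_significant": len(sig_ids)}

    # ---- network statistics -----------------------------------------------
    analysis_net = None
    if config.run_network and net is not None:
        try:
            universe = set(norm.values.index)
            analysis_net = network.induce_lcc_subgraph(net, universe & set(net.nodes))
            sig_in_net = sorted(set(sig_ids) & set(analysis_net.nodes))
            section: dict[str, Any] = {
                "n_nodes": analysis_net.number_of_nodes(),
                "n_edges": analysis_net.number_of_edges(),
                "n_significant_in_network": len(sig_in_net),
            }
            if len(sig_in_net) >= 2:
                observed, pvals = network.node_set_significance(
                    analysis_net, sig_in_net,
                    n_samples=config.permutations, seed=config.seed,
                )
                section["observed"] = observed.as_dict()
                section["p_values"] = pvals
            hb = network.classify_hub_bottleneck(analysis_net)
            section["hub_bottleneck_counts"] = hb["class"].value_counts().to_dict()
            report["network_stats"] = section
        except Exception as exc:
            raise StageError("network_stats", str(exc)) from exc
    else:
        report["network_stats"] = {"skipped": True}

    # ---- dense modules ------------------------------------------------------
    if config.run_modules and net is not None and sig_ids:
        try:
            present = set(sig_ids) & set(net.nodes)
            if present:
                neigh = modules.neighbourhood_subgraph(net, present)
                params = modules.MCODEParams(score_cutoff=config.mcode_score_cutoff)
                found = modules.find_modules(neigh, params)
                report["module_detection"] = {
                    "subgraph_nodes": neigh.number_of_nodes(),
                    "subgraph_edges": neigh.number_of_edges(),
                    "n_modules": len(found),
                    "modules": [
                        {
                            "score": m.score,
                            "size": m.size,
                            "query_fraction": modules.module_query_fraction(m, set(sig_ids)),
                        }
                        for m in found
                    ],
                }
            else:
                report["module_detection"] = {"skipped": True, "reason": "no significant protein in network"}
        except Exception as exc:
            raise StageError("module_detection", str(exc)) from exc
    else:
        report["module_detection"] = {"skipped": True}

    # ---- enrichment ---------------------------------------------------------
    if config.run_enrichment and annotations is not None and sig_ids:
        try:
            restricted = annotations.restrict_to_universe(set(norm.values.index))
            table = enrichment.fisher_overrepresentation(sig_ids, restricted)
            hits = table[table["q"] < config.alpha]
            report["enrichment"] = {
                "n_terms_tested": int(len(table)),
                "n_enriched": int(len(hits)),
                "top_terms": hits.sort_values("p").head(10).index.tolist(),
            }
        except Exception as exc:
            raise StageError("enrichment", str(exc)) from exc
    else:
        report["enrichment"] = {"skipped": True}

    report["content_hash"] = report_hash(report)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        norm.to_tsv(outdir / "normalised_matrix.tsv", outdir / "samples.tsv")
        consensus_ad.table.to_csv(outdir / "consensus_ad.tsv", sep="\t")
        consensus_age.table.to_csv(outdir / "consensus_ageing.tsv", sep="\t")
        labels.to_csv(outdir / "set_labels.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(_canonical(report), fh, indent=2, sort_keys=True)
        with open(outdir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
    return report
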