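"""End-to-end orchestration: load -> similarities -> features -> CV -> ranking.

A run loads the association list and ontology, computes the semantic and GIP
similarity matrices, integrates them, samples positive/negative pairs,
builds pair features, evaluates the reduced-feature random forest under
cross-validation, refits on all sampled pairs and ranks candidate lncRNAs
per disease.  Every intermediate matrix is written to the output directory
in the package's TSV formats, together with a manifest (config, seed,
versions, stage timings) sufficient to replay the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .data_io import (build_association_matrix, load_associations, load_ontology,
                      read_matrix, write_association_matrix, write_matrix,
                      LabelledMatrix)
from .features import build_features, sample_pairs
from .gip import gip_kernel, integrate_disease_similarity, integrate_lncrna_similarity
from .ipca import IPCAModel
from .model_eval import (CVReport, PipelineSpec, RFConfig, cross_validate,
                         fit_final_model, grid_search_n_estimators, rank_candidates)
from .semantic import SemSimConfig, SimilarityMatrix, semantic_similarity

logger = logging.getLogger("ipcarf")


@dataclass
class RunConfig:
    associations: str
    ontology: str | None = None
    disease_terms: str | None = None        # optional disease->term mapping (TSV)
    disease_similarity: str | None = None   # optional precomputed matrix (TSV)
    lncrna_similarity: str | None = None    # optional functional similarity (TSV)
    delta: float = 0.5
    semantic_model: str = "average"
    neg_ratio: float = 1.0
    use_ipca: bool = True
    k: int | None = None
    n_components: int | None = None
    n_estimators: int = 1500
    grid: list[int] | None = None           # when set, grid-search n_estimators first
    folds: int = 10
    seed: int = 42
    out_dir: str = "ipcarf_run"
    rank_diseases: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**payload)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def _load_disease_terms(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        fields = s.split("\t")
        if len(fields) != 2:
            raise ValueError(f"disease-term mapping line is not 'disease<TAB>term': {line!r}")
        mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def _semantic_for(A_dis_labels: list[str], config: RunConfig) -> tuple[SimilarityMatrix | None, set[str]]:
    """Semantic similarity over association diseases; coverage = diseases scored."""
    if config.disease_similarity:
        pre = read_matrix(config.disease_similarity)
        covered = [d for d in A_dis_labels if d in pre.row_labels]
        values = np.eye(len(A_dis_labels))
        idx = {d: pre.row_labels.index(d) for d in covered}
        for a in covered:
            for b in covered:
                values[A_dis_labels.index(a), A_dis_labels.index(b)] = pre.values[idx[a], idx[b]]
        np.fill_diagonal(values, 1.0)
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        return SimilarityMatrix(values, list(A_dis_labels), kind="semantic"), set(covered)
    if not config.ontology:
        return None, set()
    onto = load_ontology(config.ontology)
    term_of = {d: d for d in A_dis_labels}
    if config.disease_terms:
        term_of.update(_load_disease_terms(config.disease_terms))
    covered = [d for d in A_dis_labels if term_of[d] in onto.terms]
    if not covered:
        logger.warning("no association disease maps into the ontology; semantic stage skipped")
        return None, set()
    sem_cov = semantic_similarity(onto, [term_of[d] for d in covered],
                                  SemSimConfig(delta=config.delta, model=config.semantic_model))
    values = np.eye(len(A_dis_labels))
    pos = {d: i for i, d in enumerate(A_dis_labels)}
    for a_idx, a in enumerate(covered):
        for b_idx, b in enumerate(covered):
            values[pos[a], pos[b]] = sem_cov.values[a_idx, b_idx]
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(A_dis_labels), kind="semantic"), set(covered)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict[str, Any] = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "version": __version__,
        "stages": timings,
    }

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return _Timer()

    with stage("load"):
        table = load_associations(config.associations)
        A = build_association_matrix(table)
        write_association_matrix(A, out / "assoc_matrix.tsv")
        manifest["n_lnc"], manifest["n_dis"] = A.n_lnc, A.n_dis
        manifest["n_positive"] = int(A.values.sum())

    with stage("semantic_similarity"):
        sem, coverage = _semantic_for(A.dis_labels, config)
        if sem is not None:
            write_matrix(LabelledMatrix(sem.values, sem.labels, sem.labels), out / "semantic.tsv")

    with stage("gip_similarity"):
        gip_dis = gip_kernel(A, "disease")
        gip_lnc = gip_kernel(A, "lncrna")
        write_matrix(LabelledMatrix(gip_dis.values, gip_dis.labels, gip_dis.labels), out / "gip_disease.tsv")
        write_matrix(LabelledMatrix(gip_lnc.values, gip_lnc.labels, gip_lnc.labels), out / "gip_lncrna.tsv")

    with stage("integrate"):
        sim_dis = integrate_disease_similarity(sem, gip_dis, coverage) if sem is not None else gip_dis
        functional = None
        if config.lncrna_similarity:
            pre = read_matrix(config.lncrna_similarity)
            if pre.row_labels == gip_lnc.labels:
                functional = SimilarityMatrix(pre.values, pre.row_labels, kind="semantic")
            else:
                logger.warning("lncRNA functional similarity labels do not match; ignored")
        sim_lnc = integrate_lncrna_similarity(gip_lnc, functional)
        write_matrix(LabelledMatrix(sim_dis.values, sim_dis.labels, sim_dis.labels), out / "sim_disease.tsv")
        write_matrix(LabelledMatrix(sim_lnc.values, sim_lnc.labels, sim_lnc.labels), out / "sim_lncrna.tsv")

    with stage("features"):
        pairs = sample_pairs(A, neg_ratio=config.neg_ratio, seed=config.seed)
        dataset = build_features(pairs, sim_lnc, sim_dis)
        manifest["n_samples"], manifest["n_features"] = dataset.features.shape

    spec = PipelineSpec(config.use_ipca, config.k, config.n_components,
                        RFConfig(config.n_estimators, seed=config.seed))
    if config.grid:
        with stage("grid_search"):
            best, score_table = grid_search_n_estimators(
                dataset, grid=config.grid, folds=min(5, config.folds), seed=config.seed, spec=spec)
            spec.rf.n_estimators = best
            manifest["grid_search"] = {"best_n_estimators": best,
                                       "scores": {str(n): v for n, v in score_table.items()}}

    with stage("cross_validate"):
        report: CVReport = cross_validate(spec, dataset, folds=config.folds, seed=config.seed)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1), encoding="utf-8")
        manifest["cv_mean_auc"] = report.mean_auc

    with stage("final_fit_and_rank"):
        reducer, clf = fit_final_model(spec, dataset, seed=config.seed)
        if isinstance(reducer, IPCAModel):
            reducer.to_json(out / "ipca_model.json")
        rankings: dict[str, list[tuple[str, float]]] = {}
        for disease in config.rank_diseases:
            rankings[disease] = rank_candidates(clf, disease, A, sim_lnc, sim_dis, reducer)
        if rankings:
            (out / "rankings.json").write_text(json.dumps(rankings, indent=1), encoding="utf-8")
        manifest["ranked_diseases"] = list(rankings)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    logger.info("run complete: CV mean AUC %.4f -> %s", manifest["cv_mean_auc"], out)
    return manifest
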