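"""Synthetic ontologies and association matrices with planted structure.

The generator emulates the two inputs the pipeline needs — a rooted disease
ontology DAG and a binary lncRNA x disease association matrix — with a
planted-block model: lncRNAs and diseases are partitioned into blocks, and
within-block pairs associate with probability ``signal`` against a
``noise`` background.  Block structure is exactly the premise the method
rests on (similar diseases share associated lncRNAs), so the planted blocks
give a tunable ground truth for evaluating recovery.  Diseases in the same
block are also attached near each other in the DAG, so semantic similarity
carries the same signal as the interaction profiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data_io import (AssociationMatrix, DiseaseOntology, write_association_matrix,
                      write_ontology)
from .features import FeatureTable, build_features, sample_pairs
from .gip import gip_kernel, integrate_disease_similarity, integrate_lncrna_similarity
from .semantic import SemSimConfig, SimilarityMatrix, semantic_similarity

logger = logging.getLogger("ipcarf")


@dataclass
class SyntheticConfig:
    n_lnc: int = 80
    n_dis: int = 40
    n_terms: int = 60
    n_clusters: int = 4
    signal: float = 0.6
    noise: float = 0.05
    max_depth: int = 4
    neg_ratio: float = 1.0
    delta: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_lnc, self.n_dis, self.n_terms, self.n_clusters, self.max_depth) < 1:
            raise ValueError("sizes must be positive")
        if self.n_terms < self.n_dis:
            raise ValueError("need at least one ontology term per disease")
        for p in (self.signal, self.noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("signal and noise must be probabilities")
        if self.signal <= self.noise:
            logger.warning("signal <= noise: the planted structure is not learnable")


@dataclass
class SyntheticDataset:
    ontology: DiseaseOntology
    disease_terms: dict[str, str]     # disease label -> ontology term
    associations: AssociationMatrix
    lnc_blocks: dict[str, int]
    dis_blocks: dict[str, int]
    sim_lnc: SimilarityMatrix
    sim_dis: SimilarityMatrix
    features: FeatureTable
    config: SyntheticConfig


def generate_ontology(config: SyntheticConfig) -> tuple[DiseaseOntology, dict[str, str]]:
    """Random rooted DAG plus a leaf-biased disease->term mapping.

    Terms are laid down in depth layers under a single root; each non-root
    term picks 1-2 parents among strictly shallower terms, which makes the
    graph acyclic by construction.  Diseases from the same planted block are
    mapped to terms under the same depth-1 branch, so block-mates are
    semantically close.
    """
    rng = np.random.default_rng(config.seed)
    terms = [f"T{idx:04d}" for idx in range(config.n_terms)]
    root = terms[0]
    depth = {root: 0}
    edges: set[tuple[str, str]] = set()
    # depth-1 branch anchors, one per planted block where possible
    n_branches = min(config.n_clusters, config.n_terms - 1)
    branch_heads = terms[1:1 + n_branches]
    for head in branch_heads:
        depth[head] = 1
        edges.add((head, root))
    branch_members: dict[int, list[str]] = {b: [head] for b, head in enumerate(branch_heads)}
    for idx, term in enumerate(terms[1 + n_branches:]):
        block = idx % max(len(branch_heads), 1) if branch_heads else 0
        pool = branch_members.get(block, [root])
        shallow = [t for t in pool if depth[t] < config.max_depth]
        if not shallow:
            shallow = [root]  # keep the depth bound; attach directly under the root
        n_par = int(rng.integers(1, 3)) if len(shallow) > 1 else 1
        parents = rng.choice(len(shallow), size=min(n_par, len(shallow)), replace=False)
        pdepth = 0
        for pi in parents:
            edges.add((term, shallow[pi]))
            pdepth = max(pdepth, depth[shallow[pi]])
        depth[term] = pdepth + 1
        branch_members.setdefault(block, []).append(term)
    onto = DiseaseOntology(terms=set(terms), edges=edges)

    # leaf-biased mapping: deepest terms of each branch are used first
    disease_terms: dict[str, str] = {}
    used: set[str] = set()
    dis_labels = [f"disease_{idx:03d}" for idx in range(config.n_dis)]
    for d_idx, dis in enumerate(dis_labels):
        block = d_idx * config.n_clusters // config.n_dis
        pool = branch_members.get(block % max(len(branch_heads), 1), [root]) if branch_heads else [root]
        free = sorted((t for t in pool if t not in used), key=lambda t: (-depth[t], t))
        if not free:
            free = sorted((t for t in terms if t not in used), key=lambda t: (-depth[t], t))
        disease_terms[dis] = free[0]
        used.add(free[0])
    return onto, disease_terms


def generate_associations(config: SyntheticConfig) -> tuple[AssociationMatrix, dict[str, int], dict[str, int]]:
    """Planted-block binary matrix: within-block prob = signal, else noise."""
    rng = np.random.default_rng(config.seed + 1)
    lnc_labels = [f"lnc_{idx:03d}" for idx in range(config.n_lnc)]
    dis_labels = [f"disease_{idx:03d}" for idx in range(config.n_dis)]
    lnc_blocks = {l: i * config.n_clusters // config.n_lnc for i, l in enumerate(lnc_labels)}
    dis_blocks = {d: j * config.n_clusters // config.n_dis for j, d in enumerate(dis_labels)}
    lb = np.array([lnc_blocks[l] for l in lnc_labels])
    db = np.array([dis_blocks[d] for d in dis_labels])
    same = lb[:, None] == db[None, :]
    prob = np.where(same, config.signal, config.noise)
    values = (rng.random(prob.shape) < prob).astype(np.int8)
    return AssociationMatrix(values, lnc_labels, dis_labels), lnc_blocks, dis_blocks


def assemble_features(ontology: DiseaseOntology, disease_terms: dict[str, str],
                      A: AssociationMatrix, delta: float = 0.5, neg_ratio: float = 1.0,
                      seed: int = 0) -> tuple[SimilarityMatrix, SimilarityMatrix, FeatureTable]:
    """Similarity integration + pair sampling + feature building for a given matrix."""
    term_list = [disease_terms[d] for d in A.dis_labels]
    sem_terms = semantic_similarity(ontology, term_list, SemSimConfig(delta=delta))
    sem = SimilarityMatrix(sem_terms.values, list(A.dis_labels), kind="semantic")
    gip_dis = gip_kernel(A, "disease")
    gip_lnc = gip_kernel(A, "lncrna")
    sim_dis = integrate_disease_similarity(sem, gip_dis, coverage=set(A.dis_labels))
    sim_lnc = integrate_lncrna_similarity(gip_lnc)
    pairs = sample_pairs(A, neg_ratio=neg_ratio, seed=seed)
    return sim_lnc, sim_dis, build_features(pairs, sim_lnc, sim_dis)


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Run the real pipeline stages end-to-end on generated inputs."""
    config = config or SyntheticConfig()
    onto, disease_terms = generate_ontology(config)
    A, lnc_blocks, dis_blocks = generate_associations(config)
    sim_lnc, sim_dis, features = assemble_features(
        onto, disease_terms, A, delta=config.delta, neg_ratio=config.neg_ratio,
        seed=config.seed + 2)
    return SyntheticDataset(onto, disease_terms, A, lnc_blocks, dis_blocks,
                            sim_lnc, sim_dis, features, config)


def mask_positives(A: AssociationMatrix, fraction: float,
                   seed: int = 0) -> tuple[AssociationMatrix, list[tuple[str, str]]]:
    """Hide a random fraction of the known associations.

    Returns the masked matrix and the hidden (lncRNA, disease) pairs; used to
    test whether the pipeline rediscovers held-out associations.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pos = np.argwhere(A.values == 1)
    n_mask = max(1, int(round(fraction * len(pos))))
    chosen = pos[rng.choice(len(pos), size=n_mask, replace=False)]
    values = A.values.copy()
    values[chosen[:, 0], chosen[:, 1]] = 0
    masked_pairs = [(A.lnc_labels[i], A.dis_labels[j]) for i, j in chosen]
    return AssociationMatrix(values, list(A.lnc_labels), list(A.dis_labels)), masked_pairs


def save_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the bundle in the pipeline's standard file formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ontology(ds.ontology, out / "dag.tsv")
    write_association_matrix(ds.associations, out / "assoc_matrix.tsv")
    with (out / "assoc.tsv").open("w", encoding="utf-8") as fh:
        fh.write("LncRNA name\tDisease name\tDysfunction type\n")
        for i, l in enumerate(ds.associations.lnc_labels):
            for j, d in enumerate(ds.associations.dis_labels):
                if ds.associations.values[i, j]:
                    fh.write(f"{l}\t{d}\tregulation\n")
    truth = {
        "config": asdict(ds.config),
        "lnc_blocks": ds.lnc_blocks,
        "dis_blocks": ds.dis_blocks,
        "disease_terms": ds.disease_terms,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1), encoding="utf-8")
    with (out / "diseases.txt").open("w", encoding="utf-8") as fh:
        for d in ds.associations.dis_labels:
            fh.write(f"{d}\t{ds.disease_terms[d]}\n")
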