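"""Disease-disease semantic similarity on an ontology DAG.

Two models are provided.  Model 1 is the contribution-decay model: a disease
D contributes 1 to itself, and each ancestor term i receives the decayed
contribution

    C_D(i) = max{ delta * C_D(i') : i' a child of i inside DAG(D) },

where DAG(D) is D together with all of its ancestors and delta in [0, 1] is
the attenuation factor.  The semantic value G(D) is the sum of contributions
over DAG(D), and the similarity of two diseases is the mass their shared
ancestors carry relative to their total semantic values:

    sim1(D1, D2) = sum_{i in DAG(D1) ^ DAG(D2)} (C_D1(i) + C_D2(i))
                   / (G(D1) + G(D2)).

Model 2 replaces the decayed contribution with the information content of
each term over the disease corpus being compared, -log(freq(t)), combined by
the same ratio form; terms carried by every disease in the corpus have zero
information and contribute nothing.  Under either model the matrix is
symmetric with unit diagonal and entries in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .data_io import DiseaseOntology

logger = logging.getLogger("ipcarf")

DEFAULT_DELTA = 0.5  # decay per generation; the customary value in this model family


class SemanticModel(str, Enum):
    MODEL1 = "model1"
    MODEL2 = "model2"
    AVERAGE = "average"


class CombineMode(str, Enum):
    AVERAGE = "average"
    MODEL1_ONLY = "model1_only"
    MODEL2_ONLY = "model2_only"


@dataclass
class SemSimConfig:
    delta: float = DEFAULT_DELTA
    model: SemanticModel = SemanticModel.AVERAGE

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        self.model = SemanticModel(self.model)


@dataclass
class ContributionMap:
    """Per-ancestor decayed contributions C_D(i) for one disease."""

    disease: str
    contributions: dict[str, float]
    semantic_value: float

    def __post_init__(self) -> None:
        assert self.contributions[self.disease] == 1.0


@dataclass
class SimilarityMatrix:
    """Labelled square symmetric matrix with unit diagonal, entries in [0, 1]."""

    values: np.ndarray
    labels: list[str]
    kind: str = "semantic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label: {label!r}") from None

    def row(self, label: str) -> np.ndarray:
        return self.values[self.index(label)]


def ancestor_closure(ontology: DiseaseOntology, disease: str) -> set[str]:
    """DAG(D): the disease itself plus every ancestor reachable child->parent."""
    if disease not in ontology.terms:
        raise KeyError(f"unknown ontology term: {disease!r}")
    parents: dict[str, set[str]] = {}
    for c, p in ontology.edges:
        parents.setdefault(c, set()).add(p)
    closure = {disease}
    frontier = [disease]
    while frontier:
        term = frontier.pop()
        for p in parents.get(term, ()):
            if p not in closure:
                closure.add(p)
                frontier.append(p)
    return closure


def compute_contributions(ontology: DiseaseOntology, disease: str, delta: float = DEFAULT_DELTA) -> ContributionMap:
    """Decay recursion over DAG(D): C_D(D)=1, C_D(i)=max over closure children of delta*C.

    Only children lying inside DAG(D) pass contribution upward; with a
    uniform delta this makes C_D(i) = delta^(shortest hop count from D to i).
    """
    closure = ancestor_closure(ontology, disease)
    # children restricted to the closure, indexed by parent
    children: dict[str, list[str]] = {t: [] for t in closure}
    for c, p in ontology.edges:
        if c in closure and p in closure:
            children[p].append(c)

    memo: dict[str, float] = {disease: 1.0}

    def contrib(term: str) -> float:
        if term in memo:
            return memo[term]
        best = max(delta * contrib(ch) for ch in children[term])
        memo[term] = best
        return best

    contributions = {t: contrib(t) for t in closure}
    return ContributionMap(disease, contributions, sum(contributions.values()))


def _ratio_similarity(maps: dict[str, dict[str, float]], sem_values: dict[str, float],
                      diseases: list[str], kind: str) -> SimilarityMatrix:
    """Shared ratio form: mass of shared terms over total semantic value."""
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = maps[diseases[i]], maps[diseases[j]]
            shared = mi.keys() & mj.keys()
            denom = sem_values[diseases[i]] + sem_values[diseases[j]]
            if denom <= 0.0:
                # zero semantic mass (possible under model 2 when every term is
                # corpus-wide); no evidence either way -> similarity 0
                sim = 0.0
            else:
                sim = sum(mi[t] + mj[t] for t in shared) / denom
            values[i, j] = values[j, i] = min(sim, 1.0)
    return SimilarityMatrix(values, list(diseases), kind=kind)


def semsim_model1(ontology: DiseaseOntology, diseases: list[str],
                  delta: float = DEFAULT_DELTA) -> SimilarityMatrix:
    """Contribution-decay semantic similarity matrix over the given diseases."""
    if not diseases:
        raise ValueError("empty disease list")
    maps = {d: compute_contributions(ontology, d, delta) for d in diseases}
    return _ratio_similarity(
        {d: m.contributions for d, m in maps.items()},
        {d: m.semantic_value for d, m in maps.items()},
        list(diseases), kind="semantic",
    )


def semsim_model2(ontology: DiseaseOntology, diseases: list[str]) -> SimilarityMatrix:
    """Information-content semantic similarity over the disease corpus.

    Each term t in DAG(D) contributes IC(t) = -log(n_t / N), where n_t counts
    diseases of the corpus whose closure contains t.  Shared-by-all terms
    carry no information.  Combined by the same ratio form as model 1.
    """
    if not diseases:
        raise ValueError("empty disease list")
    closures = {d: ancestor_closure(ontology, d) for d in diseases}
    n_total = len(diseases)
    term_count: dict[str, int] = {}
    for cl in closures.values():
        for t in cl:
            term_count[t] = term_count.get(t, 0) + 1
    ic = {t: -math.log(c / n_total) for t, c in term_count.items()}
    maps = {d: {t: ic[t] for t in cl} for d, cl in closures.items()}
    sem_values = {d: sum(m.values()) for d, m in maps.items()}
    sim = _ratio_similarity(maps, sem_values, list(diseases), kind="semantic")
    # a disease whose closure carries zero total information is still
    # identical to itself
    np.fill_diagonal(sim.values, 1.0)
    return sim


def combine_models(s1: SimilarityMatrix, s2: SimilarityMatrix,
                   mode: CombineMode | str = CombineMode.AVERAGE) -> SimilarityMatrix:
    """Element-wise combination of the two semantic models."""
    mode = CombineMode(mode)
    if s1.labels != s2.labels:
        raise ValueError("similarity matrices have different labels")
    if mode is CombineMode.MODEL1_ONLY:
        return s1
    if mode is CombineMode.MODEL2_ONLY:
        return s2
    return SimilarityMatrix((s1.values + s2.values) / 2.0, list(s1.labels), kind="semantic")


def semantic_similarity(ontology: DiseaseOntology, diseases: list[str],
                        config: SemSimConfig | None = None) -> SimilarityMatrix:
    """Compute the configured semantic similarity (model 1, model 2 or their mean)."""
    config = config or SemSimConfig()
    if config.model is SemanticModel.MODEL1:
        return semsim_model1(ontology, diseases, config.delta)
    if config.model is SemanticModel.MODEL2:
        return semsim_model2(ontology, diseases)
    return combine_models(
        semsim_model1(ontology, diseases, config.delta),
        semsim_model2(ontology, diseases),
        CombineMode.AVERAGE,
    )
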