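"""Per-pair feature construction with balanced negative sampling.

Each lncRNA-disease pair becomes one sample: label 1 if the pair is a known
association, 0 for a sampled unassociated pair.  Its feature vector is the
lncRNA's row of the integrated lncRNA-similarity matrix concatenated with
the disease's row of the integrated disease-similarity matrix, giving width
n_lnc + n_dis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix
from .semantic import SimilarityMatrix

logger = logging.getLogger("ipcarf")


@dataclass(frozen=True)
class PairSample:
    lncrna: str
    disease: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class FeatureTable:
    features: np.ndarray            # samples x (n_lnc + n_dis)
    labels: np.ndarray              # binary vector
    pair_ids: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.pair_ids) == len(self.labels) == self.features.shape[0]):
            raise ValueError("features, labels and pair_ids must have equal length")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")

    def __len__(self) -> int:
        return self.features.shape[0]


def sample_pairs(A: AssociationMatrix, neg_ratio: float = 1.0, seed: int = 0) -> list[PairSample]:
    """All positive pairs plus ceil(neg_ratio * positives) seeded negatives.

    Negatives are drawn uniformly without replacement from the zero cells of
    the association matrix, so positives and negatives never overlap.
    """
    if neg_ratio <= 0:
        raise ValueError("neg_ratio must be positive")
    pos_idx = np.argwhere(A.values == 1)
    zero_idx = np.argwhere(A.values == 0)
    if len(pos_idx) == 0 or len(zero_idx) == 0:
        raise ValueError("association matrix needs at least one positive and one zero entry")
    n_neg = math.ceil(neg_ratio * len(pos_idx))
    if n_neg > len(zero_idx):
        raise ValueError(
            f"requested {n_neg} negatives but only {len(zero_idx)} zero cells are available")
    rng = np.random.default_rng(seed)
    chosen = zero_idx[rng.choice(len(zero_idx), size=n_neg, replace=False)]
    samples = [PairSample(A.lnc_labels[i], A.dis_labels[j], 1) for i, j in pos_idx]
    samples += [PairSample(A.lnc_labels[i], A.dis_labels[j], 0) for i, j in chosen]
    logger.info("sampled %d positives + %d negatives (ratio %.2f, seed %d)",
                len(pos_idx), n_neg, neg_ratio, seed)
    return samples


def build_features(pairs: list[PairSample], SL: SimilarityMatrix,
                   SD: SimilarityMatrix) -> FeatureTable:
    """Feature vector for (l, d) = SL row of l concatenated with SD row of d."""
    n = len(pairs)
    width = len(SL.labels) + len(SD.labels)
    features = np.empty((n, width))
    labels = np.empty(n, dtype=int)
    pair_ids: list[tuple[str, str]] = []
    for idx, p in enumerate(pairs):
        features[idx, : len(SL.labels)] = SL.row(p.lncrna)
        features[idx, len(SL.labels):] = SD.row(p.disease)
        labels[idx] = p.label
        pair_ids.append((p.lncrna, p.disease))
    return FeatureTable(features, labels, pair_ids)


def pair_feature(lncrna: str, disease: str, SL: SimilarityMatrix,
                 SD: SimilarityMatrix) -> np.ndarray:
    """Single-pair feature vector (used when scoring candidate pairs)."""
    return np.concatenate([SL.row(lncrna), SD.row(disease)])
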