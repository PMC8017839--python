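"""Gaussian interaction profile (GIP) kernel similarity.

The interaction profile of a disease is its column of the binary association
matrix; a lncRNA's profile is its row.  Two entities are similar when their
profiles are close:

    K(x, y) = exp(-k * ||profile(x) - profile(y)||^2)

with the bandwidth normalized by the mean squared profile norm over the
axis, k = count / sum_i ||profile(i)||^2.  Identical profiles get
similarity exactly 1, which operationalises the premise that similar
diseases share associated lncRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import AssociationMatrix
from .semantic import SimilarityMatrix

logger = logging.getLogger("ipcarf")

_AXES = ("disease", "lncrna")


@dataclass(frozen=True)
class GipBandwidth:
    value: float
    axis: str

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}")
        if not (self.value > 0 and np.isfinite(self.value)):
            raise ValueError("bandwidth must be positive and finite")


def _profiles(A: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "disease":
        return A.values.T.astype(float)  # one row per disease = matrix column
    if axis == "lncrna":
        return A.values.astype(float)
    raise ValueError(f"axis must be one of {_AXES}")


def gip_bandwidth(A: AssociationMatrix, axis: str) -> GipBandwidth:
    """Normalized kernel width: count over the summed squared profile norms."""
    profiles = _profiles(A, axis)
    total = float((profiles ** 2).sum())
    if total == 0.0:
        raise ValueError("all interaction profiles are zero; cannot normalize bandwidth")
    return GipBandwidth(profiles.shape[0] / total, axis)


def gip_kernel(A: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Gaussian kernel on interaction profiles along the given axis."""
    k = gip_bandwidth(A, axis).value
    profiles = _profiles(A, axis)
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-k * sq_dists)
    np.fill_diagonal(values, 1.0)
    labels = A.dis_labels if axis == "disease" else A.lnc_labels
    logger.info("GIP kernel (%s): %d profiles, bandwidth %.6g", axis, len(labels), k)
    return SimilarityMatrix(values, list(labels), kind="gip")


def integrate_disease_similarity(semantic: SimilarityMatrix, gip: SimilarityMatrix,
                                 coverage: set[str]) -> SimilarityMatrix:
    """Mean of semantic and GIP similarity where both diseases have semantic
    scores; GIP alone elsewhere."""
    if semantic.labels != gip.labels:
        raise ValueError("semantic and GIP similarity label orders differ")
    covered = np.array([lbl in coverage for lbl in gip.labels])
    both = np.outer(covered, covered)
    values = np.where(both, (semantic.values + gip.values) / 2.0, gip.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(gip.labels), kind="integrated")


def integrate_lncrna_similarity(gip: SimilarityMatrix,
                                functional: SimilarityMatrix | None = None) -> SimilarityMatrix:
    """Mean of GIP and an optional functional similarity; GIP alone otherwise."""
    if functional is None:
        return gip
    if functional.labels != gip.labels:
        raise ValueError("functional and GIP similarity label orders differ")
    values = (gip.values + functional.values) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(gip.labels), kind="integrated")
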