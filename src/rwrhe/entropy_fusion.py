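"""Entropy-weighted fusion of similarity measures.

Each similarity matrix is scored by the mean Shannon entropy of its
row-normalized rows (natural log): a near-uniform matrix carries little
discriminative information and gets a high entropy, a structured one a low
entropy. Weights are the normalized reciprocals of the mean entropies, so
low-entropy (informative) measures dominate the fused matrix

    S = sum_m w_m * S_m,   w_m = (1/E_m) / sum_n (1/E_n).

The fused entries are convex combinations of the input entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import SimilarityMatrix
from .errors import AlignmentError, DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass
class EntropyReport:
    """Per-row entropies and their mean for one similarity measure."""

    tag: str
    row_entropies: np.ndarray
    mean_entropy: float


@dataclass
class WeightVector:
    """Fusion weights per measure tag; strictly positive and summing to 1."""

    tags: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("fusion weights must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {self.weights.sum()}, expected 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.tags, map(float, self.weights)))


def row_entropy(S: SimilarityMatrix) -> EntropyReport:
    """Shannon entropy (natural log) of each row after row normalization.

    Row i is normalized to p_ij = s_ij / sum_j s_ij; entropy is
    -sum_j p_ij ln p_ij with 0*ln0 = 0. An all-zero row gets entropy 0
    with a warning. The diagonal is included in the normalization.
    """
    values = np.asarray(S.values, dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{S.tag}: similarity entries must be non-negative")
    row_sums = values.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        logger.warning("%s: %d all-zero rows get entropy 0", S.tag, int(zero_rows.sum()))
    safe_sums = np.where(zero_rows, 1.0, row_sums)
    p = values / safe_sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropies = -plogp.sum(axis=1)
    entropies[zero_rows] = 0.0
    return EntropyReport(
        tag=S.tag, row_entropies=entropies, mean_entropy=float(entropies.mean())
    )


def entropy_weights(reports: list[EntropyReport]) -> WeightVector:
    """Normalized reciprocal mean entropies: w_m = (1/E_m) / sum_n (1/E_n)."""
    means = np.array([r.mean_entropy for r in reports], dtype=float)
    if np.any(means <= 0):
        offenders = [r.tag for r, m in zip(reports, means) if m <= 0]
        raise DegenerateInputError(
            f"measures {offenders} have non-positive mean entropy; a deterministic "
            "measure would receive infinite weight"
        )
    recip = 1.0 / means
    return WeightVector(tags=[r.tag for r in reports], weights=recip / recip.sum())


def equal_weights(tags: list[str]) -> WeightVector:
    """Uniform weights 1/M over the given measures (entropy-off variant)."""
    m = len(tags)
    return WeightVector(tags=list(tags), weights=np.full(m, 1.0 / m))


def fuse(
    matrices: list[SimilarityMatrix], weights: WeightVector
) -> SimilarityMatrix:
    """Weighted sum of aligned similarity matrices, tagged ``fused``."""
    if len(matrices) != len(weights.tags):
        raise AlignmentError("number of matrices does not match number of weights")
    tags = [m.tag for m in matrices]
    if tags != weights.tags:
        raise AlignmentError(f"matrix tags {tags} do not match weight tags {weights.tags}")
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise AlignmentError(f"measure {m.tag} has a different entity index")
    values = np.zeros_like(matrices[0].values)
    for w, m in zip(weights.weights, matrices):
        values += w * m.values
    return SimilarityMatrix(ids=list(ids), values=values, tag="fused")


def fuse_measures(
    measures: dict[str, SimilarityMatrix], use_entropy: bool = True
) -> tuple[SimilarityMatrix, WeightVector, list[EntropyReport]]:
    """Weight and fuse a family of measures in one call.

    With ``use_entropy=False`` (the equal-weights ablation) the measure set
    is unchanged and only the weights become uniform.
    """
    matrices = list(measures.values())
    reports = [row_entropy(m) for m in matrices]
    weights = entropy_weights(reports) if use_entropy else equal_weights(
        [m.tag for m in matrices]
    )
    return fuse(matrices, weights), weights, reports
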