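"""In-memory containers for the heterogeneous ingredient-target network.

All matrices carry their entity labels explicitly; every numerical module
re-checks label agreement instead of trusting positional alignment.
Values are plain numpy arrays (float64 for similarities and scores,
uint8 for the binary association matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError

__all__ = [
    "IngredientRecord",
    "TargetRecord",
    "AssociationMatrix",
    "EdgeScoreTable",
    "CompositionTable",
    "EvaluationSet",
    "FingerprintSet",
    "SimilarityMatrix",
    "NormalizedMatrix",
    "ScoreMatrix",
    "TargetScoreVector",
    "IngredientScoreVector",
    "RankVector",
    "EffectScoreTable",
]

MEASURE_TAGS = ("Sr1", "Sr2", "St1", "St2", "St3", "St4", "fused")


@dataclass(frozen=True)
class IngredientRecord:
    """One active ingredient: an identifier, a name, and optional
    SMILES / oral bioavailability (percent) / drug-likeness (fraction)."""

    ingredient_id: str
    name: str = ""
    smiles: str | None = None
    ob: float | None = None
    dl: float | None = None


@dataclass(frozen=True)
class TargetRecord:
    """One protein target (gene symbol) with an optional amino-acid sequence."""

    target_id: str
    sequence: str | None = None


@dataclass
class AssociationMatrix:
    """Binary ingredient x target association matrix A.

    Rows are ingredient interaction profiles, columns are target
    interaction profiles.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise AlignmentError(
                f"association matrix shape {self.values.shape} does not match "
                f"labels ({len(self.row_ids)}, {len(self.col_ids)})"
            )
        uniq = set(np.unique(self.values))
        if not uniq <= {0, 1}:
            raise ValueError(f"association matrix must be binary, found {uniq}")

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())


@dataclass
class EdgeScoreTable:
    """Undirected weighted target-target edges with confidence scores in [0, 1].

    A pair appears at most once; symmetric duplicates are merged at read time.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class CompositionTable:
    """Membership of groups: herb -> ingredient IDs, or compound -> herb IDs."""

    groups: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, members in self.groups.items():
            if not members:
                raise ValueError(f"group {gid!r} has no members")


@dataclass
class EvaluationSet:
    """Positive / negative control ingredient IDs for ROC evaluation."""

    positives: list[str]
    negatives: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"controls overlap: {sorted(overlap)[:5]}")


@dataclass
class FingerprintSet:
    """Binary chemical fingerprints, one fixed-length bit vector per ingredient."""

    ids: list[str]
    bits: np.ndarray  # (n_ingredients, n_bits) uint8

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.ids):
            raise AlignmentError("fingerprint matrix does not match id list")


@dataclass
class SimilarityMatrix:
    """Labelled square symmetric similarity matrix for one measure or the fusion."""

    ids: list[str]
    values: np.ndarray
    tag: str = "fused"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise AlignmentError(
                f"similarity matrix shape {self.values.shape} != ({n}, {n})"
            )

    def max_asymmetry(self) -> float:
        return float(np.abs(self.values - self.values.T).max(initial=0.0))


@dataclass
class NormalizedMatrix:
    """A matrix after Laplacian (row-stochastic) or global-sum normalization."""

    ids: list[str] | tuple[list[str], list[str]]
    values: np.ndarray
    normalization: str = "laplacian"  # or "global_sum"


@dataclass
class ScoreMatrix:
    """Real-valued predicted ingredient x target association scores."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise AlignmentError("score matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix contains non-finite entries")


@dataclass
class TargetScoreVector:
    """Disease-target association probabilities (one value per target)."""

    ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids),):
            raise AlignmentError("score vector length does not match labels")


@dataclass
class IngredientScoreVector:
    """Disease-ingredient association scores (one value per ingredient)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids),):
            raise AlignmentError("score vector length does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ingredient scores contain non-finite entries")


@dataclass
class RankVector:
    """Integer ranks (1 = highest score) per ingredient."""

    ids: list[str]
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        if self.ranks.shape != (len(self.ids),):
            raise AlignmentError("rank vector length does not match labels")

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.ids, (int(r) for r in self.ranks)))


@dataclass
class EffectScoreTable:
    """Reciprocal-rank effect scores per herb or compound, sorted descending."""

    group_ids: list[str]
    scores: np.ndarray
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=int)
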