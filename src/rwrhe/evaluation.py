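"""ROC/AUC evaluation against control sets, rank CDFs, and the end-to-end
pipeline used for the ablation analysis.

The predicted disease-ingredient scores are evaluated against a positive
control set (ingredients known to be disease-associated) and a negative
control set (ingredients associated with unrelated conditions). AUC uses
the Mann-Whitney convention (ties count half), so it is invariant under
any strictly monotone transform of the scores.

Three pipeline variants support the ablation study:

* ``full`` — all similarity measures, entropy weights;
* ``no_gip`` — the two Gaussian interaction-profile kernels (Sr2, St4)
  removed, entropy weights recomputed over the remaining measures;
* ``equal_weights`` — all measures kept, uniform weights 1/M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .config import RunConfig
from .containers import (
    AssociationMatrix,
    CompositionTable,
    EdgeScoreTable,
    EvaluationSet,
    IngredientRecord,
    IngredientScoreVector,
    RankVector,
    ScoreMatrix,
    SimilarityMatrix,
    TargetRecord,
    TargetScoreVector,
)
from .entropy_fusion import EntropyReport, WeightVector, fuse_measures
from .errors import EmptyInputError
from .randomwalk import bi_random_walk, laplacian_normalize, normalize_association, seeded_rwr
from .scoring import disease_ingredient_scores, rank_ingredients
from .similarity import build_ingredient_measures, build_target_measures, morgan_fingerprints

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    """ROC curve (FPR/TPR per threshold) and its trapezoidal area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class CdfResult:
    """Proportion of positive controls retrieved within the top r, per r."""

    r_values: np.ndarray
    proportions: np.ndarray


def roc_auc(scores: IngredientScoreVector, controls: EvaluationSet) -> RocResult:
    """ROC of the scores restricted to the control ingredients.

    Every control ID must be present in the score vector; ties contribute
    half credit (Mann-Whitney), matching the trapezoidal area under the
    threshold-swept curve.
    """
    if not controls.positives or not controls.negatives:
        raise EmptyInputError("both control groups must be non-empty")
    score_of = dict(zip(scores.ids, scores.values))
    missing = [i for i in controls.positives + controls.negatives if i not in score_of]
    if missing:
        raise KeyError(f"control ingredients without scores: {missing}")
    y_true = np.array([1] * len(controls.positives) + [0] * len(controls.negatives))
    y_score = np.array(
        [score_of[i] for i in controls.positives + controls.negatives]
    )
    fpr, tpr, thresholds = roc_curve(y_true, y_score)
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(roc_auc_score(y_true, y_score)),
    )


def cdf_of_ranks(
    ranks: RankVector, positives: list[str], r_min: int = 60, r_max: int = 100
) -> CdfResult:
    """For each r in [r_min, r_max], the fraction of positives ranked <= r."""
    if not positives:
        raise EmptyInputError("positive control list is empty")
    if r_min > r_max:
        raise ValueError("r_min must not exceed r_max")
    rank_of = ranks.as_dict()
    missing = [p for p in positives if p not in rank_of]
    if missing:
        raise KeyError(f"positives without ranks: {missing}")
    pos_ranks = np.array([rank_of[p] for p in positives])
    r_values = np.arange(r_min, r_max + 1)
    proportions = (pos_ranks[None, :] <= r_values[:, None]).mean(axis=1)
    return CdfResult(r_values=r_values, proportions=proportions)


@dataclass
class PipelineInputs:
    """A complete, label-consistent input bundle for one run."""

    association: AssociationMatrix
    ingredients: list[IngredientRecord]
    targets: list[TargetRecord]
    edges: EdgeScoreTable
    seeds: list[str]
    controls: EvaluationSet | None = None
    herbs: CompositionTable | None = None
    compounds: CompositionTable | None = None


@dataclass
class PipelineResult:
    """Everything one variant run produces."""

    variant: str
    scores: IngredientScoreVector
    ranks: RankVector
    RT: ScoreMatrix
    P: TargetScoreVector
    ingredient_weights: WeightVector
    target_weights: WeightVector
    entropy_reports: list[EntropyReport] = field(default_factory=list)
    roc: RocResult | None = None


def _align_entities(inputs: PipelineInputs) -> PipelineInputs:
    """Re-index entity records against the association matrix label order.

    Entities absent from the record tables are kept with missing SMILES /
    sequence (they contribute 0 off-diagonal in the affected measure).
    """
    ing_by_id = {r.ingredient_id: r for r in inputs.ingredients}
    tgt_by_id = {t.target_id: t for t in inputs.targets}
    ingredients = [
        ing_by_id.get(rid, IngredientRecord(ingredient_id=rid))
        for rid in inputs.association.row_ids
    ]
    targets = [
        tgt_by_id.get(tid, TargetRecord(target_id=tid))
        for tid in inputs.association.col_ids
    ]
    return replace(inputs, ingredients=ingredients, targets=targets)


def compute_measures(
    inputs: PipelineInputs, cfg: RunConfig
) -> tuple[dict[str, SimilarityMatrix], dict[str, SimilarityMatrix]]:
    """Compute the ingredient- and target-side similarity measures."""
    inputs = _align_entities(inputs)
    fps = morgan_fingerprints(
        inputs.ingredients, n_bits=cfg.fingerprint_bits, radius=cfg.fingerprint_radius
    )
    r_measures = build_ingredient_measures(fps, inputs.association, cfg)
    t_measures = build_target_measures(
        inputs.targets, inputs.edges, inputs.association, cfg
    )
    return r_measures, t_measures


def run_from_measures(
    r_measures: dict[str, SimilarityMatrix],
    t_measures: dict[str, SimilarityMatrix],
    inputs: PipelineInputs,
    cfg: RunConfig,
) -> PipelineResult:
    """Fusion, walks, and scoring, given precomputed similarity measures."""
    if cfg.variant == "no_gip":
        r_measures = {k: v for k, v in r_measures.items() if k != "Sr2"}
        t_measures = {k: v for k, v in t_measures.items() if k != "St4"}
    use_entropy = cfg.variant != "equal_weights"
    sr, w_r, rep_r = fuse_measures(r_measures, use_entropy=use_entropy)
    st, w_t, rep_t = fuse_measures(t_measures, use_entropy=use_entropy)

    sr_norm = laplacian_normalize(sr)
    st_norm = laplacian_normalize(st)
    a_norm = normalize_association(inputs.association)
    rt = bi_random_walk(sr_norm, st_norm, a_norm, cfg)
    p = seeded_rwr(st_norm, inputs.seeds, cfg)
    scores = disease_ingredient_scores(rt, p)
    ranks = rank_ingredients(scores)
    roc = roc_auc(scores, inputs.controls) if inputs.controls is not None else None
    return PipelineResult(
        variant=cfg.variant,
        scores=scores,
        ranks=ranks,
        RT=rt,
        P=p,
        ingredient_weights=w_r,
        target_weights=w_t,
        entropy_reports=rep_r + rep_t,
        roc=roc,
    )


def run_variant(inputs: PipelineInputs, cfg: RunConfig) -> PipelineResult:
    """Execute similarity -> fusion -> walks -> scoring end-to-end.

    Deterministic given the inputs and configuration; the variant field of
    ``cfg`` selects the ablation.
    """
    r_measures, t_measures = compute_measures(inputs, cfg)
    return run_from_measures(r_measures, t_measures, inputs, cfg)
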