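"""ADME screening, disease-ingredient scores, ranks, and effect scores.

An ingredient's disease score combines the predicted ingredient-target
matrix RT with the disease-target probability vector P:

    P_r(r_i) = sum_j RT(r_i, t_j) * P(t_j)

i.e. the matrix-vector product RT @ P, which is linear in P. Ingredients
are ranked by descending score (rank 1 = strongest), and a herb's or
compound's effect score is the sum of the reciprocal ranks of its member
ingredients, H_k = sum_i 1/rank(i) — a monotone aggregate: moving any
member up the ranking strictly raises the group score.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    CompositionTable,
    EffectScoreTable,
    IngredientRecord,
    IngredientScoreVector,
    RankVector,
    ScoreMatrix,
    TargetScoreVector,
)
from .errors import AlignmentError

logger = logging.getLogger(__name__)


def screen_ingredients(
    records: list[IngredientRecord], ob_min: float = 20.0, dl_min: float = 0.1
) -> list[IngredientRecord]:
    """Keep ingredients with OB strictly above ``ob_min`` percent and DL
    strictly above ``dl_min``; records missing either value are dropped."""
    kept: list[IngredientRecord] = []
    for rec in records:
        if rec.ob is None or rec.dl is None:
            logger.warning("%s lacks OB/DL; dropped from screening", rec.ingredient_id)
            continue
        if rec.ob > ob_min and rec.dl > dl_min:
            kept.append(rec)
    return kept


def disease_ingredient_scores(
    RT: ScoreMatrix, P: TargetScoreVector
) -> IngredientScoreVector:
    """P_r = RT @ P; the target indices must agree exactly."""
    if list(RT.col_ids) != list(P.ids):
        raise AlignmentError("RT columns and P index differ")
    return IngredientScoreVector(ids=list(RT.row_ids), values=RT.values @ P.values)


def rank_ingredients(scores: IngredientScoreVector) -> RankVector:
    """Rank descending by score, rank 1 on top.

    Ties are broken by position in the input id order (stable), which makes
    the ranking deterministic; tied groups are logged.
    """
    values = scores.values
    if len(values) == 0:
        raise ValueError("cannot rank an empty score vector")
    order = np.lexsort((np.arange(len(values)), -values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    n_ties = len(values) - len(np.unique(values))
    if n_ties:
        logger.info("%d tied scores broken by input order", n_ties)
    return RankVector(ids=list(scores.ids), ranks=ranks)


def effect_scores(
    ranks: RankVector, composition: CompositionTable, level: str = "herb",
    herb_composition: CompositionTable | None = None,
) -> EffectScoreTable:
    """Reciprocal-rank effect score H_k = sum_{i in members(k)} 1/rank(i).

    For ``level='compound'`` the composition maps compounds to herbs and
    ``herb_composition`` must be given; a compound's ingredient set is the
    union (without multiplicity) of its member herbs' ingredient sets.
    Members absent from the ranking are skipped with a warning. Output is
    sorted descending with dense ranks.
    """
    if level not in ("herb", "compound"):
        raise ValueError(f"level must be 'herb' or 'compound', got {level!r}")
    rank_of = ranks.as_dict()

    def ingredient_set(group_id: str, members: set[str]) -> set[str]:
        if level == "herb":
            return members
        if herb_composition is None:
            raise ValueError("level='compound' requires herb_composition")
        out: set[str] = set()
        for herb in members:
            if herb not in herb_composition.groups:
                logger.warning("compound %s references unknown herb %s", group_id, herb)
                continue
            out |= herb_composition.groups[herb]
        return out

    group_ids: list[str] = []
    scores: list[float] = []
    for gid, members in composition.groups.items():
        total = 0.0
        for ing in sorted(ingredient_set(gid, members)):
            if ing not in rank_of:
                logger.warning("%s: member %s has no rank; skipped", gid, ing)
                continue
            total += 1.0 / rank_of[ing]
        group_ids.append(gid)
        scores.append(total)

    score_arr = np.asarray(scores)
    order = np.lexsort((np.arange(len(score_arr)), -score_arr))
    # dense ranks: equal scores share a rank
    out_ranks = np.empty(len(score_arr), dtype=int)
    dense = 0
    prev: float | None = None
    for pos in order:
        if prev is None or score_arr[pos] != prev:
            dense += 1
            prev = float(score_arr[pos])
        out_ranks[pos] = dense
    return EffectScoreTable(
        group_ids=[group_ids[i] for i in order],
        scores=score_arr[order],
        ranks=out_ranks[order],
    )
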