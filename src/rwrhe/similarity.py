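"""Ingredient and target similarity measures.

Ingredient side (two measures):

* ``Sr1`` — Tanimoto similarity of 2048-bit Morgan (circular, radius 2)
  fingerprints, sharpened by a logistic transform
  ``L(s) = 1 / (1 + exp(c*s + d))`` with c = -15, d = log(9999) so weak
  similarities collapse towards 0 (L(0) = 1e-4) while strong ones are
  expanded.
* ``Sr2`` — Gaussian interaction profile (GIP) kernel on the rows of the
  binary association matrix: similar ingredients share targets.

Target side (four measures):

* ``St1`` — Smith-Waterman local alignment score of protein sequences,
  kernel-normalized as SW(i,j) / sqrt(SW(i,i) * SW(j,j)).
* ``St2`` — String-style interaction confidence scores placed directly
  into a matrix.
* ``St3`` — degree-weighted common-neighbor similarity on the graph of
  high-confidence interactions (score > 0.4): each shared neighbor z
  contributes 1/degree(z); values above 1 are capped at 0.99.
* ``St4`` — GIP kernel on the columns of the association matrix.

Every measure returns a symmetric matrix with unit diagonal; entities with
missing SMILES or sequence contribute 0 off-diagonal (they are retained in
the index rather than dropped).
"""

from __future__ import annotations

import logging

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .config import RunConfig
from .containers import (
    AssociationMatrix,
    EdgeScoreTable,
    FingerprintSet,
    IngredientRecord,
    SimilarityMatrix,
    TargetRecord,
)
from .errors import DegenerateInputError, EmptyInputError, FormatError

logger = logging.getLogger(__name__)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def morgan_fingerprints(
    records: list[IngredientRecord], n_bits: int = 2048, radius: int = 2
) -> FingerprintSet:
    """Compute binary Morgan/circular fingerprints from SMILES.

    Ingredients with missing or unparseable SMILES get an all-zero vector
    (similarity 0 to everything; their diagonal is fixed to 1 downstream).
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.*")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = np.zeros((len(records), n_bits), dtype=np.uint8)
    for i, rec in enumerate(records):
        if rec.smiles is None:
            logger.warning("ingredient %s has no SMILES; zero fingerprint", rec.ingredient_id)
            continue
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning(
                "SMILES for %s did not parse; zero fingerprint", rec.ingredient_id
            )
            continue
        bits[i] = gen.GetFingerprintAsNumPy(mol)
    return FingerprintSet(ids=[r.ingredient_id for r in records], bits=bits)


def tanimoto_similarity(fps: FingerprintSet) -> SimilarityMatrix:
    """Pairwise Tanimoto score  f_i.f_j / (|f_i|^2 + |f_j|^2 - f_i.f_j).

    All-zero fingerprints yield 0 against everything; diagonals are set
    to 1 unconditionally.
    """
    if len(fps.ids) == 0:
        raise EmptyInputError("empty fingerprint set")
    f = fps.bits.astype(np.float64)
    inner = f @ f.T
    norms = np.diag(inner)
    denom = norms[:, None] + norms[None, :] - inner
    if np.any(norms == 0):
        logger.warning("%d all-zero fingerprints", int((norms == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, inner / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=list(fps.ids), values=values, tag="Sr1")


def logistic_transform(
    S: SimilarityMatrix, c: float, d: float, tag: str | None = None
) -> SimilarityMatrix:
    """Sharpen a similarity matrix elementwise with L(s) = 1/(1 + e^(c*s+d)).

    Applied off-diagonal only; the diagonal is forced to 1 (L(1) < 1 would
    otherwise make self-similarity non-maximal and distort the walk
    operators).
    """
    values = 1.0 / (1.0 + np.exp(c * S.values + d))
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=list(S.ids), values=values, tag=tag or S.tag)


def gip_kernel(
    A: AssociationMatrix, axis: str, gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over rows or columns of A.

    S(i,j) = exp(-gamma * ||IP(i) - IP(j)||^2) with the bandwidth
    gamma = gamma' / mean_i ||IP(i)||^2, so it adapts to the density of the
    association matrix.
    """
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    profiles = A.values if axis == "rows" else A.values.T
    ids = A.row_ids if axis == "rows" else A.col_ids
    p = profiles.astype(np.float64)
    sq_norms = (p * p).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise DegenerateInputError(
            "association matrix is all-zero; GIP bandwidth undefined"
        )
    gamma = gamma_prime / mean_sq
    # ||a-b||^2 = |a|^2 + |b|^2 - 2 a.b ; profiles are binary so this is exact
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (p @ p.T)
    np.maximum(sq_dist, 0.0, out=sq_dist)
    values = np.exp(-gamma * sq_dist)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)  # kill float round-off asymmetry
    return SimilarityMatrix(
        ids=list(ids), values=values, tag="Sr2" if axis == "rows" else "St4"
    )


def _make_aligner(
    open_gap: float, extend_gap: float, matrix_name: str
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    return aligner


def sequence_similarity(
    targets: list[TargetRecord],
    open_gap: float = 10.0,
    extend_gap: float = 0.5,
    matrix_name: str = "BLOSUM62",
    aligner: PairwiseAligner | None = None,
) -> SimilarityMatrix:
    """Smith-Waterman local-alignment similarity between target sequences.

    Raw SW scores are kernel-normalized: St1(i,j) = SW(i,j) /
    sqrt(SW(i,i) * SW(j,j)), which maps them into [0, 1] for any scoring
    scheme with positive self-scores. Targets without a usable sequence get
    0 off-diagonal and 1 on the diagonal.
    """
    ids = [t.target_id for t in targets]
    n = len(ids)
    if aligner is None:
        aligner = _make_aligner(open_gap, extend_gap, matrix_name)
    for t in targets:
        if t.sequence is not None:
            bad = set(t.sequence) - _AA_ALPHABET
            if bad:
                raise FormatError(
                    f"sequence for {t.target_id} has invalid residues {sorted(bad)}"
                )
    self_scores = np.zeros(n)
    usable = np.zeros(n, dtype=bool)
    for i, t in enumerate(targets):
        if t.sequence is None:
            continue
        s = aligner.score(t.sequence, t.sequence)
        if s > 0:
            self_scores[i] = s
            usable[i] = True
        else:
            logger.warning("target %s has non-positive self-score; treated as missing", t.target_id)
    values = np.zeros((n, n))
    idx = np.nonzero(usable)[0]
    for a, i in enumerate(idx):
        si = targets[i].sequence
        for j in idx[a + 1 :]:
            sw = aligner.score(si, targets[j].sequence)
            values[i, j] = values[j, i] = max(sw, 0.0) / np.sqrt(
                self_scores[i] * self_scores[j]
            )
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=ids, values=values, tag="St1")


def edge_score_similarity(
    edges: EdgeScoreTable, ids: list[str]
) -> SimilarityMatrix:
    """Place interaction confidence scores directly into a similarity matrix.

    Unlisted pairs are 0; the diagonal is 1. Edges referencing unknown
    targets are dropped with a warning.
    """
    index = {t: i for i, t in enumerate(ids)}
    values = np.zeros((len(ids), len(ids)))
    for a, b, score in edges.edges:
        if a not in index or b not in index:
            logger.warning("edge (%s, %s) references unknown target; dropped", a, b)
            continue
        i, j = index[a], index[b]
        if i == j:
            continue
        values[i, j] = values[j, i] = score
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=list(ids), values=values, tag="St2")


def common_neighbor_similarity(
    edges: EdgeScoreTable, ids: list[str], threshold: float = 0.4
) -> SimilarityMatrix:
    """Degree-weighted common-neighbor similarity on the high-confidence graph.

    Targets are neighbors when their interaction score is strictly greater
    than ``threshold``. St3(i,j) = sum over shared neighbors z of
    1/degree(z); sums strictly greater than 1 are replaced by 0.99.
    """
    index = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=np.float64)
    for a, b, score in edges.edges:
        if a not in index or b not in index:
            logger.warning("edge (%s, %s) references unknown target; dropped", a, b)
            continue
        if score > threshold and a != b:
            i, j = index[a], index[b]
            adj[i, j] = adj[j, i] = 1.0
    degrees = adj.sum(axis=1)
    inv_deg = np.divide(1.0, degrees, out=np.zeros(n), where=degrees > 0)
    # S(i,j) = sum_z adj(i,z) * adj(j,z) / k(z)
    values = (adj * inv_deg[None, :]) @ adj.T
    values[values > 1.0] = 0.99
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=list(ids), values=values, tag="St3")


def build_ingredient_measures(
    fps: FingerprintSet, A: AssociationMatrix, cfg: RunConfig
) -> dict[str, SimilarityMatrix]:
    """Assemble the ingredient-side measures (Sr1, and Sr2 unless no_gip)."""
    if fps.ids != A.row_ids:
        raise EmptyInputError("fingerprints and association rows must share ids")
    sr1 = logistic_transform(
        tanimoto_similarity(fps), cfg.logistic_c, cfg.logistic_d, tag="Sr1"
    )
    measures = {"Sr1": sr1}
    if cfg.variant != "no_gip":
        measures["Sr2"] = gip_kernel(A, "rows", cfg.gamma_r)
    return measures


def build_target_measures(
    targets: list[TargetRecord],
    edges: EdgeScoreTable,
    A: AssociationMatrix,
    cfg: RunConfig,
) -> dict[str, SimilarityMatrix]:
    """Assemble the target-side measures (St1-St3, and St4 unless no_gip)."""
    ids = [t.target_id for t in targets]
    if ids != A.col_ids:
        raise EmptyInputError("target records and association columns must share ids")
    measures = {
        "St1": sequence_similarity(targets),
        "St2": edge_score_similarity(edges, ids),
        "St3": common_neighbor_similarity(edges, ids, cfg.neighbor_threshold),
    }
    if cfg.variant != "no_gip":
        measures["St4"] = gip_kernel(A, "cols", cfg.gamma_t)
    return measures
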