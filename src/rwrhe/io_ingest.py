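"""Readers and writers for all on-disk artifacts; no numerical logic.

All tabular formats are TSV/CSV with a header row (UTF-8); sequences are
FASTA keyed by gene symbol. Readers are strict: anything outside the
documented dialect raises a typed error rather than being coerced, and
``read(write(x)) == x`` holds for every artifact type.

The canonical entity ordering is first-appearance order in the association
table; every other input is re-indexed against it downstream.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    AssociationMatrix,
    CompositionTable,
    EdgeScoreTable,
    EvaluationSet,
    IngredientRecord,
    IngredientScoreVector,
    ScoreMatrix,
    SimilarityMatrix,
    TargetRecord,
    TargetScoreVector,
)
from .errors import EmptyInputError, FormatError, OutOfRangeError

logger = logging.getLogger(__name__)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing required columns {missing}")
    return df


def read_association_table(path: str | Path) -> AssociationMatrix:
    """Read one-association-per-row TSV/CSV into a binary matrix.

    Labels appear in first-appearance order; repeated pairs collapse to a
    single 1.
    """
    df = _read_table(path, ["ingredient_id", "target_id"])
    if df.empty:
        raise EmptyInputError(f"{path} contains no associations")
    row_ids = list(dict.fromkeys(df["ingredient_id"]))
    col_ids = list(dict.fromkeys(df["target_id"]))
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: j for j, c in enumerate(col_ids)}
    values = np.zeros((len(row_ids), len(col_ids)), dtype=np.uint8)
    values[df["ingredient_id"].map(ri), df["target_id"].map(ci)] = 1
    return AssociationMatrix(row_ids=row_ids, col_ids=col_ids, values=values)


def _parse_optional_float(cell: str, column: str, path: Path) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"{path}: non-numeric value {cell!r} in column {column}") from None


def read_ingredients(path: str | Path) -> list[IngredientRecord]:
    """Read the ingredient table (id, name, optional smiles/ob/dl)."""
    path = Path(path)
    df = _read_table(path, ["ingredient_id"])
    records: list[IngredientRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        rid = row.ingredient_id
        if rid in seen:
            raise FormatError(f"{path}: duplicate ingredient_id {rid!r}")
        seen.add(rid)
        smiles = getattr(row, "smiles", "") or None
        records.append(
            IngredientRecord(
                ingredient_id=rid,
                name=getattr(row, "name", ""),
                smiles=smiles,
                ob=_parse_optional_float(getattr(row, "ob", ""), "ob", path),
                dl=_parse_optional_float(getattr(row, "dl", ""), "dl", path),
            )
        )
    return records


def read_targets_fasta(path: str | Path) -> list[TargetRecord]:
    """Read target sequences from FASTA; record IDs are gene symbols."""
    path = Path(path)
    records: list[TargetRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises ValueError on malformed input
        raise FormatError(f"{path}: cannot parse FASTA ({exc})") from exc
    for rec in parsed:
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate target id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: sequence for {rec.id} has invalid residues {sorted(bad)}"
            )
        records.append(TargetRecord(target_id=rec.id, sequence=seq or None))
    return records


def read_entities(
    ingredients_path: str | Path, targets_fasta_path: str | Path
) -> tuple[list[IngredientRecord], list[TargetRecord]]:
    """Read ingredient and target entity tables together."""
    return read_ingredients(ingredients_path), read_targets_fasta(targets_fasta_path)


def write_ingredients(records: list[IngredientRecord], path: str | Path) -> None:
    rows = [
        {
            "ingredient_id": r.ingredient_id,
            "name": r.name,
            "smiles": r.smiles if r.smiles is not None else "",
            "ob": "" if r.ob is None else repr(r.ob),
            "dl": "" if r.dl is None else repr(r.dl),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_targets_fasta(records: list[TargetRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.sequence is not None:
                fh.write(f">{r.target_id}\n{r.sequence}\n")


def read_edge_scores(path: str | Path) -> EdgeScoreTable:
    """Read a target-target edge list with confidence scores in [0, 1].

    Symmetric duplicates (a,b)/(b,a) are merged keeping the maximum score.
    Scores outside [0, 1] are rejected: raw 0-1000 String combined scores
    must be pre-scaled (``rwrhe`` CLI: ``--scale-string-scores``).
    """
    path = Path(path)
    try:
        df = _read_table(path, ["target_a", "target_b", "score"])
    except EmptyInputError:
        return EdgeScoreTable(edges=[])
    best: dict[tuple[str, str], float] = {}
    for a, b, s in zip(df["target_a"], df["target_b"], df["score"]):
        try:
            score = float(s)
        except ValueError:
            raise FormatError(f"{path}: non-numeric score {s!r}") from None
        if not 0.0 <= score <= 1.0:
            raise OutOfRangeError(
                f"{path}: score {score} for ({a}, {b}) outside [0, 1]; "
                "raw String combined scores must be divided by 1000 first"
            )
        key = (a, b) if a <= b else (b, a)
        best[key] = max(best.get(key, 0.0), score)
    return EdgeScoreTable(edges=[(a, b, s) for (a, b), s in best.items()])


def write_edge_scores(table: EdgeScoreTable, path: str | Path) -> None:
    pd.DataFrame(table.edges, columns=["target_a", "target_b", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_composition(path: str | Path) -> CompositionTable:
    """Read group membership (long format: group_id, member_id)."""
    df = _read_table(path, ["group_id", "member_id"])
    if df.empty:
        raise EmptyInputError(f"{path} contains no memberships")
    groups: dict[str, set[str]] = {}
    for gid, mid in zip(df["group_id"], df["member_id"]):
        groups.setdefault(gid, set()).add(mid)
    return CompositionTable(groups=groups)


def write_composition(table: CompositionTable, path: str | Path) -> None:
    rows = [
        {"group_id": gid, "member_id": mid}
        for gid, members in table.groups.items()
        for mid in sorted(members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seed_list(path: str | Path) -> list[str]:
    """Read disease seed target IDs (single column ``target_id``)."""
    df = _read_table(path, ["target_id"])
    seeds = list(dict.fromkeys(df["target_id"]))
    if not seeds:
        raise EmptyInputError(f"{path} contains no seed targets")
    return seeds


def write_seed_list(seeds: list[str], path: str | Path) -> None:
    pd.DataFrame({"target_id": seeds}).to_csv(path, sep="\t", index=False)


def read_controls(path: str | Path) -> EvaluationSet:
    """Read positive/negative control ingredients (ingredient_id, group)."""
    df = _read_table(path, ["ingredient_id", "group"])
    positives = list(df.loc[df["group"] == "positive", "ingredient_id"])
    negatives = list(df.loc[df["group"] == "negative", "ingredient_id"])
    bad = set(df["group"]) - {"positive", "negative"}
    if bad:
        raise FormatError(f"{path}: unknown control group labels {sorted(bad)}")
    if not positives or not negatives:
        raise EmptyInputError(f"{path}: both control groups must be non-empty")
    return EvaluationSet(positives=positives, negatives=negatives)


def write_controls(controls: EvaluationSet, path: str | Path) -> None:
    rows = [{"ingredient_id": i, "group": "positive"} for i in controls.positives]
    rows += [{"ingredient_id": i, "group": "negative"} for i in controls.negatives]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _check_finite(values: np.ndarray, path: str | Path) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(
            f"refusing to write non-finite values to {path}: NaN/inf is a bug upstream"
        )


def write_matrix(
    obj: SimilarityMatrix | ScoreMatrix | AssociationMatrix, path: str | Path
) -> None:
    """Write a labelled matrix as TSV (row labels in the first column)."""
    if isinstance(obj, SimilarityMatrix):
        row_ids = col_ids = obj.ids
    else:
        row_ids, col_ids = obj.row_ids, obj.col_ids
    values = np.asarray(obj.values, dtype=float)
    _check_finite(values, path)
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def read_matrix(path: str | Path) -> ScoreMatrix:
    """Read a labelled matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(
        row_ids=[str(i) for i in df.index],
        col_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def read_similarity_matrix(path: str | Path, tag: str = "fused") -> SimilarityMatrix:
    m = read_matrix(path)
    if m.row_ids != m.col_ids:
        raise FormatError(f"{path}: similarity matrix labels are not square")
    return SimilarityMatrix(ids=m.row_ids, values=m.values, tag=tag)


def write_scores(
    obj: TargetScoreVector | IngredientScoreVector, path: str | Path
) -> None:
    """Write a labelled score vector as two-column TSV."""
    values = np.asarray(obj.values, dtype=float)
    _check_finite(values, path)
    pd.DataFrame({"id": obj.ids, "score": values}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_scores(path: str | Path) -> IngredientScoreVector:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if list(df.columns) != ["id", "score"]:
        raise FormatError(f"{path}: expected columns ['id', 'score']")
    return IngredientScoreVector(ids=list(df["id"]), values=df["score"].to_numpy(float))


def write_association_table(A: AssociationMatrix, path: str | Path) -> None:
    """Write the binary matrix back out as one association per row."""
    rows_idx, cols_idx = np.nonzero(A.values)
    pd.DataFrame(
        {
            "ingredient_id": [A.row_ids[i] for i in rows_idx],
            "target_id": [A.col_ids[j] for j in cols_idx],
        }
    ).to_csv(path, sep="\t", index=False)


def scale_string_scores(path_in: str | Path, path_out: str | Path) -> None:
    """Divide raw String combined scores (0-1000) by 1000 and rewrite."""
    df = _read_table(path_in, ["target_a", "target_b", "score"])
    df["score"] = df["score"].astype(float) / 1000.0
    if (df["score"] > 1.0).any() or (df["score"] < 0.0).any():
        raise OutOfRangeError(f"{path_in}: scores not on the 0-1000 scale")
    df.to_csv(path_out, sep="\t", index=False, float_format="%.17g")


def records_equal(a: float | None, b: float | None, tol: float = 1e-12) -> bool:
    """Value equality for optional floats, used by round-trip checks."""
    if a is None or b is None:
        return a is b
    return math.isclose(a, b, rel_tol=tol, abs_tol=tol)
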