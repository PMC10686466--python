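"""Synthetic input bundles with planted block structure.

The generator emulates the shape of a herbal network-pharmacology dataset
without any database access: ingredients and targets are partitioned into
blocks, and block b ingredients associate with block b targets at a high
within-block probability against a low background rate. The planted signal
is mirrored in every data channel so each similarity measure is
informative:

* chemistry — each block draws SMILES from its own slice of a fixed list
  of real drug-like molecules, so within-block Tanimoto similarity exceeds
  between-block;
* sequence — targets share a 10-residue block motif embedded twice in an
  otherwise random 80-200 residue sequence;
* interactions — the target edge list is denser and higher-scoring within
  blocks;
* composition — each herb samples its ingredients mostly from one home
  block, and compounds group a few herbs.

Disease seeds are targets from block 0; positive controls are block 0
ingredients with at least one association, negative controls come from the
other blocks. A pipeline run on the default bundle should therefore rank
the positives near the top, while setting the within-block probability
equal to the background removes the signal entirely (null fixture,
AUC ~ 0.5).

Everything is reproducible from the integer seed; writing the bundle twice
with the same spec yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import io_ingest
from .containers import (
    AssociationMatrix,
    CompositionTable,
    EdgeScoreTable,
    EvaluationSet,
    IngredientRecord,
    TargetRecord,
)
from .evaluation import PipelineInputs

# Fixed pool of valid, drug-like SMILES (natural products and common drugs);
# fingerprints need parseable structures, and random strings rarely parse.
BUILTIN_SMILES: list[tuple[str, str]] = [
    ("aspirin", "CC(=O)OC1=CC=CC=C1C(=O)O"),
    ("caffeine", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"),
    ("quercetin", "O=C1C(O)=C(OC2=CC(O)=CC(O)=C12)C1=CC=C(O)C(O)=C1"),
    ("kaempferol", "O=C1C(O)=C(OC2=CC(O)=CC(O)=C12)C1=CC=C(O)C=C1"),
    ("apigenin", "O=C1C=C(OC2=CC(O)=CC(O)=C12)C1=CC=C(O)C=C1"),
    ("baicalein", "O=C1C=C(OC2=CC=C(O)C(O)=C12)C1=CC=CC=C1"),
    ("ibuprofen", "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O"),
    ("naproxen", "COC1=CC2=CC=C(C=C2C=C1)C(C)C(=O)O"),
    ("paracetamol", "CC(=O)NC1=CC=C(O)C=C1"),
    ("salicylic acid", "OC(=O)C1=CC=CC=C1O"),
    ("resveratrol", "OC1=CC(=CC(O)=C1)/C=C/C1=CC=C(O)C=C1"),
    ("curcumin", "COC1=CC(/C=C/C(=O)CC(=O)/C=C/C2=CC(OC)=C(O)C=C2)=CC=C1O"),
    ("berberine", "COC1=CC=C2C=C3C4=CC5=C(C=C4CC[N+]3=CC2=C1OC)OCO5"),
    ("nicotine", "CN1CCCC1C1=CC=CN=C1"),
    ("luteolin", "O=C1C=C(OC2=CC(O)=CC(O)=C12)C1=CC=C(O)C(O)=C1"),
    ("ferulic acid", "COC1=CC(/C=C/C(=O)O)=CC=C1O"),
    ("catechin", "OC1CC2=C(O)C=C(O)C=C2OC1C1=CC=C(O)C(O)=C1"),
    ("gallic acid", "OC(=O)C1=CC(O)=C(O)C(O)=C1"),
    ("vanillin", "COC1=CC(C=O)=CC=C1O"),
    ("cinnamic acid", "OC(=O)/C=C/C1=CC=CC=C1"),
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-structure fixture.

    Defaults are the standard recovery setting: 60 ingredients x 80 targets
    in 4 blocks, within-block association probability 0.5 against a 0.02
    background, seed 7.
    """

    n_ingredients: int = 60
    n_targets: int = 80
    n_blocks: int = 4
    within_block_assoc_prob: float = 0.5
    background_assoc_prob: float = 0.02
    edge_density: float = 0.4
    n_herbs: int = 8
    n_compounds: int = 4
    seed: int = 7

    def __post_init__(self) -> None:
        for p in (self.within_block_assoc_prob, self.background_assoc_prob,
                  self.edge_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must be in [0, 1], got {p}")
        if self.n_blocks <= 0:
            raise ValueError("n_blocks must be positive")
        if (self.n_ingredients < self.n_blocks or self.n_targets < self.n_blocks):
            raise ValueError("every block needs at least one ingredient and target")
        if self.within_block_assoc_prob < self.background_assoc_prob:
            raise ValueError(
                "within-block probability must be >= background to plant signal"
            )


def fixture_truth(spec: FixtureSpec) -> dict[str, np.ndarray]:
    """Planted block assignment for every entity (deterministic round-robin)."""
    return {
        "ingredient_blocks": np.arange(spec.n_ingredients) % spec.n_blocks,
        "target_blocks": np.arange(spec.n_targets) % spec.n_blocks,
    }


def _random_sequence(rng: np.random.Generator, motif: str) -> str:
    length = int(rng.integers(80, 201))
    seq = rng.choice(_AA, size=length)
    # embed the block motif twice so sequence similarity carries the signal
    for _ in range(2):
        pos = int(rng.integers(0, length - len(motif) + 1))
        seq[pos : pos + len(motif)] = list(motif)
    return "".join(seq)


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> PipelineInputs:
    """Generate a complete input bundle; optionally write it to ``out_dir``.

    The written files use exactly the dialects the readers expect
    (associations.tsv, ingredients.tsv, targets.fasta, edges.tsv,
    herbs.tsv, compounds.tsv, seeds.tsv, controls.tsv).
    """
    rng = np.random.default_rng(spec.seed)
    truth = fixture_truth(spec)
    ing_blocks = truth["ingredient_blocks"]
    tgt_blocks = truth["target_blocks"]
    ing_ids = [f"ING{i:04d}" for i in range(spec.n_ingredients)]
    tgt_ids = [f"TGT{j:04d}" for j in range(spec.n_targets)]

    # --- association matrix with block structure; ensure it is non-degenerate
    same_block = ing_blocks[:, None] == tgt_blocks[None, :]
    probs = np.where(
        same_block, spec.within_block_assoc_prob, spec.background_assoc_prob
    )
    values = (rng.random(probs.shape) < probs).astype(np.uint8)
    if values.sum() == 0:
        raise ValueError("fixture spec produced an empty association matrix")
    association = AssociationMatrix(row_ids=ing_ids, col_ids=tgt_ids, values=values)

    # --- ingredients: SMILES from the block's slice of the builtin pool
    per_block = len(BUILTIN_SMILES) // spec.n_blocks
    ingredients: list[IngredientRecord] = []
    for i, rid in enumerate(ing_ids):
        block = int(ing_blocks[i])
        if per_block >= 1:
            lo = block * per_block
            pick = lo + int(rng.integers(0, per_block))
        else:  # more blocks than molecules: reuse the pool cyclically
            pick = block % len(BUILTIN_SMILES)
        name, smiles = BUILTIN_SMILES[pick % len(BUILTIN_SMILES)]
        ingredients.append(
            IngredientRecord(
                ingredient_id=rid,
                name=name,
                smiles=smiles,
                ob=float(np.round(rng.uniform(20.5, 60.0), 2)),
                dl=float(np.round(rng.uniform(0.11, 0.8), 3)),
            )
        )

    # --- targets: random sequences with a per-block motif
    motifs = ["".join(rng.choice(_AA, size=10)) for _ in range(spec.n_blocks)]
    targets = [
        TargetRecord(
            target_id=tid, sequence=_random_sequence(rng, motifs[int(tgt_blocks[j])])
        )
        for j, tid in enumerate(tgt_ids)
    ]

    # --- target interaction edges: dense/high within blocks, sparse/low across
    edges: list[tuple[str, str, float]] = []
    for j in range(spec.n_targets):
        for k in range(j + 1, spec.n_targets):
            if tgt_blocks[j] == tgt_blocks[k]:
                if rng.random() < spec.edge_density:
                    edges.append(
                        (tgt_ids[j], tgt_ids[k], float(np.round(rng.uniform(0.45, 0.99), 3)))
                    )
            elif rng.random() < spec.edge_density / 8.0:
                edges.append(
                    (tgt_ids[j], tgt_ids[k], float(np.round(rng.uniform(0.05, 0.5), 3)))
                )
    edge_table = EdgeScoreTable(edges=edges)

    # --- herbs draw mostly from a home block; compounds group herbs
    herb_ids = [f"HERB{h:02d}" for h in range(spec.n_herbs)]
    herb_groups: dict[str, set[str]] = {}
    by_block = [
        [ing_ids[i] for i in range(spec.n_ingredients) if ing_blocks[i] == b]
        for b in range(spec.n_blocks)
    ]
    for h, hid in enumerate(herb_ids):
        home = by_block[h % spec.n_blocks]
        n_home = max(2, int(rng.integers(2, max(3, len(home) // 2 + 1))))
        members = set(rng.choice(home, size=min(n_home, len(home)), replace=False))
        other = [r for r in ing_ids if r not in home]
        if other and rng.random() < 0.5:
            members.add(str(rng.choice(other)))
        herb_groups[hid] = {str(m) for m in members}
    herbs = CompositionTable(groups=herb_groups)

    compound_groups: dict[str, set[str]] = {}
    for c in range(spec.n_compounds):
        k = int(rng.integers(2, min(4, spec.n_herbs) + 1))
        compound_groups[f"CMP{c:02d}"] = {
            str(h) for h in rng.choice(herb_ids, size=k, replace=False)
        }
    compounds = CompositionTable(groups=compound_groups)

    # --- disease seeds: targets of block 0 (the planted disease block)
    seeds = [tgt_ids[j] for j in range(spec.n_targets) if tgt_blocks[j] == 0]

    # --- controls: block-0 ingredients with associations vs other blocks
    positives = [
        ing_ids[i]
        for i in range(spec.n_ingredients)
        if ing_blocks[i] == 0 and values[i].sum() > 0
    ]
    negative_pool = [
        ing_ids[i] for i in range(spec.n_ingredients) if ing_blocks[i] != 0
    ]
    n_neg = min(len(negative_pool), max(len(positives), 10))
    negatives = [str(x) for x in rng.choice(negative_pool, size=n_neg, replace=False)]
    if not positives:
        raise ValueError("fixture spec left block 0 without associated ingredients")
    controls = EvaluationSet(positives=positives, negatives=sorted(negatives))

    inputs = PipelineInputs(
        association=association,
        ingredients=ingredients,
        targets=targets,
        edges=edge_table,
        seeds=seeds,
        controls=controls,
        herbs=herbs,
        compounds=compounds,
    )
    if out_dir is not None:
        write_bundle(inputs, out_dir)
    return inputs


def null_spec(spec: FixtureSpec, seed: int | None = None) -> FixtureSpec:
    """The matched no-signal fixture: within-block rate equals background."""
    return replace(
        spec,
        within_block_assoc_prob=max(spec.background_assoc_prob, 0.15),
        background_assoc_prob=max(spec.background_assoc_prob, 0.15),
        seed=spec.seed if seed is None else seed,
    )


def write_bundle(inputs: PipelineInputs, out_dir: str | Path) -> None:
    """Write a bundle in exactly the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_ingest.write_association_table(inputs.association, out / "associations.tsv")
    io_ingest.write_ingredients(inputs.ingredients, out / "ingredients.tsv")
    io_ingest.write_targets_fasta(inputs.targets, out / "targets.fasta")
    io_ingest.write_edge_scores(inputs.edges, out / "edges.tsv")
    io_ingest.write_seed_list(inputs.seeds, out / "seeds.tsv")
    if inputs.controls is not None:
        io_ingest.write_controls(inputs.controls, out / "controls.tsv")
    if inputs.herbs is not None:
        io_ingest.write_composition(inputs.herbs, out / "herbs.tsv")
    if inputs.compounds is not None:
        io_ingest.write_composition(inputs.compounds, out / "compounds.tsv")


def read_bundle(in_dir: str | Path) -> PipelineInputs:
    """Read a bundle directory written by :func:`write_bundle`."""
    d = Path(in_dir)
    ingredients, targets = io_ingest.read_entities(
        d / "ingredients.tsv", d / "targets.fasta"
    )
    return PipelineInputs(
        association=io_ingest.read_association_table(d / "associations.tsv"),
        ingredients=ingredients,
        targets=targets,
        edges=io_ingest.read_edge_scores(d / "edges.tsv"),
        seeds=io_ingest.read_seed_list(d / "seeds.tsv"),
        controls=io_ingest.read_controls(d / "controls.tsv")
        if (d / "controls.tsv").exists()
        else None,
        herbs=io_ingest.read_composition(d / "herbs.tsv")
        if (d / "herbs.tsv").exists()
        else None,
        compounds=io_ingest.read_composition(d / "compounds.tsv")
        if (d / "compounds.tsv").exists()
        else None,
    )
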