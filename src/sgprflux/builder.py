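"""Build GPR/S-GPR trees from an enzyme-composition table.

The table is the offline, user-curated stand-in for live database
retrieval: one row per (EC code, compartment, catalytic unit, gene),
with the transcript copy number the gene contributes to that unit.
Catalytic units of one EC code are isoenzymes (OR); genes within a unit
are complex subunits (AND, with copy numbers); several EC codes on one
reaction describe sequential activities that are all required (AND).
Rows whose compartment does not match the reaction's inferred compartment
are discarded, separating isoenzymes by sub-cellular location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .gpr import GprTree
from .model import MetabolicModel, Reaction

__all__ = [
    "CompositionRow",
    "ReactionAnnotation",
    "read_composition_table",
    "write_composition_table",
    "infer_reaction_compartment",
    "build_gpr_for_reaction",
    "annotate_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionRow:
    ec_code: str
    compartment: str
    catalytic_unit_id: str
    gene_id: str
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"copies must be >= 1, got {self.copies} for gene {self.gene_id!r}")


@dataclass
class ReactionAnnotation:
    reaction_id: str
    ec_codes: list[str]
    compartment: str | frozenset[str]
    # transport reactions carry the set of compartments they span

    def compartment_set(self) -> frozenset[str]:
        if isinstance(self.compartment, frozenset):
            return self.compartment
        return frozenset({self.compartment})


def read_composition_table(path: str | Path) -> list[CompositionRow]:
    """Read a TSV with columns ec_code, compartment, unit_id, gene_id, copies."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"ec_code", "compartment", "unit_id", "gene_id", "copies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    rows = [
        CompositionRow(
            ec_code=r.ec_code,
            compartment=r.compartment,
            catalytic_unit_id=r.unit_id,
            gene_id=r.gene_id,
            copies=int(r.copies),
        )
        for r in df.itertuples()
    ]
    keys = [(r.ec_code, r.compartment, r.catalytic_unit_id, r.gene_id) for r in rows]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate composition rows: {dupes}")
    return rows


def write_composition_table(rows: list[CompositionRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "ec_code": r.ec_code,
                "compartment": r.compartment,
                "unit_id": r.catalytic_unit_id,
                "gene_id": r.gene_id,
                "copies": r.copies,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def infer_reaction_compartment(
    reaction: Reaction, model: MetabolicModel
) -> str | frozenset[str]:
    """Compartment(s) of a reaction, inferred from its metabolites.

    Returns the single shared compartment, or — for transport reactions
    spanning several — the frozenset of compartments involved.
    """
    if not reaction.stoichiometry:
        raise ValueError(f"reaction {reaction.id!r} has no metabolites")
    comps = {model.metabolites[m].compartment for m in reaction.stoichiometry}
    if len(comps) == 1:
        return next(iter(comps))
    return frozenset(comps)


def build_gpr_for_reaction(
    annotation: ReactionAnnotation, table: list[CompositionRow]
) -> GprTree | None:
    """Assemble the S-GPR tree for one reaction from matching table rows.

    Returns None when no row survives the EC/compartment filter; the
    reaction then stays unconstrained by expression.  A transport reaction
    matches a row if the row's compartment is among the reaction's.
    Units and genes are canonically sorted, so building is deterministic
    regardless of table order.
    """
    comp_set = annotation.compartment_set()
    per_ec: list[GprTree] = []
    for ec in annotation.ec_codes:
        rows = sorted(
            (r for r in table if r.ec_code == ec and r.compartment in comp_set),
            key=lambda r: (r.catalytic_unit_id, r.gene_id),
        )
        if not rows:
            continue
        units: dict[str, list[CompositionRow]] = {}
        for r in rows:
            units.setdefault(r.catalytic_unit_id, []).append(r)
        unit_trees = []
        for unit_id in sorted(units):
            leaves = [GprTree.gene(r.gene_id, r.copies) for r in units[unit_id]]
            unit_trees.append(leaves[0] if len(leaves) == 1 else GprTree.and_(*leaves))
        per_ec.append(unit_trees[0] if len(unit_trees) == 1 else GprTree.or_(*unit_trees))
    if not per_ec:
        return None
    # sequential activities described by several EC codes are all required
    return per_ec[0] if len(per_ec) == 1 else GprTree.and_(*per_ec)


def annotate_model(
    model: MetabolicModel, table: list[CompositionRow]
) -> tuple[MetabolicModel, int]:
    """Attach GPR/S-GPR trees to every EC-annotated reaction of a model.

    Per-reaction failures (no matching composition rows) are logged and
    skipped.  Returns the annotated copy and the count of annotated
    reactions.
    """
    model = model.copy()
    n_annotated = 0
    for rxn in model.reactions.values():
        if not rxn.ec_codes:
            continue
        try:
            comp = infer_reaction_compartment(rxn, model)
        except ValueError as exc:
            logger.warning("skipping %s: %s", rxn.id, exc)
            continue
        tree = build_gpr_for_reaction(
            ReactionAnnotation(rxn.id, rxn.ec_codes, comp), table
        )
        if tree is None:
            logger.info("no composition rows for reaction %s (EC %s)", rxn.id, rxn.ec_codes)
            continue
        rxn.gpr = tree
        rxn.has_sgpr = True
        n_annotated += 1
    logger.info("annotated %d reactions with GPR/S-GPR rules", n_annotated)
    return model, n_annotated
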