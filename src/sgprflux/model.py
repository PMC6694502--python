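"""Constraint-based metabolic model container and I/O.

The in-memory model is deliberately small: metabolites, reactions with
stoichiometry and flux bounds, optional pathway labels, optional GPR/S-GPR
rule trees, and one objective reaction.  Two on-disk forms are supported:

* a native JSON dialect that is lossless (carries S-GPR strings, pathway
  labels and EC codes verbatim), and
* SBML Level 3 + fbc for interchange, bridged through cobra/libsbml.  fbc
  gene-product associations cannot carry stoichiometric coefficients, so
  the S-GPR string travels in the reaction notes under key ``"sgpr"`` (and
  the pathway label under ``"pathway"``).

Flux bounds are capped at +/-1000 model units on load, the common
constraint-based convention for "unbounded".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .gpr import GprTree, parse_gpr, serialize_gpr
from .solver import InfeasibleProblemError, ProblemBuilder

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelSchemaError",
    "BOUND_CAP",
    "read_model",
    "write_model",
    "add_exchange_reactions",
    "flux_variability",
    "prune_model",
    "PruneReport",
]

BOUND_CAP = 1000.0
#: |flux| below this is numerically zero (LP solver noise floor).
BLOCKED_TOL = 1e-9


class ModelSchemaError(ValueError):
    """Model file violates the expected schema; message names the element."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A (possibly boundary) reaction.

    ``stoichiometry`` maps metabolite id to a non-zero coefficient,
    negative for substrates.  ``gpr`` is the stoichiometric rule tree when
    one is attached; the classical GPR is recovered by stripping
    coefficients.  ``has_sgpr`` records whether stoichiometric information
    was actually supplied (a model imported from plain fbc has rule trees
    but no copy-number knowledge, and S-GPR-mode scoring must refuse it).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = BOUND_CAP
    name: str = ""
    pathway: str | None = None
    gpr: GprTree | None = None
    has_sgpr: bool = False
    ec_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} > upper {self.upper_bound}"
            )
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ValueError(f"reaction {self.id!r}: zero coefficient for {met!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def gpr_string(self) -> str | None:
        return None if self.gpr is None else serialize_gpr(self.gpr, "GPR")

    def sgpr_string(self) -> str | None:
        if self.gpr is None or not self.has_sgpr:
            return None
        return serialize_gpr(self.gpr, "SGPR")


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_reaction_id: str | None = None
    compartments: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelSchemaError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
        if self.objective_reaction_id is not None and self.objective_reaction_id not in self.reactions:
            raise ModelSchemaError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gpr is not None:
                out |= rxn.gpr.genes()
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites={m.id: replace(m) for m in self.metabolites.values()},
            reactions={
                r.id: replace(r, stoichiometry=dict(r.stoichiometry), ec_codes=list(r.ec_codes))
                for r in self.reactions.values()
            },
            objective_reaction_id=self.objective_reaction_id,
            compartments=dict(self.compartments),
        )

    def add_flux_variables(self, pb: ProblemBuilder, prefix: str = "v_") -> dict[str, str]:
        """Add one bounded flux variable per reaction plus steady-state rows.

        Returns the reaction-id -> variable-name map.  Multiple models can
        share one builder by using distinct prefixes (MADE does).
        """
        names = {rid: pb.add_var(prefix + rid, r.lower_bound, r.upper_bound)
                 for rid, r in self.reactions.items()}
        balance: dict[str, dict[str, float]] = {m: {} for m in self.metabolites}
        for rid, rxn in self.reactions.items():
            for met, coef in rxn.stoichiometry.items():
                balance[met][names[rid]] = coef
        for met, coefs in balance.items():
            if coefs:
                pb.add_constraint(coefs, 0.0, 0.0)
        return names


def _cap(value: float, default: float) -> float:
    if value is None or math.isinf(value) or math.isnan(value):
        return default
    return max(-BOUND_CAP, min(BOUND_CAP, float(value)))


# ---------------------------------------------------------------------------
# Native JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": model.compartments,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "pathway": r.pathway,
                "gpr": r.gpr_string(),
                "sgpr": r.sgpr_string(),
                "ec_codes": r.ec_codes,
            }
            for r in model.reactions.values()
        ],
        "objective": model.objective_reaction_id,
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        model = MetabolicModel(id=data.get("id", "model"), compartments=dict(data.get("compartments", {})))
        for m in data["metabolites"]:
            model.metabolites[m["id"]] = Metabolite(
                id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", "c")
            )
        for r in data["reactions"]:
            sgpr = r.get("sgpr")
            gpr = r.get("gpr")
            tree = None
            has_sgpr = False
            if sgpr:
                tree = parse_gpr(sgpr)
                has_sgpr = True
            elif gpr:
                tree = parse_gpr(gpr)
            model.reactions[r["id"]] = Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=_cap(r.get("lower_bound", 0.0), -BOUND_CAP),
                upper_bound=_cap(r.get("upper_bound", BOUND_CAP), BOUND_CAP),
                pathway=r.get("pathway"),
                gpr=tree,
                has_sgpr=has_sgpr,
                ec_codes=list(r.get("ec_codes") or []),
            )
        model.objective_reaction_id = data.get("objective")
    except KeyError as exc:
        raise ModelSchemaError(f"missing required field {exc}") from exc
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML bridge (cobra / libsbml)
# ---------------------------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        mets[m.id] = cmet
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
        if r.pathway:
            cr.notes["pathway"] = r.pathway
            cr.subsystem = r.pathway
        sgpr = r.sgpr_string()
        if sgpr:
            cr.notes["sgpr"] = sgpr
        if r.ec_codes:
            cr.notes["ec_codes"] = ";".join(r.ec_codes)
        rxns.append(cr)
    cm.add_reactions(rxns)
    # gene rules set after add_reactions so genes register with the model
    for r in model.reactions.values():
        if r.gpr is not None:
            cm.reactions.get_by_id(r.id).gene_reaction_rule = serialize_gpr(r.gpr, "GPR")
    if model.objective_reaction_id:
        cm.objective = model.objective_reaction_id
    return cm


def _from_cobra(cm) -> MetabolicModel:
    from cobra.util.solver import linear_reaction_coefficients

    model = MetabolicModel(id=cm.id or "model", compartments=dict(cm.compartments))
    for m in cm.metabolites:
        model.metabolites[m.id] = Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
    for r in cm.reactions:
        sgpr = r.notes.get("sgpr")
        tree = None
        has_sgpr = False
        if sgpr:
            tree = parse_gpr(str(sgpr))
            has_sgpr = True
        elif r.gene_reaction_rule:
            tree = parse_gpr(r.gene_reaction_rule)
        ec_raw = r.notes.get("ec_codes", "")
        model.reactions[r.id] = Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=_cap(r.lower_bound, -BOUND_CAP),
            upper_bound=_cap(r.upper_bound, BOUND_CAP),
            pathway=r.notes.get("pathway") or (r.subsystem or None),
            gpr=tree,
            has_sgpr=has_sgpr,
            ec_codes=[e for e in str(ec_raw).split(";") if e],
        )
    objectives = linear_reaction_coefficients(cm)
    if objectives:
        model.objective_reaction_id = next(iter(objectives)).id
    model.validate()
    return model


def read_model(path: str | Path, fmt: str | None = None) -> MetabolicModel:
    """Read a model from the native JSON dialect or SBML (auto by suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("SBML" if path.suffix.lower() in (".xml", ".sbml") else "JSON")
    if fmt.upper() == "JSON":
        with open(path) as fh:
            return _model_from_dict(json.load(fh))
    import cobra

    return _from_cobra(cobra.io.read_sbml_model(str(path)))


def write_model(model: MetabolicModel, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("SBML" if path.suffix.lower() in (".xml", ".sbml") else "JSON")
    if fmt.upper() == "JSON":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        import cobra

        cobra.io.write_sbml_model(_to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# Exchange-reaction augmentation
# ---------------------------------------------------------------------------

def add_exchange_reactions(
    model: MetabolicModel, metabolite_ids: list[str], cap: float = BOUND_CAP
) -> tuple[MetabolicModel, int]:
    """Ensure each listed metabolite has uptake and secretion exchanges.

    Per metabolite lacking them, two irreversible boundary reactions are
    added: an uptake written as production from nothing (``-> M``, bounds
    [0, cap], so uptake flux is positive) and a secretion (``M ->``, bounds
    [0, cap]).  Nothing is added for a direction an existing exchange
    already covers; a reversible exchange covers both directions.
    """
    unknown = [m for m in metabolite_ids if m not in model.metabolites]
    if unknown:
        raise KeyError(f"unknown metabolite ids: {unknown}")
    model = model.copy()
    n_added = 0
    for mid in metabolite_ids:
        uptake_covered = secretion_covered = False
        for rxn in model.reactions.values():
            if not rxn.is_exchange or mid not in rxn.stoichiometry:
                continue
            coef = rxn.stoichiometry[mid]
            # positive flux * positive coef produces M (uptake into the system)
            if (coef > 0 and rxn.upper_bound > 0) or (coef < 0 and rxn.lower_bound < 0):
                uptake_covered = True
            if (coef < 0 and rxn.upper_bound > 0) or (coef > 0 and rxn.lower_bound < 0):
                secretion_covered = True
        if not uptake_covered:
            rid = f"EX_{mid}_uptake"
            if rid in model.reactions:
                raise ValueError(f"reaction id collision for {rid!r}")
            model.reactions[rid] = Reaction(rid, {mid: 1.0}, 0.0, cap, name=f"{mid} uptake")
            n_added += 1
        if not secretion_covered:
            rid = f"EX_{mid}_secretion"
            if rid in model.reactions:
                raise ValueError(f"reaction id collision for {rid!r}")
            model.reactions[rid] = Reaction(rid, {mid: -1.0}, 0.0, cap, name=f"{mid} secretion")
            n_added += 1
    return model, n_added


# ---------------------------------------------------------------------------
# Flux variability and pruning
# ---------------------------------------------------------------------------

def flux_variability(
    model: MetabolicModel,
    fraction_of_optimum: float | None = None,
    reactions: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction [min, max] flux over the steady-state polytope.

    With ``fraction_of_optimum`` set, the objective reaction's flux is
    first maximized and then constrained to at least that fraction of the
    optimum during the per-reaction sweeps.
    """
    target = reactions if reactions is not None else list(model.reactions)
    opt_constraint = None
    if fraction_of_optimum is not None:
        if model.objective_reaction_id is None:
            raise ValueError("fraction_of_optimum requires an objective reaction")
        pb = ProblemBuilder(sense="max")
        names = model.add_flux_variables(pb)
        pb.set_objective(names[model.objective_reaction_id], 1.0)
        try:
            opt = pb.solve().objective
        except InfeasibleProblemError as exc:
            raise InfeasibleProblemError(f"model {model.id!r} infeasible: {exc}") from exc
        opt_constraint = fraction_of_optimum * opt

    ranges: dict[str, tuple[float, float]] = {}
    for rid in target:
        lohi = []
        for sense in ("min", "max"):
            pb = ProblemBuilder(sense=sense)
            names = model.add_flux_variables(pb)
            pb.set_objective(names[rid], 1.0)
            if opt_constraint is not None:
                pb.add_constraint({names[model.objective_reaction_id]: 1.0}, opt_constraint)
            try:
                lohi.append(pb.solve().objective)
            except InfeasibleProblemError as exc:
                raise InfeasibleProblemError(
                    f"model {model.id!r} infeasible during FVA of {rid!r}: {exc}"
                ) from exc
        ranges[rid] = (lohi[0], lohi[1])
    return ranges


@dataclass
class PruneReport:
    removed_reactions: list[str] = field(default_factory=list)
    tightened_reactions: list[str] = field(default_factory=list)
    removed_metabolites: list[str] = field(default_factory=list)
    iterations: int = 0

    @property
    def empty(self) -> bool:
        return not (self.removed_reactions or self.tightened_reactions or self.removed_metabolites)


def prune_model(model: MetabolicModel, tol: float = BLOCKED_TOL) -> tuple[MetabolicModel, PruneReport]:
    """Remove blocked reactions, tighten one-way reversibles, drop dead ends.

    A reaction whose FVA range is [0, 0] can never carry flux and is
    removed; a reversible reaction with exactly one feasible direction has
    its bounds tightened to that direction; metabolites left with no
    reaction are dropped.  Iterates to a fixed point.  Raises if the
    objective reaction itself is blocked.
    """
    model = model.copy()
    report = PruneReport()
    while True:
        report.iterations += 1
        ranges = flux_variability(model)
        changed = False
        for rid, (lo, hi) in ranges.items():
            blocked = abs(lo) < tol and abs(hi) < tol
            if blocked:
                if rid == model.objective_reaction_id:
                    raise InfeasibleProblemError(
                        f"objective reaction {rid!r} is blocked; the model cannot express its phenotype"
                    )
                del model.reactions[rid]
                report.removed_reactions.append(rid)
                changed = True
                continue
            rxn = model.reactions[rid]
            if rxn.reversible:
                if lo > -tol:  # reverse direction infeasible
                    rxn.lower_bound = 0.0
                    report.tightened_reactions.append(rid)
                    changed = True
                elif hi < tol:  # forward direction infeasible
                    rxn.upper_bound = 0.0
                    report.tightened_reactions.append(rid)
                    changed = True
        used = {m for r in model.reactions.values() for m in r.stoichiometry}
        for mid in [m for m in model.metabolites if m not in used]:
            del model.metabolites[mid]
            report.removed_metabolites.append(mid)
            changed = True
        if not changed:
            break
    return model, report
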