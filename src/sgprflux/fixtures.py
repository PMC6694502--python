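"""Seeded generators for toy networks, expression, and measurements.

The generators emulate the study design the package targets: a metabolic
network with isoenzyme (OR) and multi-copy complex (AND with copy
numbers) motifs, two expression conditions that differ at only a small
fraction of genes, and replicate metabolite peak areas at two time
points.  Everything is driven by a :class:`FixtureSpec` seed, and the
same seed reproduces bit-identical fixtures.

:func:`generate_discriminating_case` builds the deterministic scenario
where stoichiometry changes the outcome: a reaction gated by S-GPR
``2*g1 and g2`` whose GPR score (2.0) sits above and S-GPR score (1.5)
below the integration thresholds, so the classical rule calls its
downstream exchange active while the stoichiometric rule — in agreement
with the bundled measurements — does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .builder import CompositionRow
from .gpr import ExpressionProfile, GprTree
from .integration import (
    ActivityState,
    FluxDistribution,
    IntegrationConfig,
    classify_activity,
)
from .model import MetabolicModel, Metabolite, Reaction
from .solver import InfeasibleProblemError, ProblemBuilder

__all__ = [
    "FixtureSpec",
    "DiscriminatingCase",
    "generate_toy_model",
    "default_planted",
    "planted_state",
    "generate_expression",
    "generate_measurements",
    "composition_table_for",
    "metabolite_exchange_map",
    "generate_discriminating_case",
]

UPTAKE_CAP = 10.0


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults mirror a small two-condition design: two 3-step pathways,
    one isoenzyme pair and one multi-copy complex, log-normal expression
    with sd 0.1 on the log scale, a two-fold separation between the
    expression of active- and inactive-pathway genes, five replicates,
    and 10% of genes changed between conditions.
    """

    seed: int = 0
    n_chains: int = 2
    chain_length: int = 3
    n_branches: int = 1
    n_isozyme_pairs: int = 1
    n_complexes: int = 1
    complex_max_copies: int = 3
    noise_sd: float = 0.1
    n_replicates: int = 5
    effect_size: float = 2.0
    fraction_changed: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_chains", "chain_length", "n_branches", "n_isozyme_pairs", "n_complexes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_complexes and self.complex_max_copies < 2:
            raise ValueError("complex_max_copies must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def metabolite_exchange_map(model: MetabolicModel) -> dict[str, list[str]]:
    """Map each boundary metabolite to its exchange reaction ids."""
    out: dict[str, list[str]] = {}
    for rid, rxn in model.reactions.items():
        if rxn.is_exchange:
            out.setdefault(next(iter(rxn.stoichiometry)), []).append(rid)
    for rids in out.values():
        rids.sort()
    return out


# ---------------------------------------------------------------------------
# Toy model
# ---------------------------------------------------------------------------

def generate_toy_model(spec: FixtureSpec) -> MetabolicModel:
    """Connected toy network of irreversible chains with rule motifs.

    Each chain is uptake -> M_0 -> ... -> M_L -> secretion with one gene
    per internal step; isoenzyme pairs (``gA or gB``) and complexes with
    copy numbers >= 2 (``gX and k*gY``) are distributed over the internal
    reactions round-robin; branches tap a mid-chain metabolite into an
    extra secreted product.  Internal reactions of chain *i* carry pathway
    label ``PWY{i}``; the objective is the first chain's secretion.  By
    construction every reaction can carry flux and nothing is reversible,
    so the model prunes to itself.
    """
    rng = np.random.default_rng(spec.seed)
    model = MetabolicModel(id=f"toy_seed{spec.seed}", compartments={"c": "cytosol"})
    gene_counter = ec_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter}"

    def next_ec() -> str:
        nonlocal ec_counter
        ec_counter += 1
        return f"1.1.1.{ec_counter}"

    internal: list[Reaction] = []
    if spec.n_chains == 0:
        # minimal feasible ->A-> model
        model.metabolites["A"] = Metabolite("A", compartment="c")
        model.reactions["EX_A_uptake"] = Reaction("EX_A_uptake", {"A": 1.0}, 0, UPTAKE_CAP)
        model.reactions["EX_A_secretion"] = Reaction("EX_A_secretion", {"A": -1.0}, 0, UPTAKE_CAP)
        model.objective_reaction_id = "EX_A_secretion"
        model.validate()
        return model

    for chain in range(spec.n_chains):
        mets = [f"M{chain}_{j}" for j in range(spec.chain_length + 1)]
        for mid in mets:
            model.metabolites[mid] = Metabolite(mid, compartment="c")
        rid = f"EX_M{chain}_0_uptake"
        model.reactions[rid] = Reaction(rid, {mets[0]: 1.0}, 0, UPTAKE_CAP)
        for j in range(spec.chain_length):
            rid = f"R{chain}_{j}"
            rxn = Reaction(
                rid,
                {mets[j]: -1.0, mets[j + 1]: 1.0},
                0,
                UPTAKE_CAP,
                pathway=f"PWY{chain}",
                gpr=GprTree.gene(next_gene()),
                has_sgpr=True,
                ec_codes=[next_ec()],
            )
            model.reactions[rid] = rxn
            internal.append(rxn)
        rid = f"EX_M{chain}_{spec.chain_length}_secretion"
        model.reactions[rid] = Reaction(rid, {mets[-1]: -1.0}, 0, UPTAKE_CAP)

    for b in range(spec.n_branches):
        chain = b % spec.n_chains
        tap = f"M{chain}_{max(1, spec.chain_length // 2)}"
        bm = f"B{b}"
        model.metabolites[bm] = Metabolite(bm, compartment="c")
        rid = f"RB{b}"
        rxn = Reaction(
            rid,
            {tap: -1.0, bm: 1.0},
            0,
            UPTAKE_CAP,
            pathway=f"PWY{chain}",
            gpr=GprTree.gene(next_gene()),
            has_sgpr=True,
            ec_codes=[next_ec()],
        )
        model.reactions[rid] = rxn
        internal.append(rxn)
        rid = f"EX_{bm}_secretion"
        model.reactions[rid] = Reaction(rid, {bm: -1.0}, 0, UPTAKE_CAP)

    # decorate internal reactions with isoenzyme and complex motifs
    slots = list(internal)
    for k in range(spec.n_isozyme_pairs):
        rxn = slots[k % len(slots)]
        rxn.gpr = GprTree.or_(GprTree.gene(next_gene()), GprTree.gene(next_gene()))
    for k in range(spec.n_complexes):
        rxn = slots[(spec.n_isozyme_pairs + k) % len(slots)]
        copies = int(rng.integers(2, spec.complex_max_copies + 1))
        rxn.gpr = GprTree.and_(GprTree.gene(next_gene()), GprTree.gene(next_gene(), copies))

    model.objective_reaction_id = f"EX_M0_{spec.chain_length}_secretion"
    model.validate()
    return model


def default_planted(model: MetabolicModel) -> set[str]:
    """Planted-active set: GPR-carrying reactions of even-numbered pathways."""
    out = set()
    for rid, rxn in model.reactions.items():
        if rxn.gpr is not None and rxn.pathway and int(rxn.pathway.removeprefix("PWY")) % 2 == 0:
            out.add(rid)
    return out


def _planted_witness(
    model: MetabolicModel, planted: set[str], config: IntegrationConfig
) -> FluxDistribution:
    pb = ProblemBuilder(sense="min")
    names = model.add_flux_variables(pb)
    for rid, rxn in model.reactions.items():
        if rid in planted:
            # irreversible fixtures: force forward flux
            pb.add_constraint({names[rid]: 1.0}, config.flux_epsilon)
        elif rxn.gpr is not None:
            pb.add_constraint(
                {names[rid]: 1.0}, -config.activity_epsilon, config.activity_epsilon
            )
    t = {}
    for rid, v in names.items():
        tv = pb.add_var("t_" + rid, 0.0, obj=1.0)
        pb.add_constraint({tv: 1.0, v: -1.0}, 0.0)
        pb.add_constraint({tv: 1.0, v: 1.0}, 0.0)
    try:
        sol = pb.solve()
    except InfeasibleProblemError as exc:
        raise InfeasibleProblemError(
            f"planted set {sorted(planted)} is not a feasible active pattern: {exc}"
        ) from exc
    return FluxDistribution({r: sol[v] for r, v in names.items()})


def planted_state(
    model: MetabolicModel, planted: set[str], config: IntegrationConfig | None = None
) -> ActivityState:
    """Full activity state implied by a planted-active reaction set.

    The witness is the minimum-total-flux distribution that forces flux
    through every planted reaction and none through the other
    rule-carrying reactions; exchanges fall where stoichiometry puts them.
    Raises when the planted pattern is infeasible.
    """
    config = config or IntegrationConfig()
    return classify_activity(_planted_witness(model, planted, config), config)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    model: MetabolicModel,
    planted_active: set[str],
    spec: FixtureSpec,
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Two-condition expression profiles around a planted activity pattern.

    Genes of planted-active reactions draw log-normally around a high
    mean, all others around a low mean (ratio = ``effect_size``); a gene
    contributing ``k`` copies to a planted complex draws around ``k``
    times the high mean so its per-complex level stays high.  The treated
    condition re-draws a ``fraction_changed`` subset of genes from the
    opposite class.  Per-gene log2 fold changes and Welch-t p-values are
    computed from the replicate draws and attached to the treated profile.
    """
    planted_state(model, planted_active, IntegrationConfig())  # feasibility gate
    rng = np.random.default_rng(spec.seed + 1)
    high, low = spec.effect_size, 1.0

    targets: dict[str, float] = {}
    for rid, rxn in sorted(model.reactions.items()):
        if rxn.gpr is None:
            continue
        for leaf in rxn.gpr.leaves():
            base = high * leaf.copy_number if rid in planted_active else low
            targets[leaf.gene_id] = max(targets.get(leaf.gene_id, 0.0), base)

    genes = sorted(targets)
    changed = {
        g for g in genes if rng.random() < spec.fraction_changed
    }

    def draw(mean: float) -> np.ndarray:
        return mean * np.exp(rng.normal(0.0, spec.noise_sd, size=spec.n_replicates))

    control_reps: dict[str, np.ndarray] = {}
    treated_reps: dict[str, np.ndarray] = {}
    for g in genes:
        control_reps[g] = draw(targets[g])
        if g in changed:
            flipped = targets[g] / spec.effect_size if targets[g] > low else targets[g] * spec.effect_size
            treated_reps[g] = draw(flipped)
        else:
            treated_reps[g] = draw(targets[g])

    log_fc, p_value = {}, {}
    for g in genes:
        log_fc[g] = float(np.log2(treated_reps[g].mean() / control_reps[g].mean()))
        if spec.noise_sd == 0:
            p_value[g] = 0.0 if g in changed else 1.0
        else:
            p_value[g] = float(
                stats.ttest_ind(
                    np.log(treated_reps[g]), np.log(control_reps[g]), equal_var=False
                ).pvalue
            )

    control = ExpressionProfile(
        values={g: float(r.mean()) for g, r in control_reps.items()}, condition="control"
    )
    treated = ExpressionProfile(
        values={g: float(r.mean()) for g, r in treated_reps.items()},
        p_value=p_value,
        log_fc=log_fc,
        condition="treated",
    )
    return control, treated


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def generate_measurements(
    model: MetabolicModel,
    state: ActivityState,
    spec: FixtureSpec,
    change_factor: float = 3.0,
    base_area: float = 1000.0,
):
    """Replicate peak areas consistent with an exchange activity state.

    Metabolites whose exchange reactions are active get a
    ``change_factor`` shift between t0 and t5h (direction by exchange
    orientation: net secretion raises the area, net uptake lowers it);
    inactive exchanges stay level.  Multiplicative log-normal noise with
    sd ``noise_sd`` on the log scale is applied per replicate.
    """
    from .evaluation import MetaboliteMeasurement

    rng = np.random.default_rng(spec.seed + 2)
    out = []
    for met, rids in sorted(metabolite_exchange_map(model).items()):
        active = [r for r in rids if state.states.get(r) == "active"]
        secreting = any(
            model.reactions[r].stoichiometry[met] < 0 for r in active
        )
        factor = 1.0
        if active:
            factor = change_factor if secreting else 1.0 / change_factor
        noise = lambda: np.exp(rng.normal(0.0, spec.noise_sd, size=spec.n_replicates))
        t0 = base_area * noise()
        t5 = base_area * factor * noise()
        out.append(MetaboliteMeasurement(met, t0.tolist(), t5.tolist()))
    return out


# ---------------------------------------------------------------------------
# Composition table
# ---------------------------------------------------------------------------

def composition_table_for(model: MetabolicModel) -> list[CompositionRow]:
    """Composition rows that rebuild each reaction's rule tree.

    Supports the shapes the toy generator emits (single leaf, OR of
    leaves/ANDs, AND of leaves): the top-level OR branches become
    catalytic units, AND members become subunit rows with copy numbers.
    """
    rows: list[CompositionRow] = []
    for rid, rxn in sorted(model.reactions.items()):
        if rxn.gpr is None or not rxn.ec_codes:
            continue
        comp = model.metabolites[next(iter(rxn.stoichiometry))].compartment
        ec = rxn.ec_codes[0]
        units = list(rxn.gpr.children) if rxn.gpr.kind == "OR" else [rxn.gpr]
        for u, unit in enumerate(units, start=1):
            leaves = [unit] if unit.kind == "GENE" else list(unit.children)
            for leaf in leaves:
                if leaf.kind != "GENE":
                    raise ValueError(f"reaction {rid!r}: rule tree too nested for table export")
                rows.append(
                    CompositionRow(ec, comp, f"U{u}", leaf.gene_id, leaf.copy_number)
                )
    return rows


# ---------------------------------------------------------------------------
# The discriminating case
# ---------------------------------------------------------------------------

@dataclass
class DiscriminatingCase:
    model: MetabolicModel
    profile: ExpressionProfile
    measurements: list = field(default_factory=list)
    metabolite_exchanges: dict[str, list[str]] = field(default_factory=dict)
    gimme_config: IntegrationConfig = field(default_factory=IntegrationConfig)
    imat_config: IntegrationConfig = field(default_factory=IntegrationConfig)


def generate_discriminating_case() -> DiscriminatingCase:
    """Deterministic fixture on which GPR and S-GPR verdicts diverge.

    The network converts A to the secreted product B through two routes:
    a plain reaction (gene g3, score 1.6) and a complex-catalyzed
    reaction needing two copies of g1 (S-GPR ``2*g1 and g2``) that
    co-produces a side metabolite M.  With expression g1=3, g2=2 the
    complex route scores min(3, 2) = 2 classically but min(3/2, 2) = 1.5
    stoichiometrically.  The integration thresholds sit between 1.5 and
    2, so classical rules route flux through the complex (secreting M)
    while stoichiometric rules avoid it; the bundled measurements show no
    change in M, so only the S-GPR verdict is right.
    """
    from .evaluation import MetaboliteMeasurement

    model = MetabolicModel(id="discriminating", compartments={"c": "cytosol"})
    for mid in ("A", "B", "M"):
        model.metabolites[mid] = Metabolite(mid, compartment="c")
    model.reactions["EX_A_uptake"] = Reaction("EX_A_uptake", {"A": 1.0}, 0, UPTAKE_CAP)
    model.reactions["R_alt"] = Reaction(
        "R_alt", {"A": -1.0, "B": 1.0}, 0, UPTAKE_CAP,
        pathway="alternative route", gpr=GprTree.gene("g3"), has_sgpr=True,
    )
    model.reactions["R_cx"] = Reaction(
        "R_cx", {"A": -1.0, "B": 1.0, "M": 1.0}, 0, UPTAKE_CAP,
        pathway="complex route",
        gpr=GprTree.and_(GprTree.gene("g1", 2), GprTree.gene("g2")),
        has_sgpr=True,
    )
    model.reactions["EX_B_secretion"] = Reaction("EX_B_secretion", {"B": -1.0}, 0, UPTAKE_CAP)
    model.reactions["EX_M_secretion"] = Reaction("EX_M_secretion", {"M": -1.0}, 0, UPTAKE_CAP)
    model.reactions["EX_M_uptake"] = Reaction("EX_M_uptake", {"M": 1.0}, 0, UPTAKE_CAP)
    model.objective_reaction_id = "EX_B_secretion"
    model.validate()

    profile = ExpressionProfile(values={"g1": 3.0, "g2": 2.0, "g3": 1.6}, condition="exposed")

    measurements = [
        MetaboliteMeasurement("B", [100, 102, 104, 106, 108], [300, 303, 306, 309, 312]),
        MetaboliteMeasurement("M", [200, 201, 202, 203, 204], [200.5, 201.5, 199.5, 202.5, 198.5]),
    ]
    return DiscriminatingCase(
        model=model,
        profile=profile,
        measurements=measurements,
        metabolite_exchanges={"B": ["EX_B_secretion"], "M": ["EX_M_secretion", "EX_M_uptake"]},
        gimme_config=IntegrationConfig(
            gimme_threshold_mode="absolute", gimme_threshold_value=1.75
        ),
        imat_config=IntegrationConfig(),
    )
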