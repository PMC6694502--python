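"""FBA/pFBA cores and four transcriptome-constrained integration methods.

All four methods consume reaction-level expression scores produced by
propagating a profile through each reaction's GPR or S-GPR tree
(:func:`reaction_scores`):

* **GIMME** — LP; penalizes flux through reactions scored below a
  threshold (mean + SD of defined scores by default) while retaining a
  required fraction of the objective optimum (the RMF).  The optimal
  penalty sum is the inconsistency score.
* **iMAT** — MILP; partitions scored reactions into highly/lowly expressed
  by score quantiles (40th/60th percentiles by default) and maximizes the
  number of high reactions carrying at least epsilon flux in either
  direction plus low reactions carrying none.
* **Gonçalves-style relative integration** — pFBA on the untreated model
  fixes control fluxes v_c; each scored reaction's treated flux is then
  confined to the interval between v_c and r*v_c (r the treated/control
  expression ratio, sign preserved) and the treated state is the
  minimal-total-flux solution under those bounds.
* **MADE** — MILP over paired binary activity vectors (control, treated);
  per-reaction desired transitions (up/down/same) come from propagating
  gene log-fold-changes through the rule tree and thresholding at a
  significance level; matched transitions are rewarded with weight 1 - p.

Every method resolves LP/MILP degeneracy with a parsimonious second
stage (fix the method's optimum, minimize total absolute flux) before
reactions are classified active (|v| >= activity_epsilon) or inactive,
which makes the reported activity states reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean
from typing import Literal

import numpy as np

from .gpr import ExpressionProfile, GprConfig, GprTree, evaluate_values
from .model import MetabolicModel
from .solver import InfeasibleProblemError, ProblemBuilder

__all__ = [
    "FluxDistribution",
    "ReactionScoreSet",
    "IntegrationConfig",
    "ActivityState",
    "reaction_scores",
    "ratio_profile",
    "fba",
    "pfba",
    "classify_activity",
    "gimme",
    "imat",
    "goncalves",
    "made",
    "GimmeResult",
    "ImatResult",
    "GoncalvesResult",
    "MadeResult",
]


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def total_absolute_flux(self) -> float:
        return sum(abs(v) for v in self.fluxes.values())


@dataclass
class ReactionScoreSet:
    """Reaction-level expression scores; only catalyzed reactions appear."""

    scores: dict[str, float]
    provenance: Literal["GPR", "SGPR"]
    condition: str = ""


@dataclass
class ActivityState:
    """Binary activity labels per reaction, plus optional input labels."""

    states: dict[str, Literal["active", "inactive"]]
    input_labels: dict[str, str] = field(default_factory=dict)
    condition: str = ""

    def active_reactions(self) -> set[str]:
        return {r for r, s in self.states.items() if s == "active"}


@dataclass
class IntegrationConfig:
    """Shared knobs for the integration methods.

    ``activity_epsilon`` is the classification tolerance (|v| at or above
    it counts as active); ``flux_epsilon`` is the larger flux magnitude
    the iMAT/MADE MILPs force through a reaction declared active (the
    original iMAT convention of 1.0).  GIMME's threshold is mean + SD of
    the defined scores unless a percentile or absolute value is chosen.
    ``random_seed`` is carried for interface stability; the solver path is
    deterministic and does not consume it.
    """

    activity_epsilon: float = 1e-6
    flux_epsilon: float = 1.0
    gimme_threshold_mode: Literal["mean_plus_sd", "percentile", "absolute"] = "mean_plus_sd"
    gimme_threshold_value: float = 0.0  # percentile q or absolute x, per mode
    gimme_rmf_fraction: float = 0.9
    imat_low_quantile: float = 0.40
    imat_high_quantile: float = 0.60
    made_alpha: float = 0.05
    made_rmf_fraction: float = 0.9
    optimality_tolerance: float = 1e-9
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gimme_rmf_fraction <= 1.0:
            raise ValueError("gimme_rmf_fraction must be in (0, 1]")
        if not self.imat_low_quantile < self.imat_high_quantile:
            raise ValueError("imat_low_quantile must be < imat_high_quantile")


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def reaction_scores(
    model: MetabolicModel,
    profile: ExpressionProfile,
    gpr_config: GprConfig | None = None,
) -> ReactionScoreSet:
    """Propagate a profile through every reaction's rule tree.

    In SGPR mode, reactions whose rules were loaded without stoichiometric
    information are refused (the copy numbers are simply unknown).
    """
    gpr_config = gpr_config or GprConfig()
    scores: dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        if rxn.gpr is None:
            continue
        if gpr_config.gpr_mode == "SGPR" and not rxn.has_sgpr:
            raise ValueError(
                f"reaction {rid!r} has no S-GPR information; cannot score in SGPR mode"
            )
        value = evaluate_values(rxn.gpr, profile.values, gpr_config)
        if value is not None:
            scores[rid] = value
    return ReactionScoreSet(
        scores=scores, provenance=gpr_config.gpr_mode, condition=profile.condition
    )


def ratio_profile(
    control: ExpressionProfile, treated: ExpressionProfile
) -> ExpressionProfile:
    """Per-gene treated/control expression ratios (genes measured in both).

    Genes with zero control expression are dropped (the ratio is
    undefined); downstream methods treat them as unscored.
    """
    values = {
        g: treated.values[g] / control.values[g]
        for g in treated.values
        if g in control.values and control.values[g] > 0
    }
    return ExpressionProfile(
        values=values,
        p_value=dict(treated.p_value),
        log_fc=dict(treated.log_fc),
        condition=f"{treated.condition or 'treated'}/{control.condition or 'control'}",
    )


# ---------------------------------------------------------------------------
# FBA / pFBA
# ---------------------------------------------------------------------------

def _abs_flux_vars(
    pb: ProblemBuilder, names: dict[str, str], prefix: str = "t_"
) -> dict[str, str]:
    """Auxiliary t_r >= |v_r| variables (tight at any L1 minimum)."""
    tnames = {}
    for rid, vname in names.items():
        t = pb.add_var(prefix + rid, 0.0)
        pb.add_constraint({t: 1.0, vname: -1.0}, 0.0)  # t >= v
        pb.add_constraint({t: 1.0, vname: 1.0}, 0.0)  # t >= -v
        tnames[rid] = t
    return tnames


def fba(
    model: MetabolicModel, objective: str | None = None
) -> tuple[float, FluxDistribution]:
    """Maximize the objective reaction's flux; return optimum and a witness."""
    objective = objective or model.objective_reaction_id
    if objective is None:
        raise ValueError("no objective reaction given or set on the model")
    pb = ProblemBuilder(sense="max")
    names = model.add_flux_variables(pb)
    pb.set_objective(names[objective], 1.0)
    sol = pb.solve()
    return sol.objective, FluxDistribution({r: sol[v] for r, v in names.items()})


def pfba(model: MetabolicModel, objective: str | None = None) -> FluxDistribution:
    """Parsimonious FBA: fix the FBA optimum, then minimize total |v|."""
    objective = objective or model.objective_reaction_id
    opt, _ = fba(model, objective)
    pb = ProblemBuilder(sense="min")
    names = model.add_flux_variables(pb)
    tnames = _abs_flux_vars(pb, names)
    for t in tnames.values():
        pb.set_objective(t, 1.0)
    pb.add_constraint({names[objective]: 1.0}, opt - 1e-9 * max(1.0, abs(opt)))
    sol = pb.solve()
    return FluxDistribution({r: sol[v] for r, v in names.items()})


def classify_activity(
    flux: FluxDistribution, config: IntegrationConfig | None = None
) -> ActivityState:
    """Active iff the reaction carries flux in either direction."""
    config = config or IntegrationConfig()
    eps = config.activity_epsilon
    return ActivityState(
        states={
            rid: "active" if abs(v) >= eps else "inactive"
            for rid, v in flux.fluxes.items()
        }
    )


# ---------------------------------------------------------------------------
# GIMME
# ---------------------------------------------------------------------------

@dataclass
class GimmeResult:
    flux: FluxDistribution
    inconsistency: float
    activity: ActivityState
    threshold: float
    penalties: dict[str, float]


def gimme_threshold(scores: ReactionScoreSet, config: IntegrationConfig) -> float:
    vals = np.array(list(scores.scores.values()), dtype=float)
    if vals.size == 0:
        raise ValueError("no defined reaction scores; cannot resolve a GIMME threshold")
    mode = config.gimme_threshold_mode
    if mode == "mean_plus_sd":
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return float(np.mean(vals)) + sd
    if mode == "percentile":
        return float(np.percentile(vals, config.gimme_threshold_value))
    if mode == "absolute":
        return float(config.gimme_threshold_value)
    raise ValueError(f"unknown gimme_threshold_mode {mode!r}")


def gimme(
    model: MetabolicModel,
    scores: ReactionScoreSet,
    config: IntegrationConfig | None = None,
    objective: str | None = None,
) -> GimmeResult:
    """Penalized-flux integration with a required metabolic functionality.

    Minimizes sum(max(0, threshold - score_r) * |v_r|) subject to steady
    state, bounds, and objective flux >= rmf_fraction * FBA optimum.  The
    optimal value is the inconsistency score; 0 means a fully consistent
    flux exists through adequately expressed reactions only.
    """
    config = config or IntegrationConfig()
    objective = objective or model.objective_reaction_id
    if objective is None:
        raise ValueError("GIMME requires an objective reaction (the RMF)")
    threshold = gimme_threshold(scores, config)
    penalties = {
        rid: max(0.0, threshold - s) for rid, s in scores.scores.items()
    }
    opt, _ = fba(model, objective)
    rmf = config.gimme_rmf_fraction * opt

    def build(extra_l1: bool, cap_inconsistency: float | None):
        pb = ProblemBuilder(sense="min")
        names = model.add_flux_variables(pb)
        tnames = _abs_flux_vars(pb, names)
        pb.add_constraint({names[objective]: 1.0}, rmf)
        pen_expr = {tnames[rid]: c for rid, c in penalties.items() if c > 0}
        if extra_l1:
            for t in tnames.values():
                pb.set_objective(t, 1.0)
            if pen_expr and cap_inconsistency is not None:
                pb.add_constraint(pen_expr, -math.inf, cap_inconsistency)
        else:
            for t, c in pen_expr.items():
                pb.set_objective(t, c)
        return pb, names

    pb, names = build(False, None)
    try:
        sol = pb.solve()
    except InfeasibleProblemError as exc:
        raise InfeasibleProblemError(
            f"RMF infeasible: objective {objective!r} cannot reach {rmf:g}"
        ) from exc
    inconsistency = sol.objective
    # parsimonious tie-break at the optimal inconsistency
    slack = config.optimality_tolerance * max(1.0, abs(inconsistency))
    pb2, names2 = build(True, inconsistency + slack)
    sol2 = pb2.solve()
    flux = FluxDistribution({r: sol2[v] for r, v in names2.items()})
    return GimmeResult(
        flux=flux,
        inconsistency=inconsistency,
        activity=classify_activity(flux, config),
        threshold=threshold,
        penalties=penalties,
    )


# ---------------------------------------------------------------------------
# iMAT
# ---------------------------------------------------------------------------

@dataclass
class ImatResult:
    activity: ActivityState
    flux: FluxDistribution
    objective_value: float
    labels: dict[str, str]  # high / moderate / low per scored reaction
    thresholds: tuple[float, float]


def imat_partition(
    scores: ReactionScoreSet, config: IntegrationConfig
) -> tuple[dict[str, str], tuple[float, float]]:
    """Label scored reactions high/moderate/low by score quantiles."""
    vals = np.array(list(scores.scores.values()), dtype=float)
    if vals.size == 0:
        raise ValueError("no defined reaction scores; cannot partition for iMAT")
    lo = float(np.quantile(vals, config.imat_low_quantile))
    hi = float(np.quantile(vals, config.imat_high_quantile))
    labels = {}
    for rid, s in scores.scores.items():
        if s > hi:
            labels[rid] = "high"
        elif s < lo:
            labels[rid] = "low"
        else:
            labels[rid] = "moderate"
    return labels, (lo, hi)


def _imat_problem(
    model: MetabolicModel,
    labels: dict[str, str],
    config: IntegrationConfig,
) -> tuple[ProblemBuilder, dict[str, str], list[str]]:
    """Shared MILP skeleton: flux vars + indicator binaries + reward list."""
    eps = config.flux_epsilon
    eps0 = config.activity_epsilon
    pb = ProblemBuilder(sense="max")
    names = model.add_flux_variables(pb)
    reward_vars: list[str] = []
    for rid, label in labels.items():
        rxn = model.reactions[rid]
        v = names[rid]
        if label == "high":
            ys = []
            if rxn.upper_bound >= eps:
                yf = pb.add_var("yf_" + rid, 0, 1, integer=True)
                # yf = 1  =>  v >= eps
                pb.add_constraint({v: 1.0, yf: -(eps - rxn.lower_bound)}, rxn.lower_bound)
                ys.append(yf)
            if rxn.lower_bound <= -eps:
                yb = pb.add_var("yb_" + rid, 0, 1, integer=True)
                # yb = 1  =>  v <= -eps
                pb.add_constraint({v: 1.0, yb: (eps + rxn.upper_bound)}, -math.inf, rxn.upper_bound)
                ys.append(yb)
            if len(ys) == 2:
                pb.add_constraint({ys[0]: 1.0, ys[1]: 1.0}, -math.inf, 1.0)
            reward_vars.extend(ys)
        elif label == "low":
            x = pb.add_var("x_" + rid, 0, 1, integer=True)
            # x = 1  =>  |v| <= activity_epsilon
            pb.add_constraint({v: 1.0, x: (rxn.upper_bound - eps0)}, -math.inf, rxn.upper_bound)
            pb.add_constraint({v: 1.0, x: (rxn.lower_bound + eps0)}, rxn.lower_bound)
            reward_vars.append(x)
    return pb, names, reward_vars


def imat(
    model: MetabolicModel,
    scores: ReactionScoreSet,
    config: IntegrationConfig | None = None,
) -> ImatResult:
    """Quantile-partitioned MILP activity maximization.

    Rewards each highly-expressed reaction that carries |v| >= flux_epsilon
    in either direction and each lowly-expressed reaction that carries
    none; the returned flux is a parsimonious witness of an optimal
    assignment.
    """
    config = config or IntegrationConfig()
    labels, thresholds = imat_partition(scores, config)

    pb, names, reward_vars = _imat_problem(model, labels, config)
    for y in reward_vars:
        pb.set_objective(y, 1.0)
    sol = pb.solve()
    best = sol.objective

    # parsimonious witness at the optimal reward
    pb2, names2, reward_vars2 = _imat_problem(model, labels, config)
    tnames = _abs_flux_vars(pb2, names2)
    pb2.sense = "min"
    for t in tnames.values():
        pb2.set_objective(t, 1.0)
    if reward_vars2:
        pb2.add_constraint({y: 1.0 for y in reward_vars2}, round(best) - 0.5)
    sol2 = pb2.solve()
    flux = FluxDistribution({r: sol2[v] for r, v in names2.items()})
    state = classify_activity(flux, config)
    state.input_labels = dict(labels)
    return ImatResult(
        activity=state,
        flux=flux,
        objective_value=float(round(best)),
        labels=labels,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Gonçalves-style relative integration
# ---------------------------------------------------------------------------

@dataclass
class GoncalvesResult:
    control_flux: FluxDistribution
    treated_flux: FluxDistribution
    control_activity: ActivityState
    treated_activity: ActivityState
    rescaled_bounds: dict[str, tuple[float, float]]


def goncalves(
    model: MetabolicModel,
    relative_scores: ReactionScoreSet,
    config: IntegrationConfig | None = None,
    objective: str | None = None,
) -> GoncalvesResult:
    """Relative-expression bound rescaling around a control pFBA state.

    Step 1: pFBA on the unmodified model gives control fluxes v_c.
    Step 2: each reaction with a defined treated/control ratio r has its
    treated flux confined to the closed interval between v_c and r*v_c
    (sign preserved), intersected with the original bounds.
    Step 3: the treated state is the minimum-total-flux distribution under
    the rescaled bounds; the interval lower ends keep the control
    phenotype flowing, and not re-maximizing the objective lets
    down-regulation actually lower flux.
    """
    config = config or IntegrationConfig()
    control = pfba(model, objective)

    treated_model = model.copy()
    rescaled: dict[str, tuple[float, float]] = {}
    bad: list[str] = []
    for rid, ratio in relative_scores.scores.items():
        rxn = treated_model.reactions[rid]
        vc = control[rid]
        lo, hi = min(vc, ratio * vc), max(vc, ratio * vc)
        new_lb = max(rxn.lower_bound, lo)
        new_ub = min(rxn.upper_bound, hi)
        if new_lb > new_ub + 1e-12:
            bad.append(rid)
            continue
        rxn.lower_bound, rxn.upper_bound = new_lb, min(new_ub, max(new_lb, new_ub))
        rescaled[rid] = (new_lb, new_ub)
    if bad:
        raise InfeasibleProblemError(
            f"contradictory bounds after expression rescaling for reactions: {bad}"
        )

    pb = ProblemBuilder(sense="min")
    names = treated_model.add_flux_variables(pb)
    tnames = _abs_flux_vars(pb, names)
    for t in tnames.values():
        pb.set_objective(t, 1.0)
    try:
        sol = pb.solve()
    except InfeasibleProblemError as exc:
        raise InfeasibleProblemError(
            f"treated model infeasible under rescaled bounds: {exc}"
        ) from exc
    treated = FluxDistribution({r: sol[v] for r, v in names.items()})
    return GoncalvesResult(
        control_flux=control,
        treated_flux=treated,
        control_activity=classify_activity(control, config),
        treated_activity=classify_activity(treated, config),
        rescaled_bounds=rescaled,
    )


# ---------------------------------------------------------------------------
# MADE
# ---------------------------------------------------------------------------

@dataclass
class MadeResult:
    control_activity: ActivityState
    treated_activity: ActivityState
    objective_value: float
    desired: dict[str, str]  # up / down / same per scored reaction
    weights: dict[str, float]


def _propagate_lfc(
    tree: GprTree,
    log_fc: dict[str, float],
    p_value: dict[str, float],
    gpr_config: GprConfig,
) -> tuple[float, float] | None:
    """Reaction-level (log fold change, p) through the rule tree.

    The log-fold-change aggregates exactly like expression (AND -> min,
    OR -> mean/max, SGPR divides leaves by copy number); the p-value
    carried along is that of the selected limiting/leading leaf (mean of
    the branch p-values under OR-mean).
    """
    if tree.kind == "GENE":
        if tree.gene_id not in log_fc:
            return None
        v = float(log_fc[tree.gene_id])
        if gpr_config.gpr_mode == "SGPR":
            v = v / tree.copy_number
        return v, float(p_value.get(tree.gene_id, 1.0))
    pairs = [
        p
        for p in (_propagate_lfc(c, log_fc, p_value, gpr_config) for c in tree.children)
        if p is not None
    ]
    if not pairs:
        return None
    if tree.kind == "AND":
        return min(pairs, key=lambda t: t[0])
    if gpr_config.or_mode == "max":
        return max(pairs, key=lambda t: t[0])
    return fmean(p[0] for p in pairs), fmean(p[1] for p in pairs)


def made_transitions(
    model: MetabolicModel,
    profile_treated: ExpressionProfile,
    gpr_config: GprConfig,
    alpha: float,
) -> tuple[dict[str, str], dict[str, float]]:
    """Desired per-reaction transitions and their weights (1 - p)."""
    desired: dict[str, str] = {}
    weights: dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        if rxn.gpr is None:
            continue
        if gpr_config.gpr_mode == "SGPR" and not rxn.has_sgpr:
            raise ValueError(
                f"reaction {rid!r} has no S-GPR information; cannot score in SGPR mode"
            )
        pair = _propagate_lfc(rxn.gpr, profile_treated.log_fc, profile_treated.p_value, gpr_config)
        if pair is None:
            continue
        lfc, p = pair
        if p < alpha and lfc > 0:
            desired[rid] = "up"
        elif p < alpha and lfc < 0:
            desired[rid] = "down"
        else:
            desired[rid] = "same"
        weights[rid] = 1.0 - p
    return desired, weights


def _made_condition_block(
    pb: ProblemBuilder,
    model: MetabolicModel,
    prefix: str,
    desired: dict[str, str],
    config: IntegrationConfig,
    objective: str,
    rmf: float,
) -> tuple[dict[str, str], dict[str, dict[str, float]]]:
    """Flux vars + activity binaries for one condition.

    Returns (flux var names, activity expression per scored reaction): the
    activity of reaction r is the sum of its direction binaries (1 when
    the reaction carries |v| >= flux_epsilon, 0 when |v| <= the
    classification epsilon).
    """
    eps = config.flux_epsilon
    eps0 = config.activity_epsilon
    names = model.add_flux_variables(pb, prefix=f"v{prefix}_")
    pb.add_constraint({names[objective]: 1.0}, rmf)
    activity: dict[str, dict[str, float]] = {}
    for rid in desired:
        rxn = model.reactions[rid]
        v = names[rid]
        dirs: list[str] = []
        if rxn.upper_bound >= eps:
            f = pb.add_var(f"f{prefix}_{rid}", 0, 1, integer=True)
            pb.add_constraint({v: 1.0, f: -(eps - rxn.lower_bound)}, rxn.lower_bound)
            dirs.append(f)
        if rxn.lower_bound <= -eps:
            b = pb.add_var(f"b{prefix}_{rid}", 0, 1, integer=True)
            pb.add_constraint({v: 1.0, b: (eps + rxn.upper_bound)}, -math.inf, rxn.upper_bound)
            dirs.append(b)
        if len(dirs) == 2:
            pb.add_constraint({dirs[0]: 1.0, dirs[1]: 1.0}, -math.inf, 1.0)
        a_expr = {d: 1.0 for d in dirs}
        # a = 0 (all direction binaries zero)  =>  |v| <= eps0
        pb.add_constraint(
            {v: 1.0, **{d: -(rxn.upper_bound - eps0) for d in dirs}}, -math.inf, eps0
        )
        pb.add_constraint({v: 1.0, **{d: -(rxn.lower_bound + eps0) for d in dirs}}, -eps0)
        activity[rid] = a_expr
    return names, activity


def _build_made_problem(
    model_control: MetabolicModel,
    model_treated: MetabolicModel,
    desired: dict[str, str],
    weights: dict[str, float],
    config: IntegrationConfig,
    objective_control: str,
    objective_treated: str,
    rmf_control: float,
    rmf_treated: float,
):
    pb = ProblemBuilder(sense="max")
    names_c, act_c = _made_condition_block(
        pb, model_control, "c", desired, config, objective_control, rmf_control
    )
    names_t, act_t = _made_condition_block(
        pb, model_treated, "t", desired, config, objective_treated, rmf_treated
    )
    match_vars: dict[str, str] = {}
    for rid, want in desired.items():
        m = pb.add_var("m_" + rid, 0, 1)
        ac, at = act_c[rid], act_t[rid]
        if want == "up":  # control inactive, treated active
            pb.add_constraint({m: 1.0, **{d: 1.0 for d in ac}}, -math.inf, 1.0)
            pb.add_constraint({m: 1.0, **{d: -1.0 for d in at}}, -math.inf, 0.0)
        elif want == "down":  # control active, treated inactive
            pb.add_constraint({m: 1.0, **{d: -1.0 for d in ac}}, -math.inf, 0.0)
            pb.add_constraint({m: 1.0, **{d: 1.0 for d in at}}, -math.inf, 1.0)
        else:  # same activity on both sides
            pb.add_constraint(
                {m: 1.0, **{d: -1.0 for d in ac}, **{d: 1.0 for d in at}}, -math.inf, 1.0
            )
            pb.add_constraint(
                {m: 1.0, **{d: 1.0 for d in ac}, **{d: -1.0 for d in at}}, -math.inf, 1.0
            )
        match_vars[rid] = m
    return pb, names_c, names_t, match_vars


def made(
    model_control: MetabolicModel,
    model_treated: MetabolicModel,
    profile_treated: ExpressionProfile,
    config: IntegrationConfig | None = None,
    gpr_config: GprConfig | None = None,
) -> MadeResult:
    """Metabolic adjustment by differential expression, over two conditions.

    ``model_control`` and ``model_treated`` share a network (bounds may
    differ).  ``profile_treated`` must carry per-gene log_fc and p_value
    relative to control.  Both conditions must meet their RMF (objective
    flux >= made_rmf_fraction of that condition's FBA optimum); the MILP
    maximizes the weighted number of realized desired transitions.
    """
    config = config or IntegrationConfig()
    gpr_config = gpr_config or GprConfig()
    if set(model_control.reactions) != set(model_treated.reactions):
        raise ValueError("MADE requires the two condition models to share one network")
    desired, weights = made_transitions(model_treated, profile_treated, gpr_config, config.made_alpha)

    obj_c = model_control.objective_reaction_id
    obj_t = model_treated.objective_reaction_id
    if obj_c is None or obj_t is None:
        raise ValueError("MADE requires objective reactions on both condition models")
    rmf_c = config.made_rmf_fraction * fba(model_control, obj_c)[0]
    rmf_t = config.made_rmf_fraction * fba(model_treated, obj_t)[0]

    pb, names_c, names_t, match_vars = _build_made_problem(
        model_control, model_treated, desired, weights, config, obj_c, obj_t, rmf_c, rmf_t
    )
    for rid, m in match_vars.items():
        pb.set_objective(m, weights[rid])
    sol = pb.solve()
    best = sol.objective

    # parsimonious second stage at the optimal matching score
    pb2, names_c2, names_t2, match_vars2 = _build_made_problem(
        model_control, model_treated, desired, weights, config, obj_c, obj_t, rmf_c, rmf_t
    )
    t_c = _abs_flux_vars(pb2, names_c2, prefix="tc_")
    t_t = _abs_flux_vars(pb2, names_t2, prefix="tt_")
    pb2.sense = "min"
    for t in list(t_c.values()) + list(t_t.values()):
        pb2.set_objective(t, 1.0)
    if match_vars2:
        slack = config.optimality_tolerance * max(1.0, abs(best))
        pb2.add_constraint(
            {m: weights[rid] for rid, m in match_vars2.items()}, best - slack
        )
    sol2 = pb2.solve()
    flux_c = FluxDistribution({r: sol2[v] for r, v in names_c2.items()})
    flux_t = FluxDistribution({r: sol2[v] for r, v in names_t2.items()})
    state_c = classify_activity(flux_c, config)
    state_t = classify_activity(flux_t, config)
    state_c.input_labels = dict(desired)
    state_t.input_labels = dict(desired)
    state_c.condition = "control"
    state_t.condition = "treated"
    return MadeResult(
        control_activity=state_c,
        treated_activity=state_t,
        objective_value=best,
        desired=desired,
        weights=weights,
    )
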