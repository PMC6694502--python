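"""FBA/pFBA cores and the four integration methods."""

from __future__ import annotations

import numpy as np
import pytest

from sgprflux.fixtures import FixtureSpec, generate_toy_model
from sgprflux.gpr import ExpressionProfile, GprConfig, GprTree, parse_gpr
from sgprflux.integration import (
    ActivityState,
    FluxDistribution,
    IntegrationConfig,
    ReactionScoreSet,
    classify_activity,
    fba,
    gimme,
    goncalves,
    imat,
    made,
    pfba,
    ratio_profile,
    reaction_scores,
)
from sgprflux.model import MetabolicModel, Metabolite, Reaction, _to_cobra
from sgprflux.solver import InfeasibleProblemError

from conftest import make_chain
from oracles import imat_bruteforce_optimum


class TestFba:
    def test_bottleneck_sets_the_optimum(self):
        model = make_chain((10, 4, 10))
        opt, flux = fba(model)
        assert opt == pytest.approx(4.0)
        assert flux["R"] == pytest.approx(4.0)

    def test_all_zero_bounds_give_zero_optimum(self):
        model = make_chain((0, 0, 0))
        opt, _ = fba(model)
        assert opt == pytest.approx(0.0)

    def test_agrees_with_independent_cobra_formulation(self):
        """Branched seeded toy: our LP optimum equals cobra/GLPK's."""
        model = generate_toy_model(FixtureSpec(seed=42, n_branches=2))
        opt, _ = fba(model)
        cm = _to_cobra(model)
        assert opt == pytest.approx(cm.slim_optimize(), abs=1e-6)

    def test_missing_objective_is_an_error(self, chain_model):
        chain_model.objective_reaction_id = None
        with pytest.raises(ValueError):
            fba(chain_model)


class TestPfba:
    def test_futile_cycle_carries_no_flux(self, chain_model):
        m = chain_model.copy()
        m.metabolites["C"] = Metabolite("C", compartment="c")
        m.reactions["C1"] = Reaction("C1", {"X1": -1.0, "C": 1.0}, 0, 10)
        m.reactions["C2"] = Reaction("C2", {"C": -1.0, "X1": 1.0}, 0, 10)
        flux = pfba(m)
        assert abs(flux["C1"]) < 1e-6 and abs(flux["C2"]) < 1e-6
        assert flux["E"] == pytest.approx(10.0, rel=1e-6)

    def test_shorter_route_wins(self):
        """Two A->B routes of equal capacity: all flux takes the 1-step one."""
        m = MetabolicModel(id="routes", compartments={"c": "c"})
        for mid in ("A", "B", "X"):
            m.metabolites[mid] = Metabolite(mid, compartment="c")
        m.reactions["U"] = Reaction("U", {"A": 1.0}, 0, 10)
        m.reactions["direct"] = Reaction("direct", {"A": -1.0, "B": 1.0}, 0, 10)
        m.reactions["via1"] = Reaction("via1", {"A": -1.0, "X": 1.0}, 0, 10)
        m.reactions["via2"] = Reaction("via2", {"X": -1.0, "B": 1.0}, 0, 10)
        m.reactions["E"] = Reaction("E", {"B": -1.0}, 0, 10)
        m.objective_reaction_id = "E"
        flux = pfba(m)
        assert flux["direct"] == pytest.approx(10.0, rel=1e-6)
        assert abs(flux["via1"]) < 1e-6

    def test_total_flux_not_above_plain_fba(self, chain_model):
        _, plain = fba(chain_model)
        assert pfba(chain_model).total_absolute_flux() <= plain.total_absolute_flux() + 1e-6


class TestClassify:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, "inactive"), (-2.0, "active"), (1e-9, "inactive"), (1e-3, "active")],
    )
    def test_either_direction_counts(self, value, expected):
        state = classify_activity(FluxDistribution({"R": value}))
        assert state.states["R"] == expected


class TestGimme:
    def test_no_penalties_means_zero_inconsistency(self, chain_model):
        scores = ReactionScoreSet(scores={"R": 9.0}, provenance="GPR")
        cfg = IntegrationConfig(gimme_threshold_mode="absolute", gimme_threshold_value=5.0)
        res = gimme(chain_model, scores, cfg)
        assert res.inconsistency == pytest.approx(0.0, abs=1e-9)
        assert res.flux["E"] >= 0.9 * 10 - 1e-6

    def test_chain_inconsistency_hand_lp(self, chain_model):
        """Penalty (5-2) on the only route at RMF 0.9*10 gives 3*9 = 27."""
        scores = ReactionScoreSet(scores={"R": 2.0}, provenance="GPR")
        cfg = IntegrationConfig(gimme_threshold_mode="absolute", gimme_threshold_value=5.0)
        res = gimme(chain_model, scores, cfg)
        assert res.inconsistency == pytest.approx(27.0)
        assert res.flux["R"] == pytest.approx(9.0)
        assert res.activity.states["R"] == "active"

    def test_mean_plus_sd_of_constant_scores(self, chain_model):
        m = make_chain((10, 10, 10, 10, 10))  # three scored steps
        scores = ReactionScoreSet(scores={"R0": 2.0, "R1": 2.0, "R2": 2.0}, provenance="GPR")
        res = gimme(m, scores, IntegrationConfig())
        assert res.threshold == pytest.approx(2.0)
        assert res.inconsistency == pytest.approx(0.0, abs=1e-9)

    def test_rmf_infeasible_raises(self, chain_model):
        chain_model.reactions["U"].upper_bound = 0.0
        chain_model.reactions["R"].lower_bound = 1.0
        scores = ReactionScoreSet(scores={"R": 1.0}, provenance="GPR")
        with pytest.raises(InfeasibleProblemError):
            gimme(chain_model, scores, IntegrationConfig())


def imat_toy() -> MetabolicModel:
    """->A with a high and a low isozyme route A->B, then B->."""
    m = MetabolicModel(id="imat_toy", compartments={"c": "c"})
    for mid in ("A", "B"):
        m.metabolites[mid] = Metabolite(mid, compartment="c")
    m.reactions["U"] = Reaction("U", {"A": 1.0}, 0, 10)
    m.reactions["Rhigh"] = Reaction(
        "Rhigh", {"A": -1.0, "B": 1.0}, 0, 10, gpr=GprTree.gene("gh"), has_sgpr=True
    )
    m.reactions["Rlow"] = Reaction(
        "Rlow", {"A": -1.0, "B": 1.0}, 0, 10, gpr=GprTree.gene("gl"), has_sgpr=True
    )
    m.reactions["E"] = Reaction("E", {"B": -1.0}, 0, 10)
    m.objective_reaction_id = "E"
    m.validate()
    return m


class TestImat:
    def test_high_on_low_off_reaches_full_reward(self):
        model = imat_toy()
        scores = ReactionScoreSet(scores={"Rhigh": 10.0, "Rlow": 1.0}, provenance="GPR")
        res = imat(model, scores, IntegrationConfig())
        assert res.objective_value == 2
        assert res.activity.states["Rhigh"] == "active"
        assert res.activity.states["Rlow"] == "inactive"
        assert abs(res.flux["Rhigh"]) >= 1.0 - 1e-9

    def test_all_moderate_scores_give_zero_objective(self):
        model = imat_toy()
        scores = ReactionScoreSet(scores={"Rhigh": 5.0, "Rlow": 5.0}, provenance="GPR")
        res = imat(model, scores, IntegrationConfig())
        assert res.objective_value == 0
        assert set(res.labels.values()) == {"moderate"}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_on_seeded_toys(self, seed):
        """MILP optimum equals exhaustive enumeration + LP feasibility."""
        model = generate_toy_model(
            FixtureSpec(seed=seed, n_chains=2, chain_length=2, n_branches=0)
        )
        rng = np.random.default_rng(seed)
        scored = sorted(r for r in model.reactions if model.reactions[r].gpr is not None)
        scores = ReactionScoreSet(
            scores={r: float(rng.uniform(0, 10)) for r in scored}, provenance="GPR"
        )
        cfg = IntegrationConfig()
        res = imat(model, scores, cfg)
        assert res.objective_value == imat_bruteforce_optimum(model, scores, cfg)


class TestGoncalves:
    def test_unit_ratios_reproduce_control(self, chain_model):
        ratios = ReactionScoreSet(scores={"R": 1.0}, provenance="GPR")
        res = goncalves(chain_model, ratios)
        for rid in chain_model.reactions:
            assert res.treated_flux[rid] == pytest.approx(res.control_flux[rid], abs=1e-6)

    def test_downscaled_bottleneck_halves_the_chain(self):
        """Control flux 8 with ratio 0.5 pins the treated chain at 4.

        Oracle: over the interval [4, 8] allowed for the bottleneck, total
        absolute flux of the 3-reaction chain is 3*v, minimized at v = 4.
        """
        model = make_chain((10, 8, 10))
        ratios = ReactionScoreSet(scores={"R": 0.5}, provenance="GPR")
        res = goncalves(model, ratios)
        assert res.control_flux["R"] == pytest.approx(8.0, rel=1e-6)
        assert res.treated_flux["R"] == pytest.approx(4.0, rel=1e-6)
        assert res.treated_flux["E"] == pytest.approx(4.0, rel=1e-6)

    def test_upscaling_at_capacity_keeps_the_cap(self):
        model = make_chain((10, 8, 10))
        ratios = ReactionScoreSet(scores={"R": 2.0}, provenance="GPR")
        res = goncalves(model, ratios)
        assert res.treated_flux["R"] == pytest.approx(8.0, rel=1e-6)

    def test_zero_control_flux_stays_zero(self):
        """A reaction inactive in control is pinned inactive whatever the ratio."""
        m = imat_toy()
        # pFBA control picks one route; the other gets flux 0
        ratios = ReactionScoreSet(scores={"Rhigh": 3.0, "Rlow": 3.0}, provenance="GPR")
        res = goncalves(m, ratios)
        used = [r for r in ("Rhigh", "Rlow") if abs(res.control_flux[r]) > 1e-6]
        unused = [r for r in ("Rhigh", "Rlow") if r not in used]
        assert len(used) == 1
        assert abs(res.treated_flux[unused[0]]) < 1e-6


def made_toy() -> MetabolicModel:
    """Chain plus an optional gated branch with its own secretion."""
    m = make_chain((10, 10, 10))
    m.metabolites["P"] = Metabolite("P", compartment="c")
    m.reactions["Rg"] = Reaction(
        "Rg", {"X0": -1.0, "P": 1.0}, 0, 10, gpr=GprTree.gene("gup"), has_sgpr=True
    )
    m.reactions["EP"] = Reaction("EP", {"P": -1.0}, 0, 10)
    m.validate()
    return m


class TestMade:
    def test_identical_profiles_yield_identical_states(self):
        model = made_toy()
        profile = ExpressionProfile(
            values={"R": 1.0, "gup": 1.0},
            log_fc={"R": 0.0, "gup": 0.0, "gx": 0.0},
            p_value={"R": 1.0, "gup": 1.0, "gx": 1.0},
        )
        res = made(model, model.copy(), profile)
        assert res.control_activity.states == res.treated_activity.states
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_significant_up_transition_realized(self):
        """One up-regulated gene gating an optional branch: reward 1 - p."""
        model = made_toy()
        profile = ExpressionProfile(
            values={"gup": 4.0, "gx": 1.0},
            log_fc={"gup": 2.0, "gx": 0.0},
            p_value={"gup": 0.01, "gx": 1.0},
        )
        res = made(model, model.copy(), profile)
        assert res.desired == {"R": "same", "Rg": "up"}
        assert res.objective_value == pytest.approx(0.99 + (1 - 1.0) + 0.0)
        assert res.control_activity.states["Rg"] == "inactive"
        assert res.treated_activity.states["Rg"] == "active"

    def test_infeasible_down_transition_left_unmatched(self):
        """The RMF keeps the chain running, so 'down' on it cannot be realized."""
        model = made_toy()
        profile = ExpressionProfile(
            values={"gx": 1.0},
            log_fc={"gx": -3.0},
            p_value={"gx": 0.001},
        )
        res = made(model, model.copy(), profile)
        assert res.desired["R"] == "down"
        assert res.control_activity.states["R"] == "active"
        assert res.treated_activity.states["R"] == "active"
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_different_networks_rejected(self, chain_model):
        other = made_toy()
        profile = ExpressionProfile(values={}, log_fc={}, p_value={})
        with pytest.raises(ValueError, match="share"):
            made(chain_model, other, profile)


class TestScoreSets:
    def test_only_catalyzed_reactions_scored(self, chain_model):
        profile = ExpressionProfile(values={"gx": 2.0})
        scores = reaction_scores(chain_model, profile, GprConfig())
        assert set(scores.scores) == {"R"}

    def test_ratio_profile_drops_zero_control(self):
        control = ExpressionProfile(values={"a": 2.0, "b": 0.0})
        treated = ExpressionProfile(values={"a": 4.0, "b": 5.0})
        ratios = ratio_profile(control, treated)
        assert ratios.values == {"a": 2.0}


class TestDeterminism:
    @pytest.mark.parametrize("method", ["gimme", "imat"])
    def test_activity_state_reproducible(self, method):
        model = generate_toy_model(FixtureSpec(seed=5))
        rng = np.random.default_rng(5)
        scored = sorted(r for r in model.reactions if model.reactions[r].gpr is not None)
        scores = ReactionScoreSet(
            scores={r: float(rng.uniform(0, 10)) for r in scored}, provenance="GPR"
        )
        run = lambda: (
            gimme(model, scores, IntegrationConfig()).activity
            if method == "gimme"
            else imat(model, scores, IntegrationConfig()).activity
        )
        first, second = run(), run()
        assert first.states == second.states
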