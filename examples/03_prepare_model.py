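"""Model preprocessing: exchange augmentation, blocked-reaction pruning.

Measured metabolites need exchange reactions so predictions can be
compared with uptake/secretion data; blocked reactions (zero flux in
every steady state), one-way reversibles and dead-end metabolites are
then removed so downstream MILPs stay small.
"""

from sgprflux import add_exchange_reactions, prune_model
from sgprflux.fixtures import FixtureSpec, generate_toy_model
from sgprflux.model import Metabolite, Reaction

model = generate_toy_model(FixtureSpec(seed=7))
print(f"toy model: {len(model.reactions)} reactions, {len(model.metabolites)} metabolites")

# make the mid-chain metabolite measurable: uptake + secretion are added
model, n_added = add_exchange_reactions(model, ["M0_1"])
print(f"added {n_added} irreversible exchange reactions for M0_1")

# decorate with a dead-end side product and a feeder whose reverse is impossible
model.metabolites["DEAD"] = Metabolite("DEAD", compartment="c")
model.reactions["R_dead"] = Reaction("R_dead", {"M0_0": -1.0, "DEAD": 1.0}, 0, 10)
model.metabolites["W"] = Metabolite("W", compartment="c")
model.reactions["W_in"] = Reaction("W_in", {"W": 1.0}, -5, 5)
model.reactions["W_use"] = Reaction("W_use", {"W": -1.0, "M0_0": 1.0}, 0, 5)

pruned, report = prune_model(model)
print(f"pruned:    removed {report.removed_reactions},")
print(f"           tightened {report.tightened_reactions} to irreversible,")
print(f"           dropped metabolites {report.removed_metabolites}")
print("R_dead can never reach steady state (DEAD has no consumer), so it is removed;")
print("W_in's reverse direction would consume W that nothing produces, so it is one-way.")
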