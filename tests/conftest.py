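"""Shared builders for small hand-checkable metabolic networks."""

from __future__ import annotations

import pytest

from sgprflux.gpr import GprTree
from sgprflux.model import MetabolicModel, Metabolite, Reaction


def make_chain(
    caps: tuple[float, ...] = (10.0, 10.0, 10.0),
    gene: str = "gx",
) -> MetabolicModel:
    """Linear ->A->B-> chain: uptake, one catalyzed step per inner cap, secretion.

    ``caps`` are (uptake, step..., secretion) upper bounds; the secretion is
    the objective.  Inner steps carry single-gene rules gx, gx2, ...
    """
    model = MetabolicModel(id="chain", compartments={"c": "cytosol"})
    n_steps = len(caps) - 2
    mets = [f"X{i}" for i in range(n_steps + 1)]
    for mid in mets:
        model.metabolites[mid] = Metabolite(mid, compartment="c")
    model.reactions["U"] = Reaction("U", {mets[0]: 1.0}, 0, caps[0])
    for i in range(n_steps):
        rid = f"R{i}" if n_steps > 1 else "R"
        g = f"{gene}{i + 1}" if n_steps > 1 else gene
        model.reactions[rid] = Reaction(
            rid,
            {mets[i]: -1.0, mets[i + 1]: 1.0},
            0,
            caps[i + 1],
            gpr=GprTree.gene(g),
            has_sgpr=True,
        )
    model.reactions["E"] = Reaction("E", {mets[-1]: -1.0}, 0, caps[-1])
    model.objective_reaction_id = "E"
    model.validate()
    return model


@pytest.fixture
def chain_model() -> MetabolicModel:
    return make_chain()
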