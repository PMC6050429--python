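import numpy as np
import pytest

from gpersim import (
    Model,
    RateConstant,
    Reaction,
    Species,
)


def make_reaction(rid, reactants, products, kf, kr=None):
    """Reaction with correctly-ordered rate constants from plain dicts."""
    r_order = sum(reactants.values())
    p_order = sum(products.values())
    return Reaction(
        id=rid,
        reactants=reactants,
        products=products,
        kf=RateConstant(f"{rid}_kf", kf, order=r_order),
        kr=RateConstant(f"{rid}_kr", kr, order=p_order) if kr is not None else None,
        reversible=kr is not None,
    )


@pytest.fixture
def decay_model():
    """Irreversible S -> P, k = 0.5/s, S0 = 2 uM: closed-form exponential."""
    return Model(
        name="decay",
        species=[
            Species("S", initial_concentration=2.0),
            Species("P", initial_concentration=0.0),
        ],
        reactions=[make_reaction("r1", {"S": 1}, {"P": 1}, 0.5)],
    )


@pytest.fixture
def akt_model():
    """The reversible membrane-recruitment step Akt + PIP3 <-> Aktm."""
    return Model(
        name="akt_recruitment",
        species=[
            Species("Akt", initial_concentration=1.0),
            Species("PIP3", initial_concentration=1.0),
            Species("Aktm", initial_concentration=1.0),
        ],
        reactions=[make_reaction("r1", {"Akt": 1, "PIP3": 1}, {"Aktm": 1}, 1.0, 1.0)],
    )


@pytest.fixture
def cycle_model():
    """Closed three-state receptor cycle R -> Rp -> Rint -> R."""
    return Model(
        name="receptor_cycle",
        species=[
            Species("R", initial_concentration=1.0),
            Species("Rp"),
            Species("Rint"),
        ],
        reactions=[
            make_reaction("r1", {"R": 1}, {"Rp": 1}, 0.1),
            make_reaction("r2", {"Rp": 1}, {"Rint": 1}, 0.05),
            make_reaction("r3", {"Rint": 1}, {"R": 1}, 0.02),
        ],
    )
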