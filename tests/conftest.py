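from __future__ import annotations

from typing import Dict

import pytest

from stibnite import loads, unparse
from stibnite.examples import LISTINGS, LISTING_NAMES
from stibnite.model import Model


@pytest.fixture(scope="session")
def listings() -> Dict[str, str]:
    return dict(LISTINGS)


@pytest.fixture(scope="session")
def listing_names():
    return list(LISTING_NAMES)


@pytest.fixture(scope="session")
def models(listings) -> Dict[str, Model]:
    return {name: loads(text) for name, text in listings.items()}


def model_signature(m: Model):
    """Order-insensitive semantic summary, for model equality checks."""
    def e(x):
        from stibnite.syntax import unparse_expr
        return None if x is None else unparse_expr(x)

    def init(x):
        # an absent initial value means 0; SBML export materializes it
        return "0" if x is None else e(x)

    return {
        "name": m.name,
        "species": {s.id: (s.boundary, init(s.initial)) for s in
                    m.species.values()},
        "parameters": {p.id: (p.constant, init(p.initial)) for p in
                       m.parameters.values()},
        "reactions": {r.id: (tuple((pt.species, pt.stoichiometry)
                                   for pt in r.reactants),
                             tuple((pt.species, pt.stoichiometry)
                                   for pt in r.products),
                             e(r.kinetic_law), r.reversible)
                      for r in m.reactions.values()},
        "rules": sorted((ru.kind, ru.target or "", e(ru.formula),
                         ru.name or "") for ru in m.rules),
        "events": [(e(ev.trigger), tuple((t, e(x))
                                         for t, x in ev.assignments))
                   for ev in m.events],
        "stoich": sorted(m.stoich_symbols),
    }
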