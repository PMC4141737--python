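"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import string

import numpy as np
import pandas as pd
import pytest

from tcr_phosdyn.rule_model import (
    Bind,
    ComponentDef,
    ComponentPattern,
    FREE,
    ModelSpec,
    MoleculePattern,
    MoleculeTypeDef,
    Observable,
    Pattern,
    Rule,
    SeedSpecies,
    SetState,
    Unbind,
    parse_model,
)

MINIMAL_MODEL = """
begin parameters
  k1 5
end parameters
begin molecule types
  A(y~U~P)
end molecule types
begin seed species
  A(y~U) 10
end seed species
begin observables
  Molecules A_P A(y~P)
end observables
begin reaction rules
  flip: A(y~U) -> A(y~P) k1
end reaction rules
"""

BINDING_MODEL = """
begin parameters
  k_on 0.01
  k_off 0.1
end parameters
begin molecule types
  A(b)
  B(a)
end molecule types
begin seed species
  A(b) 30
  B(a) 40
end seed species
begin observables
  Molecules AB A(b!1).B(a!1)
end observables
begin reaction rules
  bind: A(b) + B(a) -> A(b!1).B(a!1) k_on
  unbind: A(b!1).B(a!1) -> A(b) + B(a) k_off
end reaction rules
"""

DECAY_MODEL = """
begin parameters
  k 0.1
end parameters
begin molecule types
  A(y~U~P)
end molecule types
begin seed species
  A(y~P) 1000
end seed species
begin observables
  Molecules A_P A(y~P)
end observables
begin reaction rules
  decay: A(y~P) -> A(y~U) k
end reaction rules
"""


@pytest.fixture
def minimal_spec():
    return parse_model(MINIMAL_MODEL)


@pytest.fixture
def binding_spec():
    return parse_model(BINDING_MODEL)


@pytest.fixture
def decay_spec():
    return parse_model(DECAY_MODEL)


def random_model_spec(rng: np.random.Generator) -> ModelSpec:
    """A random valid model: stateful/stateless components, seeds, state-flip
    and bind/unbind rules, observables.  Used for round-trip properties."""
    n_types = int(rng.integers(1, 4))
    types = []
    for i in range(n_types):
        comps = []
        n_comp = int(rng.integers(1, 4))
        for j in range(n_comp):
            if rng.random() < 0.5:
                comps.append(ComponentDef(name=f"c{j}", states=("U", "P")))
            else:
                comps.append(ComponentDef(name=f"c{j}"))
        loc = str(rng.choice(["E", "M", "C"]))
        types.append(MoleculeTypeDef(name=f"M{i}", components=tuple(comps), location=loc))

    params = {f"k{i}": float(np.round(10.0 ** rng.uniform(-3, 1), 6)) for i in range(4)}

    seeds = []
    for mt in types:
        comps = tuple(
            ComponentPattern(name=c.name, state=(str(rng.choice(c.states)) if c.states else None))
            for c in mt.components
        )
        seeds.append(
            SeedSpecies(
                molecule=MoleculePattern(type_name=mt.name, components=comps),
                count=int(rng.integers(0, 50)),
            )
        )

    rules = []
    ridx = 0
    for mt in types:
        stateful = [c for c in mt.components if c.states]
        if stateful and rng.random() < 0.8:
            comp = stateful[0]
            pat = Pattern((MoleculePattern(mt.name, (ComponentPattern(comp.name, state="U"),)),))
            rules.append(
                Rule(
                    name=f"r{ridx}",
                    reactants=(pat,),
                    transformation=SetState(0, 0, comp.name, "P"),
                    rate_param=str(rng.choice(sorted(params))),
                )
            )
            ridx += 1
    stateless_sites = [
        (mt, c) for mt in types for c in mt.components if not c.states
    ]
    if len(stateless_sites) >= 2:
        (mta, ca), (mtb, cb) = stateless_sites[0], stateless_sites[1]
        p1 = Pattern((MoleculePattern(mta.name, (ComponentPattern(ca.name, bond=FREE),)),))
        p2 = Pattern((MoleculePattern(mtb.name, (ComponentPattern(cb.name, bond=FREE),)),))
        rules.append(
            Rule(
                name=f"r{ridx}",
                reactants=(p1, p2),
                transformation=Bind((0, 0, ca.name), (1, 0, cb.name)),
                rate_param=str(rng.choice(sorted(params))),
            )
        )
        ridx += 1
        bound = Pattern((
            MoleculePattern(mta.name, (ComponentPattern(ca.name, bond=1),)),
            MoleculePattern(mtb.name, (ComponentPattern(cb.name, bond=1),)),
        ))
        rules.append(
            Rule(
                name=f"r{ridx}",
                reactants=(bound,),
                transformation=Unbind((0, 0, ca.name), (0, 1, cb.name)),
                rate_param=str(rng.choice(sorted(params))),
            )
        )

    observables = []
    for mt in types:
        stateful = [c for c in mt.components if c.states]
        if stateful:
            pat = Pattern((MoleculePattern(mt.name, (ComponentPattern(stateful[0].name, state="P", bond="wild"),)),))
            observables.append(Observable(name=f"{mt.name}_P", patterns=(pat,)))

    return ModelSpec(
        molecule_types=tuple(types),
        parameters=params,
        seed_species=tuple(seeds),
        rules=tuple(rules),
        observables=tuple(observables),
    )


def make_site_table(courses: dict[str, list[float]]) -> pd.DataFrame:
    """Site-level mean table from {protein: [mean_t5, mean_t15, mean_t30, mean_t60]}."""
    rows = []
    for protein, vals in courses.items():
        rec = {"protein": protein, "residues": "100"}
        for col, v in zip(("t5", "t15", "t30", "t60"), vals):
            rec[f"mean_{col}"] = v
            rec[f"sd_{col}"] = 0.0
            rec[f"n_{col}"] = 3
        rows.append(rec)
    return pd.DataFrame(rows)
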