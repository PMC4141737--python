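"""Data model for rule-based chemical kinetics and a reader/writer for a BNGL subset.

A model is a collection of molecule types (proteins with named components:
binding domains and phosphorylation sites), seed species with copy numbers,
named rate parameters, reaction rules (bind / unbind / state change under
elementary mass action), and observables (pattern counts).

The text dialect covers exactly the constructs needed for site-level
signaling models: ``parameters``, ``molecule types``, ``seed species``,
``observables`` and ``reaction rules`` blocks.  Compartments, functional
rate laws and synthesis/degradation arrows are rejected loudly rather than
silently skipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "ComponentDef",
    "MoleculeTypeDef",
    "BondSpec",
    "FREE",
    "BOUND_ANY",
    "WILD",
    "ComponentPattern",
    "MoleculePattern",
    "Pattern",
    "SetState",
    "Bind",
    "Unbind",
    "Rule",
    "Observable",
    "SeedSpecies",
    "ModelSpec",
    "ModelSyntaxError",
    "ModelValidationError",
    "parse_model",
    "write_model",
    "validate_model",
]

PTYR_STATES = ("U", "P")


class ModelSyntaxError(ValueError):
    """Raised for malformed model text; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class ModelValidationError(ValueError):
    """Raised when a structurally parseable model violates its invariants."""


# ---------------------------------------------------------------------------
# molecule types


@dataclass(frozen=True)
class ComponentDef:
    """A named component of a molecule type.

    ``states`` is empty for a pure binding domain; a phosphotyrosine site
    carries exactly ("U", "P").
    """

    name: str
    states: tuple[str, ...] = ()

    @property
    def kind(self) -> str:
        if not self.states:
            return "binding-domain"
        if tuple(self.states) == PTYR_STATES:
            return "pTyr-site"
        return "motif"


@dataclass(frozen=True)
class MoleculeTypeDef:
    name: str
    components: tuple[ComponentDef, ...] = ()
    location: str = "C"  # E (extracellular), M (membrane), C (cytosol); annotation only

    def __post_init__(self):
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ModelValidationError(
                f"duplicate component names in molecule type {self.name}"
            )
        if self.location not in ("E", "M", "C"):
            raise ModelValidationError(
                f"molecule type {self.name}: location must be E, M or C"
            )

    def component(self, name: str) -> ComponentDef:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"{self.name} has no component {name!r}")

    def component_index(self, name: str) -> int:
        for i, c in enumerate(self.components):
            if c.name == name:
                return i
        raise KeyError(f"{self.name} has no component {name!r}")


# ---------------------------------------------------------------------------
# patterns

# Bond constraints on a mentioned component:
#   FREE       component must be unbound              A(b)
#   BOUND_ANY  bound to an unspecified partner        A(b!+)
#   WILD       unconstrained (bound or not)           A(b!?)
#   int        bond label; appears exactly twice      A(b!1).B(a!1)
FREE = "free"
BOUND_ANY = "bound-any"
WILD = "wild"
BondSpec = Union[str, int]


@dataclass(frozen=True)
class ComponentPattern:
    name: str
    state: Optional[str] = None  # None = any state
    bond: BondSpec = FREE


@dataclass(frozen=True)
class MoleculePattern:
    type_name: str
    components: tuple[ComponentPattern, ...] = ()

    def component(self, name: str) -> ComponentPattern:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class Pattern:
    """A site-graph pattern: one or more molecule atoms joined by bond labels."""

    molecules: tuple[MoleculePattern, ...]

    def bond_edges(self) -> dict[int, list[tuple[int, str]]]:
        """Map bond label -> [(atom index, component name), ...]."""
        edges: dict[int, list[tuple[int, str]]] = {}
        for i, mol in enumerate(self.molecules):
            for comp in mol.components:
                if isinstance(comp.bond, int):
                    edges.setdefault(comp.bond, []).append((i, comp.name))
        return edges


# ---------------------------------------------------------------------------
# rules

@dataclass(frozen=True)
class SetState:
    """Flip the state of one component of one reactant atom (e.g. U -> P)."""

    reactant: int  # reactant pattern index
    atom: int  # atom index within that pattern
    component: str
    new_state: str


@dataclass(frozen=True)
class Bind:
    """Form a bond between a component of reactant 0/atom a and reactant 1/atom b
    (or two atoms of the same reactant for an intramolecular variant)."""

    first: tuple[int, int, str]  # (reactant, atom, component)
    second: tuple[int, int, str]


@dataclass(frozen=True)
class Unbind:
    """Break the labelled bond between two atoms of a single reactant pattern."""

    first: tuple[int, int, str]
    second: tuple[int, int, str]


Transformation = Union[SetState, Bind, Unbind]


@dataclass(frozen=True)
class Rule:
    name: str
    reactants: tuple[Pattern, ...]  # 1 (unimolecular) or 2 (bimolecular)
    transformation: Transformation
    rate_param: str  # symbol resolved in the parameter table

    @property
    def arity(self) -> int:
        return len(self.reactants)


@dataclass(frozen=True)
class Observable:
    name: str
    patterns: tuple[Pattern, ...]


@dataclass(frozen=True)
class SeedSpecies:
    """A fully specified, unbound molecule instance and its initial copy number."""

    molecule: MoleculePattern
    count: int

    def __post_init__(self):
        if self.count < 0:
            raise ModelValidationError(
                f"seed species {self.molecule.type_name}: negative copy number"
            )


@dataclass(frozen=True)
class ModelSpec:
    molecule_types: tuple[MoleculeTypeDef, ...] = ()
    parameters: Mapping[str, float] = field(default_factory=dict)
    seed_species: tuple[SeedSpecies, ...] = ()
    rules: tuple[Rule, ...] = ()
    observables: tuple[Observable, ...] = ()

    def molecule_type(self, name: str) -> MoleculeTypeDef:
        for mt in self.molecule_types:
            if mt.name == name:
                return mt
        raise KeyError(f"unknown molecule type {name!r}")

    def canonical(self) -> "ModelSpec":
        """Alphabetical ordering of every block (the on-disk ordering)."""
        return ModelSpec(
            molecule_types=tuple(sorted(self.molecule_types, key=lambda m: m.name)),
            parameters=dict(sorted(self.parameters.items())),
            seed_species=tuple(
                sorted(self.seed_species, key=lambda s: _species_key(s.molecule))
            ),
            rules=tuple(sorted(self.rules, key=lambda r: r.name)),
            observables=tuple(sorted(self.observables, key=lambda o: o.name)),
        )

    def with_seed_count(self, type_name: str, count: int) -> "ModelSpec":
        """Return a copy with every seed species of ``type_name`` set to ``count``."""
        found = False
        seeds = []
        for s in self.seed_species:
            if s.molecule.type_name == type_name:
                seeds.append(replace(s, count=count))
                found = True
            else:
                seeds.append(s)
        if not found:
            raise KeyError(f"no seed species of type {type_name!r}")
        return replace(self, seed_species=tuple(seeds))


def _species_key(mol: MoleculePattern) -> tuple:
    return (mol.type_name, tuple((c.name, c.state or "") for c in mol.components))


# ---------------------------------------------------------------------------
# parsing

_BLOCKS = ("parameters", "molecule types", "seed species", "observables", "reaction rules")

_MOL_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)\((.*)\)$")


def _strip_comment(line: str) -> tuple[str, str]:
    if "#" in line:
        code, _, comment = line.partition("#")
        return code.strip(), comment.strip()
    return line.strip(), ""


def _parse_component_token(tok: str, lineno: int) -> ComponentPattern:
    m = re.match(r"^([A-Za-z_][A-Za-z0-9_]*)((?:~[A-Za-z0-9]+)*)(!(?:\d+|\+|\?))?$", tok)
    if not m:
        raise ModelSyntaxError(f"bad component token {tok!r}", lineno)
    name, states_part, bond_part = m.group(1), m.group(2), m.group(3)
    states = tuple(s for s in states_part.split("~") if s)
    if len(states) > 1:
        raise ModelSyntaxError(
            f"component {tok!r}: patterns carry at most one state", lineno
        )
    state = states[0] if states else None
    if bond_part is None:
        bond: BondSpec = FREE
    elif bond_part == "!+":
        bond = BOUND_ANY
    elif bond_part == "!?":
        bond = WILD
    else:
        bond = int(bond_part[1:])
    return ComponentPattern(name=name, state=state, bond=bond)


def _parse_molecule_pattern(text: str, lineno: int) -> MoleculePattern:
    m = _MOL_RE.match(text.strip())
    if not m:
        raise ModelSyntaxError(f"bad molecule pattern {text!r}", lineno)
    name, inner = m.group(1), m.group(2).strip()
    comps: list[ComponentPattern] = []
    if inner:
        for tok in _split_top(inner, ","):
            comps.append(_parse_component_token(tok.strip(), lineno))
    return MoleculePattern(type_name=name, components=tuple(comps))


def _split_top(text: str, sep: str) -> list[str]:
    # no nesting in this dialect; plain split is safe
    return [t for t in text.split(sep) if t.strip()]


def _split_summands(text: str) -> list[str]:
    # '+' separates reactants only when whitespace-surrounded ('!+' is a bond)
    return [t for t in re.split(r"\s+\+\s+", text.strip()) if t]


def parse_pattern(text: str, lineno: int = 0) -> Pattern:
    """Parse a (possibly multi-molecule, dot-joined) site-graph pattern."""
    mols = tuple(_parse_molecule_pattern(t, lineno) for t in text.strip().split("."))
    pat = Pattern(molecules=mols)
    for label, ends in pat.bond_edges().items():
        if len(ends) != 2:
            raise ModelSyntaxError(
                f"bond label !{label} appears {len(ends)} time(s); must appear exactly twice",
                lineno,
            )
    return pat


def _parse_molecule_type(text: str, lineno: int, location: str) -> MoleculeTypeDef:
    m = _MOL_RE.match(text.strip())
    if not m:
        raise ModelSyntaxError(f"bad molecule type {text!r}", lineno)
    name, inner = m.group(1), m.group(2).strip()
    comps: list[ComponentDef] = []
    if inner:
        for tok in _split_top(inner, ","):
            tok = tok.strip()
            cm = re.match(r"^([A-Za-z_][A-Za-z0-9_]*)((?:~[A-Za-z0-9]+)*)$", tok)
            if not cm:
                raise ModelSyntaxError(f"bad component declaration {tok!r}", lineno)
            states = tuple(s for s in cm.group(2).split("~") if s)
            comps.append(ComponentDef(name=cm.group(1), states=states))
    return MoleculeTypeDef(name=name, components=tuple(comps), location=location)


def _flatten(side: list[Pattern]) -> list[tuple[int, int, MoleculePattern]]:
    out = []
    for pi, pat in enumerate(side):
        for ai, mol in enumerate(pat.molecules):
            out.append((pi, ai, mol))
    return out


def _bond_pairs(side: list[Pattern]) -> set[frozenset]:
    """Set of bonds, each as frozenset of (flat position, component name)."""
    pairs = set()
    flat_index = {}
    pos = 0
    for pi, pat in enumerate(side):
        for ai in range(len(pat.molecules)):
            flat_index[(pi, ai)] = pos
            pos += 1
        for label, ends in pat.bond_edges().items():
            (a_atom, a_comp), (b_atom, b_comp) = ends
            pairs.add(
                frozenset({(flat_index[(pi, a_atom)], a_comp), (flat_index[(pi, b_atom)], b_comp)})
            )
    return pairs


def _diff_rule(
    name: str,
    reactants: list[Pattern],
    products: list[Pattern],
    rate: str,
    lineno: int,
) -> Rule:
    """Infer the single transformation by positional diff of the two sides.

    Product molecules must appear in the same order as reactant molecules
    (the dialect's convention); exactly one elementary change is allowed.
    """
    rflat = _flatten(reactants)
    pflat = _flatten(products)
    if len(rflat) != len(pflat):
        raise ModelSyntaxError(
            f"rule {name}: molecule created or destroyed (not supported)", lineno
        )
    for (rpi, rai, rmol), (_, _, pmol) in zip(rflat, pflat):
        if rmol.type_name != pmol.type_name:
            raise ModelSyntaxError(
                f"rule {name}: reactant/product molecules must align positionally", lineno
            )

    state_changes = []
    for k, ((rpi, rai, rmol), (_, _, pmol)) in enumerate(zip(rflat, pflat)):
        rstates = {c.name: c.state for c in rmol.components}
        pstates = {c.name: c.state for c in pmol.components}
        if set(rstates) != set(pstates):
            raise ModelSyntaxError(
                f"rule {name}: components mentioned must match across the arrow", lineno
            )
        for cname in rstates:
            if rstates[cname] != pstates[cname]:
                if rstates[cname] is None or pstates[cname] is None:
                    raise ModelSyntaxError(
                        f"rule {name}: state change requires explicit states on both sides",
                        lineno,
                    )
                state_changes.append((rpi, rai, cname, pstates[cname]))

    rbonds = _bond_pairs(reactants)
    pbonds = _bond_pairs(products)
    added = pbonds - rbonds
    removed = rbonds - pbonds

    n_changes = len(state_changes) + len(added) + len(removed)
    if n_changes != 1:
        raise ModelSyntaxError(
            f"rule {name}: exactly one elementary change required, found {n_changes}",
            lineno,
        )

    def flat_to_rxn(flat_pos: int) -> tuple[int, int]:
        return rflat[flat_pos][0], rflat[flat_pos][1]

    if state_changes:
        rpi, rai, cname, new_state = state_changes[0]
        tf: Transformation = SetState(reactant=rpi, atom=rai, component=cname, new_state=new_state)
    elif added:
        (a_pos, a_comp), (b_pos, b_comp) = sorted(next(iter(added)))
        pa, aa = flat_to_rxn(a_pos)
        pb, ab = flat_to_rxn(b_pos)
        tf = Bind(first=(pa, aa, a_comp), second=(pb, ab, b_comp))
        # the bound components must be declared free on the reactant side
        for (pp, aatom, comp) in (tf.first, tf.second):
            cp = reactants[pp].molecules[aatom].component(comp)
            if cp.bond != FREE:
                raise ModelSyntaxError(
                    f"rule {name}: binding component {comp!r} must be free in reactants",
                    lineno,
                )
    else:
        (a_pos, a_comp), (b_pos, b_comp) = sorted(next(iter(removed)))
        pa, aa = flat_to_rxn(a_pos)
        pb, ab = flat_to_rxn(b_pos)
        if pa != pb:
            raise ModelSyntaxError(
                f"rule {name}: unbinding atoms must share one reactant pattern", lineno
            )
        tf = Unbind(first=(pa, aa, a_comp), second=(pb, ab, b_comp))

    if len(reactants) not in (1, 2):
        raise ModelSyntaxError(f"rule {name}: 1 or 2 reactant patterns required", lineno)
    return Rule(name=name, reactants=tuple(reactants), transformation=tf, rate_param=rate)


_RULE_RE = re.compile(r"^(?:([A-Za-z_][A-Za-z0-9_]*)\s*:)?\s*(.+?)\s*->\s*(.+)$")


def parse_model(text: str) -> ModelSpec:
    """Parse BNGL-subset model text into a validated :class:`ModelSpec`.

    Raises :class:`ModelSyntaxError` (with line number) on malformed input and
    :class:`ModelValidationError` if cross-references do not resolve.  Unknown
    block names and unsupported constructs raise; nothing is silently skipped.
    """
    params: dict[str, float] = {}
    mol_types: list[MoleculeTypeDef] = []
    seeds: list[SeedSpecies] = []
    observables: list[Observable] = []
    rules: list[Rule] = []
    auto_rule_idx = 0

    block: Optional[str] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        code, comment = _strip_comment(raw)
        if not code:
            continue
        low = code.lower()
        if low.startswith("begin "):
            if block is not None:
                raise ModelSyntaxError(f"nested block {code!r}", lineno)
            name = low[len("begin "):].strip()
            if name not in _BLOCKS:
                raise ModelSyntaxError(f"unknown block {name!r}", lineno)
            block = name
            continue
        if low.startswith("end"):
            ended = low[len("end"):].strip()
            if block is None or (ended and ended != block):
                raise ModelSyntaxError(f"stray {code!r}", lineno)
            block = None
            continue
        if block is None:
            raise ModelSyntaxError(f"statement outside any block: {code!r}", lineno)

        if block == "parameters":
            parts = code.split()
            if len(parts) != 2:
                raise ModelSyntaxError(f"bad parameter line {code!r}", lineno)
            try:
                value = float(parts[1])
            except ValueError:
                raise ModelSyntaxError(f"bad parameter value {parts[1]!r}", lineno)
            if parts[0] in params:
                raise ModelSyntaxError(f"duplicate parameter {parts[0]!r}", lineno)
            params[parts[0]] = value

        elif block == "molecule types":
            loc = "C"
            m = re.search(r"loc\s*=\s*([EMC])", comment)
            if m:
                loc = m.group(1)
            mol_types.append(_parse_molecule_type(code, lineno, loc))

        elif block == "seed species":
            parts = code.rsplit(None, 1)
            if len(parts) != 2:
                raise ModelSyntaxError(f"bad seed species line {code!r}", lineno)
            mol = _parse_molecule_pattern(parts[0], lineno)
            for cp in mol.components:
                if isinstance(cp.bond, int) or cp.bond in (BOUND_ANY, WILD):
                    raise ModelSyntaxError(
                        "seed species must be unbound single molecules", lineno
                    )
            try:
                count = int(parts[1])
            except ValueError:
                raise ModelSyntaxError(f"bad copy number {parts[1]!r}", lineno)
            if count < 0:
                raise ModelSyntaxError("negative copy number", lineno)
            seeds.append(SeedSpecies(molecule=mol, count=count))

        elif block == "observables":
            parts = code.split()
            if len(parts) < 3 or parts[0] != "Molecules":
                raise ModelSyntaxError(
                    f"observable must read 'Molecules <name> <pattern>...': {code!r}",
                    lineno,
                )
            pats = tuple(parse_pattern(p, lineno) for p in parts[2:])
            observables.append(Observable(name=parts[1], patterns=pats))

        elif block == "reaction rules":
            if "<->" in code:
                raise ModelSyntaxError("reversible arrows not supported; write two rules", lineno)
            m = _RULE_RE.match(code)
            if not m:
                raise ModelSyntaxError(f"bad rule line {code!r}", lineno)
            name = m.group(1)
            if name is None:
                auto_rule_idx += 1
                name = f"rule_{auto_rule_idx}"
            rhs = m.group(3).rsplit(None, 1)
            if len(rhs) != 2:
                raise ModelSyntaxError(f"rule {name}: missing rate constant", lineno)
            products_text, rate = rhs
            reactants = [parse_pattern(t, lineno) for t in _split_summands(m.group(2))]
            products = [parse_pattern(t, lineno) for t in _split_summands(products_text)]
            rules.append(_diff_rule(name, reactants, products, rate, lineno))

    if block is not None:
        raise ModelSyntaxError(f"unterminated block {block!r}", len(text.splitlines()))

    spec = ModelSpec(
        molecule_types=tuple(mol_types),
        parameters=params,
        seed_species=tuple(seeds),
        rules=tuple(rules),
        observables=tuple(observables),
    )
    report = validate_model(spec)
    if report:
        raise ModelValidationError("; ".join(report))
    return spec


# ---------------------------------------------------------------------------
# writing


def _format_component_pattern(cp: ComponentPattern) -> str:
    s = cp.name
    if cp.state is not None:
        s += f"~{cp.state}"
    if cp.bond == BOUND_ANY:
        s += "!+"
    elif cp.bond == WILD:
        s += "!?"
    elif isinstance(cp.bond, int):
        s += f"!{cp.bond}"
    return s


def format_pattern(pat: Pattern) -> str:
    return ".".join(
        f"{mol.type_name}({','.join(_format_component_pattern(c) for c in mol.components)})"
        for mol in pat.molecules
    )


def _products_of(rule: Rule) -> list[Pattern]:
    """Reconstruct the product side from reactants + transformation."""
    tf = rule.transformation
    reactants = [
        Pattern(tuple(MoleculePattern(m.type_name, tuple(m.components)) for m in p.molecules))
        for p in rule.reactants
    ]

    def set_comp(pat_i, atom_i, comp_name, **kw):
        mols = list(reactants[pat_i].molecules)
        comps = list(mols[atom_i].components)
        for ci, c in enumerate(comps):
            if c.name == comp_name:
                comps[ci] = replace(c, **kw)
        mols[atom_i] = replace(mols[atom_i], components=tuple(comps))
        reactants[pat_i] = Pattern(tuple(mols))

    if isinstance(tf, SetState):
        set_comp(tf.reactant, tf.atom, tf.component, state=tf.new_state)
        return reactants
    if isinstance(tf, Bind):
        label = max(
            [0]
            + [
                c.bond
                for p in reactants
                for m in p.molecules
                for c in m.components
                if isinstance(c.bond, int)
            ]
        ) + 1
        (pa, aa, ca), (pb, ab, cb) = tf.first, tf.second
        set_comp(pa, aa, ca, bond=label)
        if pa == pb:
            set_comp(pa, ab, cb, bond=label)
            return reactants
        # merge the two reactant patterns into one product complex
        merged = Pattern(reactants[pa].molecules + reactants[pb].molecules)
        mols = list(merged.molecules)
        atom_off = len(reactants[pa].molecules)
        comps = list(mols[atom_off + ab].components)
        for ci, c in enumerate(comps):
            if c.name == cb:
                comps[ci] = replace(c, bond=label)
        mols[atom_off + ab] = replace(mols[atom_off + ab], components=tuple(comps))
        return [Pattern(tuple(mols))]
    if isinstance(tf, Unbind):
        (pa, aa, ca), (_, ab, cb) = tf.first, tf.second
        set_comp(pa, aa, ca, bond=FREE)
        set_comp(pa, ab, cb, bond=FREE)
        # split the complex into its connected components
        pat = reactants[pa]
        comps_graph: dict[int, set[int]] = {i: set() for i in range(len(pat.molecules))}
        for _, ends in pat.bond_edges().items():
            (i, _), (j, _) = ends
            comps_graph[i].add(j)
            comps_graph[j].add(i)
        seen: set[int] = set()
        out: list[Pattern] = []
        for i in range(len(pat.molecules)):
            if i in seen:
                continue
            stack, group = [i], []
            while stack:
                k = stack.pop()
                if k in seen:
                    continue
                seen.add(k)
                group.append(k)
                stack.extend(comps_graph[k])
            out.append(Pattern(tuple(pat.molecules[k] for k in sorted(group))))
        others = [p for pi, p in enumerate(reactants) if pi != pa]
        return out + others
    raise TypeError(f"unknown transformation {tf!r}")


def write_model(spec: ModelSpec) -> str:
    """Emit canonical model text; ``parse_model(write_model(s)) == s.canonical()``."""
    spec = spec.canonical()
    lines: list[str] = []

    lines.append("begin parameters")
    for name, value in spec.parameters.items():
        lines.append(f"  {name} {value:.12g}")
    lines.append("end parameters")

    lines.append("begin molecule types")
    for mt in spec.molecule_types:
        comps = ",".join(c.name + "".join(f"~{s}" for s in c.states) for c in mt.components)
        loc = f"  # loc={mt.location}" if mt.location != "C" else ""
        lines.append(f"  {mt.name}({comps}){loc}")
    lines.append("end molecule types")

    lines.append("begin seed species")
    for s in spec.seed_species:
        mol = format_pattern(Pattern((s.molecule,)))
        lines.append(f"  {mol} {s.count}")
    lines.append("end seed species")

    lines.append("begin observables")
    for ob in spec.observables:
        pats = " ".join(format_pattern(p) for p in ob.patterns)
        lines.append(f"  Molecules {ob.name} {pats}")
    lines.append("end observables")

    lines.append("begin reaction rules")
    for rule in spec.rules:
        lhs = " + ".join(format_pattern(p) for p in rule.reactants)
        rhs = " + ".join(format_pattern(p) for p in _products_of(rule))
        lines.append(f"  {rule.name}: {lhs} -> {rhs} {rule.rate_param}")
    lines.append("end reaction rules")

    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# validation


def _check_pattern(spec: ModelSpec, pat: Pattern, where: str, report: list[str]) -> None:
    for mol in pat.molecules:
        try:
            mt = spec.molecule_type(mol.type_name)
        except KeyError:
            report.append(f"{where}: unknown molecule type {mol.type_name!r}")
            continue
        seen = set()
        for cp in mol.components:
            if cp.name in seen:
                report.append(f"{where}: component {cp.name!r} mentioned twice")
            seen.add(cp.name)
            try:
                cd = mt.component(cp.name)
            except KeyError:
                report.append(
                    f"{where}: {mol.type_name} has no component {cp.name!r}"
                )
                continue
            if cp.state is not None and cp.state not in cd.states:
                report.append(
                    f"{where}: state {cp.state!r} not in alphabet of "
                    f"{mol.type_name}.{cp.name}"
                )
    for label, ends in pat.bond_edges().items():
        if len(ends) != 2:
            report.append(f"{where}: bond !{label} does not appear exactly twice")
    if len(pat.molecules) > 1:
        # multi-molecule patterns must be connected through their bond labels
        adj: dict[int, set[int]] = {i: set() for i in range(len(pat.molecules))}
        for _, ends in pat.bond_edges().items():
            if len(ends) == 2:
                (i, _), (j, _) = ends
                adj[i].add(j)
                adj[j].add(i)
        seen2, stack = set(), [0]
        while stack:
            k = stack.pop()
            if k in seen2:
                continue
            seen2.add(k)
            stack.extend(adj[k])
        if len(seen2) != len(pat.molecules):
            report.append(f"{where}: multi-molecule pattern is not connected")


def validate_model(spec: ModelSpec) -> list[str]:
    """Return a list of violations; the empty list iff the model is valid."""
    report: list[str] = []

    names = [mt.name for mt in spec.molecule_types]
    for n in set(names):
        if names.count(n) > 1:
            report.append(f"duplicate molecule type {n!r}")

    for p, v in spec.parameters.items():
        if v < 0:
            report.append(f"parameter {p!r} is negative")

    for s in spec.seed_species:
        where = f"seed species {s.molecule.type_name}"
        try:
            mt = spec.molecule_type(s.molecule.type_name)
        except KeyError:
            report.append(f"{where}: unknown molecule type")
            continue
        mentioned = {c.name for c in s.molecule.components}
        for cd in mt.components:
            if cd.states and cd.name not in mentioned:
                report.append(f"{where}: stateful component {cd.name!r} needs an explicit state")
        for cp in s.molecule.components:
            try:
                cd = mt.component(cp.name)
            except KeyError:
                report.append(f"{where}: no component {cp.name!r}")
                continue
            if cd.states and cp.state not in cd.states:
                report.append(f"{where}: bad state for {cp.name!r}")

    rule_names = [r.name for r in spec.rules]
    for n in set(rule_names):
        if rule_names.count(n) > 1:
            report.append(f"duplicate rule name {n!r}")

    for rule in spec.rules:
        where = f"rule {rule.name}"
        for pat in rule.reactants:
            _check_pattern(spec, pat, where, report)
        if rule.rate_param not in spec.parameters:
            try:
                float(rule.rate_param)
            except ValueError:
                report.append(f"{where}: undeclared rate parameter {rule.rate_param!r}")
        tf = rule.transformation
        refs = []
        if isinstance(tf, SetState):
            refs = [(tf.reactant, tf.atom, tf.component)]
        elif isinstance(tf, (Bind, Unbind)):
            refs = [tf.first, tf.second]
        for (pi, ai, comp) in refs:
            if pi >= len(rule.reactants) or ai >= len(rule.reactants[pi].molecules):
                report.append(f"{where}: transformation references missing atom")
                continue
            mol = rule.reactants[pi].molecules[ai]
            if all(c.name != comp for c in mol.components):
                report.append(
                    f"{where}: transformation references unmentioned component {comp!r}"
                )
        if isinstance(tf, SetState):
            try:
                mt = spec.molecule_type(rule.reactants[tf.reactant].molecules[tf.atom].type_name)
                cd = mt.component(tf.component)
                if tf.new_state not in cd.states:
                    report.append(f"{where}: target state {tf.new_state!r} not in alphabet")
            except (KeyError, IndexError):
                pass

    ob_names = [o.name for o in spec.observables]
    for n in set(ob_names):
        if ob_names.count(n) > 1:
            report.append(f"duplicate observable {n!r}")
    for ob in spec.observables:
        for pat in ob.patterns:
            _check_pattern(spec, pat, f"observable {ob.name}", report)

    return report
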