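"""Network-free particle-based stochastic simulator.

Tracks every molecule instance (its component states and bonds) and fires
reaction rules by the Gillespie direct method: waiting times are exponential
in the total propensity and the next rule is chosen proportionally to its
propensity.  Rule propensities come from counting embeddings of reactant
site-graph patterns into the mixture site-graph; no reaction network is ever
enumerated.

Conventions (the mass-action ones):
  * a pattern's match count is its embedding count divided by the order of
    its automorphism group, so a symmetric dimer pattern counts each dimer
    once;
  * a bimolecular rule whose two reactant patterns are identical has
    propensity k * M * (M - 1) over the M matches (ordered pairs of distinct
    matches);
  * distinct single-molecule reactant patterns that can overlap on the same
    molecule have the shared molecules subtracted from the pair count; for
    multi-molecule patterns the rare self-pair is rejected at firing time
    (a null event that only advances the clock).

Time is in seconds throughout; bimolecular rate constants are events per
second per reactant pair (copy-number units — the model lives in a single
well-mixed volume).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .rule_model import (
    BOUND_ANY,
    FREE,
    WILD,
    Bind,
    ModelSpec,
    MoleculePattern,
    Pattern,
    Rule,
    SetState,
    SeedSpecies,
    Unbind,
)

__all__ = [
    "Mixture",
    "SimProtocol",
    "Trajectory",
    "QuiescentMixture",
    "count_embeddings",
    "rule_propensity",
    "match_count",
    "step",
    "RuleEngine",
    "simulate",
    "simulate_runs",
    "equilibrate",
    "advance",
    "average_runs",
    "read_protocol",
    "write_protocol",
]


class QuiescentMixture(Exception):
    """Signals zero total propensity; callers advance to the next observation."""


# ---------------------------------------------------------------------------
# mixture


class Molecule:
    __slots__ = ("id", "type_name", "states", "bonds")

    def __init__(self, mid: int, type_name: str, states: list, bonds: list):
        self.id = mid
        self.type_name = type_name
        self.states = states  # per component index: state string or None
        self.bonds = bonds  # per component index: (partner Molecule, comp idx) or None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Molecule {self.id} {self.type_name}>"


class Mixture:
    """The particle state: molecule instances with states and symmetric bonds."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.t = 0.0
        self.molecules: list[Molecule] = []
        self.by_type: dict[str, list[Molecule]] = {}
        self._comp_index: dict[str, dict[str, int]] = {
            mt.name: {c.name: i for i, c in enumerate(mt.components)}
            for mt in spec.molecule_types
        }

    # -- construction -------------------------------------------------------

    def add_molecule(self, mol_pattern: MoleculePattern) -> Molecule:
        mt = self.spec.molecule_type(mol_pattern.type_name)
        states: list = []
        for cd in mt.components:
            states.append(cd.states[0] if cd.states else None)
        for cp in mol_pattern.components:
            ci = self._comp_index[mt.name][cp.name]
            if cp.state is not None:
                states[ci] = cp.state
        m = Molecule(len(self.molecules), mt.name, states, [None] * len(mt.components))
        self.molecules.append(m)
        self.by_type.setdefault(mt.name, []).append(m)
        return m

    @classmethod
    def from_seed_species(cls, spec: ModelSpec) -> "Mixture":
        mix = cls(spec)
        for seed in spec.seed_species:
            for _ in range(seed.count):
                mix.add_molecule(seed.molecule)
        return mix

    def inject(self, type_name: str, count: int) -> list[Molecule]:
        """Add ``count`` fresh molecules of a type in its default (first) states."""
        if type_name not in self._comp_index:
            raise KeyError(f"unknown molecule type {type_name!r}")
        return [self.add_molecule(MoleculePattern(type_name)) for _ in range(count)]

    # -- invariants ---------------------------------------------------------

    def check_invariants(self) -> None:
        for m in self.molecules:
            mt = self.spec.molecule_type(m.type_name)
            for ci, cd in enumerate(mt.components):
                if cd.states and m.states[ci] not in cd.states:
                    raise AssertionError(f"{m}: bad state at {cd.name}")
                b = m.bonds[ci]
                if b is not None:
                    partner, pci = b
                    back = partner.bonds[pci]
                    if back is None or back[0] is not m or back[1] != ci:
                        raise AssertionError(f"{m}: asymmetric bond at {cd.name}")

    def counts_by_type(self) -> dict[str, int]:
        return {t: len(ms) for t, ms in self.by_type.items()}


# ---------------------------------------------------------------------------
# pattern compilation and embedding


@dataclass
class _CompiledAtom:
    type_name: str
    # (comp index, state or None, bond spec) -- bond spec FREE/BOUND_ANY/WILD/int
    constraints: tuple


@dataclass
class _CompiledPattern:
    atoms: list[_CompiledAtom]
    # edges: (atom_a, comp_idx_a, atom_b, comp_idx_b) per labelled bond
    edges: list[tuple[int, int, int, int]]
    automorphisms: int
    source: Pattern

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def compile_pattern(spec: ModelSpec, pattern: Pattern) -> _CompiledPattern:
    comp_index = {
        mt.name: {c.name: i for i, c in enumerate(mt.components)}
        for mt in spec.molecule_types
    }
    atoms: list[_CompiledAtom] = []
    for mol in pattern.molecules:
        if mol.type_name not in comp_index:
            raise KeyError(f"pattern references unknown type {mol.type_name!r}")
        cons = []
        for cp in mol.components:
            ci = comp_index[mol.type_name][cp.name]
            cons.append((ci, cp.state, cp.bond))
        atoms.append(_CompiledAtom(mol.type_name, tuple(cons)))
    edges = []
    for label, ends in pattern.bond_edges().items():
        (ia, ca), (ib, cb) = ends
        edges.append(
            (ia, comp_index[pattern.molecules[ia].type_name][ca],
             ib, comp_index[pattern.molecules[ib].type_name][cb])
        )
    cp = _CompiledPattern(atoms=atoms, edges=edges, automorphisms=1, source=pattern)
    cp.automorphisms = _automorphism_order(cp)
    return cp


def _automorphism_order(cp: _CompiledPattern) -> int:
    """Order of the pattern's symmetry group (brute force; patterns are tiny)."""
    n = cp.n_atoms
    if n == 1:
        return 1
    edge_set = {frozenset({(a, ca), (b, cb)}) for (a, ca, b, cb) in cp.edges}
    count = 0
    for perm in itertools.permutations(range(n)):
        if any(cp.atoms[i].type_name != cp.atoms[perm[i]].type_name for i in range(n)):
            continue
        if any(cp.atoms[i].constraints != cp.atoms[perm[i]].constraints for i in range(n)):
            continue
        permuted = {
            frozenset({(perm[a], ca), (perm[b], cb)}) for (a, ca, b, cb) in cp.edges
        }
        if permuted == edge_set:
            count += 1
    return max(count, 1)


def _atom_matches_local(atom: _CompiledAtom, mol: Molecule) -> bool:
    if mol.type_name != atom.type_name:
        return False
    for ci, state, bond in atom.constraints:
        if state is not None and mol.states[ci] != state:
            return False
        b = mol.bonds[ci]
        if bond == FREE:
            if b is not None:
                return False
        elif bond == BOUND_ANY:
            if b is None:
                return False
        elif bond == WILD:
            pass
        else:  # labelled; checked by edge walk, but must be bound
            if b is None:
                return False
    return True


def _embed_at(cp: _CompiledPattern, anchor: Molecule) -> Optional[list[Molecule]]:
    """Extend atom0 -> anchor along the pattern's labelled bonds.

    Every atom is connected to atom0 through labelled bonds, and each labelled
    bond in the mixture determines a unique partner, so the assignment is
    forced: the embedding either exists (returned as atom -> molecule list)
    or it does not (None).
    """
    n = cp.n_atoms
    if not _atom_matches_local(cp.atoms[0], anchor):
        return None
    assign: list[Optional[Molecule]] = [None] * n
    assign[0] = anchor
    # walk edges until all atoms assigned; edges list is tiny
    pending = list(cp.edges)
    while pending:
        progress = False
        rest = []
        for (a, ca, b, cb) in pending:
            ma, mb = assign[a], assign[b]
            if ma is None and mb is None:
                rest.append((a, ca, b, cb))
                continue
            progress = True
            if ma is not None:
                bond = ma.bonds[ca]
                if bond is None or bond[1] != cb:
                    return None
                target = bond[0]
                if mb is None:
                    if not _atom_matches_local(cp.atoms[b], target):
                        return None
                    if any(target is x for x in assign if x is not None):
                        return None  # injective mapping
                    assign[b] = target
                elif mb is not target:
                    return None
            else:
                bond = mb.bonds[cb]
                if bond is None or bond[1] != ca:
                    return None
                target = bond[0]
                if not _atom_matches_local(cp.atoms[a], target):
                    return None
                if any(target is x for x in assign if x is not None):
                    return None
                assign[a] = target
        if rest and not progress:  # disconnected pattern (validated against earlier)
            raise ValueError("pattern atoms are not connected by bond labels")
        pending = rest
    return assign  # type: ignore[return-value]


def count_embeddings(
    mixture: Mixture, pattern: Pattern, symmetry_corrected: bool = True
) -> int:
    """Number of embeddings of ``pattern`` into the mixture site-graph.

    With ``symmetry_corrected=True`` (default) the raw embedding count is
    divided by the order of the pattern's automorphism group, which is the
    mass-action match count (a symmetric homodimer pattern counts each dimer
    once).
    """
    cp = compile_pattern(mixture.spec, pattern)
    raw = 0
    for mol in mixture.by_type.get(cp.atoms[0].type_name, ()):  # anchors
        if _embed_at(cp, mol) is not None:
            raw += 1
    return raw // cp.automorphisms if symmetry_corrected else raw


def match_count(mixture: Mixture, pattern: Pattern) -> float:
    """Symmetry-corrected match count (embeddings / automorphism order)."""
    return count_embeddings(mixture, pattern, symmetry_corrected=True)


def rule_propensity(rule: Rule, mixture: Mixture) -> float:
    """Mass-action propensity of ``rule`` in ``mixture`` (events per second).

    Unimolecular: k x match count.  Bimolecular: k x M1 x M2 over the two
    reactant match counts, with k x M x (M - 1) when the two patterns are
    identical, and single-molecule patterns of the same type have molecules
    matching both sides subtracted from the pair count (a molecule cannot
    react with itself).
    """
    spec = mixture.spec
    if rule.rate_param in spec.parameters:
        k = float(spec.parameters[rule.rate_param])
    else:
        k = float(rule.rate_param)
    if k == 0.0:
        return 0.0
    if rule.arity == 1:
        return k * match_count(mixture, rule.reactants[0])
    p1, p2 = rule.reactants
    m1 = match_count(mixture, p1)
    if p1 == p2:
        return k * m1 * max(m1 - 1.0, 0.0)
    m2 = match_count(mixture, p2)
    if len(p1.molecules) == 1 and len(p2.molecules) == 1 and (
        p1.molecules[0].type_name == p2.molecules[0].type_name
    ):
        cp1 = compile_pattern(spec, p1)
        cp2 = compile_pattern(spec, p2)
        overlap = sum(
            1
            for mol in mixture.by_type.get(p1.molecules[0].type_name, ())
            if _embed_at(cp1, mol) is not None and _embed_at(cp2, mol) is not None
        )
        return k * max(m1 * m2 - overlap, 0.0)
    return k * m1 * m2


# ---------------------------------------------------------------------------
# incremental match index


class _SampleSet:
    """Set with O(1) add/discard/uniform-sample (swap-remove list + index map)."""

    __slots__ = ("items", "pos")

    def __init__(self):
        self.items: list[Molecule] = []
        self.pos: dict[int, int] = {}

    def add(self, m: Molecule) -> None:
        if m.id not in self.pos:
            self.pos[m.id] = len(self.items)
            self.items.append(m)

    def discard(self, m: Molecule) -> None:
        i = self.pos.pop(m.id, None)
        if i is None:
            return
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last.id] = i

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, m: Molecule) -> bool:
        return m.id in self.pos

    def sample(self, rng: np.random.Generator) -> Molecule:
        return self.items[int(rng.integers(len(self.items)))]


class RuleEngine:
    """Rule engine over a mixture: anchored-match bookkeeping + event firing."""

    def __init__(self, spec: ModelSpec, mixture: Mixture):
        self.spec = spec
        self.mix = mixture
        self.rules = list(spec.rules)
        self.rates = [self._rate_of(r) for r in self.rules]
        self.compiled: list[list[_CompiledPattern]] = [
            [compile_pattern(spec, p) for p in r.reactants] for r in self.rules
        ]
        self.identical_reactants = [
            r.arity == 2 and r.reactants[0] == r.reactants[1] for r in self.rules
        ]
        # slots[(rule_i, side)] -> _SampleSet of anchor molecules
        self.slots: dict[tuple[int, int], _SampleSet] = {}
        # anchor type -> [(rule_i, side, compiled pattern)]
        self.by_anchor_type: dict[str, list[tuple[int, int, _CompiledPattern]]] = {}
        self.max_radius = 0
        for ri, pats in enumerate(self.compiled):
            for si, cp in enumerate(pats):
                self.slots[(ri, si)] = _SampleSet()
                self.by_anchor_type.setdefault(cp.atoms[0].type_name, []).append(
                    (ri, si, cp)
                )
                self.max_radius = max(self.max_radius, cp.n_atoms - 1)
        self.obs_compiled = [
            (ob.name, [compile_pattern(spec, p) for p in ob.patterns])
            for ob in spec.observables
        ]
        for mol in mixture.molecules:
            self._refresh_molecule(mol)

    def _rate_of(self, rule: Rule) -> float:
        if rule.rate_param in self.spec.parameters:
            return float(self.spec.parameters[rule.rate_param])
        return float(rule.rate_param)

    # -- bookkeeping --------------------------------------------------------

    def _refresh_molecule(self, mol: Molecule) -> None:
        for (ri, si, cp) in self.by_anchor_type.get(mol.type_name, ()):
            ok = _embed_at(cp, mol) is not None
            s = self.slots[(ri, si)]
            if ok:
                s.add(mol)
            else:
                s.discard(mol)

    def refresh_new_molecules(self, mols: Iterable[Molecule]) -> None:
        for m in mols:
            self._refresh_molecule(m)

    def _neighborhood(self, seeds: Iterable[Molecule]) -> set:
        out: dict[int, Molecule] = {}
        frontier = list(seeds)
        for m in frontier:
            out[m.id] = m
        for _ in range(self.max_radius):
            nxt = []
            for m in frontier:
                for b in m.bonds:
                    if b is not None and b[0].id not in out:
                        out[b[0].id] = b[0]
                        nxt.append(b[0])
            frontier = nxt
            if not frontier:
                break
        return set(out.values())

    def _update_after(self, touched: Iterable[Molecule], pre_neighborhood: set) -> None:
        affected = pre_neighborhood | self._neighborhood(touched)
        for m in affected:
            self._refresh_molecule(m)

    # -- propensities -------------------------------------------------------

    def match_count(self, ri: int, si: int) -> float:
        cp = self.compiled[ri][si]
        return len(self.slots[(ri, si)]) / cp.automorphisms

    def propensity(self, ri: int) -> float:
        rule = self.rules[ri]
        k = self.rates[ri]
        if k == 0.0:
            return 0.0
        if rule.arity == 1:
            return k * self.match_count(ri, 0)
        m1 = self.match_count(ri, 0)
        m2 = self.match_count(ri, 1)
        if self.identical_reactants[ri]:
            return k * m1 * max(m1 - 1.0, 0.0)
        cps = self.compiled[ri]
        if cps[0].n_atoms == 1 and cps[1].n_atoms == 1 and (
            cps[0].atoms[0].type_name == cps[1].atoms[0].type_name
        ):
            s1, s2 = self.slots[(ri, 0)], self.slots[(ri, 1)]
            small, big = (s1, s2) if len(s1) <= len(s2) else (s2, s1)
            overlap = sum(1 for m in small.items if m in big)
            return k * max(m1 * m2 - overlap, 0.0)
        return k * m1 * m2

    def propensities(self) -> np.ndarray:
        return np.array([self.propensity(ri) for ri in range(len(self.rules))])

    # -- firing -------------------------------------------------------------

    def fire(self, ri: int, rng: np.random.Generator) -> bool:
        """Fire one embedding of rule ``ri``.  Returns False for a null event
        (an overlapping bimolecular pair that was rejected)."""
        rule = self.rules[ri]
        embeddings: list[list[Molecule]] = []
        if rule.arity == 1:
            anchor = self.slots[(ri, 0)].sample(rng)
            emb = _embed_at(self.compiled[ri][0], anchor)
            assert emb is not None
            embeddings.append(emb)
        else:
            for _ in range(30):
                a1 = self.slots[(ri, 0)].sample(rng)
                a2 = self.slots[(ri, 1)].sample(rng)
                e1 = _embed_at(self.compiled[ri][0], a1)
                e2 = _embed_at(self.compiled[ri][1], a2)
                assert e1 is not None and e2 is not None
                ids1 = {m.id for m in e1}
                if all(m.id not in ids1 for m in e2):
                    embeddings = [e1, e2]
                    break
            else:
                return False  # null event: no non-overlapping pair found
        touched = [m for emb in embeddings for m in emb]
        pre = self._neighborhood(touched)
        tf = rule.transformation
        if isinstance(tf, SetState):
            mol = embeddings[tf.reactant][tf.atom]
            ci = self.mix._comp_index[mol.type_name][tf.component]
            mol.states[ci] = tf.new_state
        elif isinstance(tf, Bind):
            (pa, aa, ca), (pb, ab, cb) = tf.first, tf.second
            ma = embeddings[pa][aa]
            mb = embeddings[pb][ab]
            cia = self.mix._comp_index[ma.type_name][ca]
            cib = self.mix._comp_index[mb.type_name][cb]
            if ma.bonds[cia] is not None or mb.bonds[cib] is not None:
                return False  # should not happen: patterns require free sites
            ma.bonds[cia] = (mb, cib)
            mb.bonds[cib] = (ma, cia)
        elif isinstance(tf, Unbind):
            (pa, aa, ca), (_, ab, cb) = tf.first, tf.second
            ma = embeddings[pa][aa]
            mb = embeddings[pa][ab]
            cia = self.mix._comp_index[ma.type_name][ca]
            cib = self.mix._comp_index[mb.type_name][cb]
            ma.bonds[cia] = None
            mb.bonds[cib] = None
        else:  # pragma: no cover
            raise TypeError(f"unknown transformation {tf!r}")
        self._update_after(touched, pre)
        return True

    # -- observables --------------------------------------------------------

    def observe(self) -> dict[str, int]:
        out = {}
        for name, cps in self.obs_compiled:
            total = 0
            for cp in cps:
                raw = 0
                for mol in self.mix.by_type.get(cp.atoms[0].type_name, ()):
                    if _embed_at(cp, mol) is not None:
                        raw += 1
                total += raw // cp.automorphisms
            out[name] = total
        return out


# ---------------------------------------------------------------------------
# protocol & trajectory


@dataclass(frozen=True)
class SimProtocol:
    """Simulation protocol: equilibrate, inject the stimulus at t=0, observe.

    ``stimulus`` maps molecule type names to copy numbers injected at t=0
    (fresh molecules in their default states).  The t=0 observation is taken
    from the equilibrated, still-unstimulated mixture.
    """

    t_eq: float = 100.0
    grid: tuple[float, ...] = (0.0, 5.0, 15.0, 30.0, 60.0)
    n_runs: int = 1
    seed: int = 0
    stimulus: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.t_eq <= 0:
            raise ValueError("t_eq must be positive")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("observation grid must be strictly increasing")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class Trajectory:
    times: np.ndarray  # observation grid, seconds
    counts: dict[str, np.ndarray]  # observable -> counts per grid time
    seed: int
    run_index: int = 0

    def __eq__(self, other):
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and self.counts.keys() == other.counts.keys()
            and all(np.array_equal(self.counts[k], other.counts[k]) for k in self.counts)
        )


def step(engine: RuleEngine, rng: np.random.Generator) -> tuple[float, Optional[int]]:
    """One Gillespie direct-method event.

    Returns (waiting time tau, fired rule index or None for a null event).
    Raises :class:`QuiescentMixture` when the total propensity is zero.
    """
    props = engine.propensities()
    total = props.sum()
    if total <= 0.0:
        raise QuiescentMixture
    tau = rng.exponential(1.0 / total)
    u = rng.random() * total
    ri = int(np.searchsorted(np.cumsum(props), u, side="right"))
    ri = min(ri, len(props) - 1)
    fired = engine.fire(ri, rng)
    return tau, (ri if fired else None)


def _advance(engine: RuleEngine, rng: np.random.Generator, t_end: float) -> None:
    """Advance the mixture to absolute time ``t_end`` (exact-time sampling:
    the state recorded at an observation time is the state in force there)."""
    mix = engine.mix
    while True:
        props = engine.propensities()
        total = props.sum()
        if total <= 0.0:
            mix.t = t_end
            return
        tau = rng.exponential(1.0 / total)
        if mix.t + tau > t_end:
            mix.t = t_end
            return
        mix.t += tau
        u = rng.random() * total
        ri = int(np.searchsorted(np.cumsum(props), u, side="right"))
        ri = min(ri, len(props) - 1)
        engine.fire(ri, rng)


def advance(mixture: Mixture, t_end: float) -> Mixture:
    """Advance an equilibrated mixture (from :func:`equilibrate`) to ``t_end``,
    reusing its attached rule engine and random stream."""
    engine = getattr(mixture, "_engine", None)
    rng = getattr(mixture, "_rng", None)
    if engine is None or rng is None:
        raise ValueError("mixture has no attached engine; obtain it from equilibrate()")
    _advance(engine, rng, t_end)
    return mixture


def equilibrate(
    spec: ModelSpec, protocol: SimProtocol, seed: int
) -> Mixture:
    """Simulate the stimulus-free seed mixture for ``t_eq`` and return it
    (clock reset to 0, ready for stimulation)."""
    for sp in protocol.stimulus:
        for s in spec.seed_species:
            if s.molecule.type_name == sp and s.count > 0:
                raise ValueError(f"stimulus species {sp!r} present in seed species")
    rng = np.random.Generator(np.random.PCG64(seed))
    mix = Mixture.from_seed_species(spec)
    engine = RuleEngine(spec, mix)
    _advance(engine, rng, protocol.t_eq)
    mix.t = 0.0
    mix._engine = engine  # reuse the match index for the production phase
    mix._rng = rng
    return mix


def simulate(
    spec: ModelSpec, protocol: SimProtocol, seed: int, run_index: int = 0
) -> Trajectory:
    """Equilibrate, inject the stimulus at t=0, record observables on the grid.

    Identical (spec, protocol, seed) give a bit-identical trajectory.
    """
    mix = equilibrate(spec, protocol, seed)
    engine: RuleEngine = mix._engine
    rng: np.random.Generator = mix._rng
    grid = list(protocol.grid)
    counts: dict[str, list[int]] = {ob.name: [] for ob in spec.observables}

    def record():
        for name, v in engine.observe().items():
            counts[name].append(v)

    idx = 0
    if grid and grid[0] == 0.0:
        record()  # baseline from the unstimulated steady state
        idx = 1
    new = []
    for sp_name, n in protocol.stimulus.items():
        new.extend(mix.inject(sp_name, n))
    engine.refresh_new_molecules(new)
    for t_obs in grid[idx:]:
        _advance(engine, rng, t_obs)
        record()
    return Trajectory(
        times=np.asarray(grid, dtype=float),
        counts={k: np.asarray(v, dtype=np.int64) for k, v in counts.items()},
        seed=seed,
        run_index=run_index,
    )


def simulate_runs(spec: ModelSpec, protocol: SimProtocol) -> list[Trajectory]:
    """``n_runs`` independent runs with per-run seeds ``protocol.seed + i``."""
    return [
        simulate(spec, protocol, seed=protocol.seed + i, run_index=i)
        for i in range(protocol.n_runs)
    ]


def average_runs(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Arithmetic mean and SD per observable per grid time.

    Returns a tidy frame with columns time_s, observable, mean, sd, n_runs.
    """
    if not trajectories:
        raise ValueError("no trajectories to average")
    t0 = trajectories[0]
    names = list(t0.counts)
    for tr in trajectories[1:]:
        if not np.array_equal(tr.times, t0.times) or list(tr.counts) != names:
            raise ValueError("trajectories have mismatched grids or observables")
    rows = []
    for name in names:
        stack = np.stack([tr.counts[name] for tr in trajectories])  # runs x times
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1) if len(trajectories) > 1 else np.zeros(stack.shape[1])
        for j, t in enumerate(t0.times):
            rows.append(
                {"time_s": t, "observable": name, "mean": mean[j], "sd": sd[j],
                 "n_runs": len(trajectories)}
            )
    return pd.DataFrame(rows)


def mean_course(averaged: pd.DataFrame, observable: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract (times, mean counts) for one observable from `average_runs` output."""
    sub = averaged[averaged["observable"] == observable].sort_values("time_s")
    if sub.empty:
        raise KeyError(f"observable {observable!r} not in averaged trajectory")
    return sub["time_s"].to_numpy(), sub["mean"].to_numpy()


# ---------------------------------------------------------------------------
# protocol files (the role of the study's .rnf simulation-protocol file)


def write_protocol(protocol: SimProtocol) -> str:
    lines = [
        f"t_eq {protocol.t_eq:g}",
        "grid " + " ".join(f"{t:g}" for t in protocol.grid),
        f"n_runs {protocol.n_runs}",
        f"seed {protocol.seed}",
    ]
    for name, n in protocol.stimulus.items():
        lines.append(f"stimulus {name} {n}")
    return "\n".join(lines) + "\n"


def read_protocol(text: str) -> SimProtocol:
    kw: dict = {"stimulus": {}}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0]
        if key == "t_eq":
            kw["t_eq"] = float(parts[1])
        elif key == "grid":
            kw["grid"] = tuple(float(x) for x in parts[1:])
        elif key == "n_runs":
            kw["n_runs"] = int(parts[1])
        elif key == "seed":
            kw["seed"] = int(parts[1])
        elif key == "stimulus":
            kw["stimulus"][parts[1]] = int(parts[2])
        else:
            raise ValueError(f"protocol line {lineno}: unknown key {key!r}")
    return SimProtocol(**kw)
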