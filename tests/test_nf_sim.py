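"""The network-free simulator: embedding counts, propensities, stepping,
equilibration and run averaging, checked against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tcr_phosdyn.nf_sim import (
    Mixture,
    QuiescentMixture,
    RuleEngine,
    SimProtocol,
    average_runs,
    count_embeddings,
    equilibrate,
    match_count,
    mean_course,
    read_protocol,
    rule_propensity,
    simulate,
    simulate_runs,
    step,
    write_protocol,
)
from tcr_phosdyn.rule_model import (
    BOUND_ANY,
    FREE,
    WILD,
    parse_model,
    parse_pattern,
)

from conftest import BINDING_MODEL, DECAY_MODEL


# ---------------------------------------------------------------------------
# brute-force subgraph-monomorphism oracle (independent of the implementation)


def brute_force_embeddings(mixture, pattern):
    """Count injective mappings of pattern atoms onto molecules satisfying all
    type, state and bond constraints, by exhaustive enumeration."""
    spec = mixture.spec
    comp_idx = {
        mt.name: {c.name: i for i, c in enumerate(mt.components)}
        for mt in spec.molecule_types
    }
    atoms = pattern.molecules
    label_ends = pattern.bond_edges()
    n = len(atoms)
    count = 0
    for combo in itertools.permutations(mixture.molecules, n):
        ok = True
        for atom, mol in zip(atoms, combo):
            if mol.type_name != atom.type_name:
                ok = False
                break
            for cp in atom.components:
                ci = comp_idx[atom.type_name][cp.name]
                if cp.state is not None and mol.states[ci] != cp.state:
                    ok = False
                    break
                bond = mol.bonds[ci]
                if cp.bond == FREE and bond is not None:
                    ok = False
                elif cp.bond == BOUND_ANY and bond is None:
                    ok = False
                elif isinstance(cp.bond, int) and bond is None:
                    ok = False
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        for _, ends in label_ends.items():
            (ia, ca), (ib, cb) = ends
            mol_a, mol_b = combo[ia], combo[ib]
            ci_a = comp_idx[mol_a.type_name][ca]
            ci_b = comp_idx[mol_b.type_name][cb]
            bond = mol_a.bonds[ci_a]
            if bond is None or bond[0] is not mol_b or bond[1] != ci_b:
                ok = False
                break
        if ok:
            count += 1
    return count


MIX_SPEC = parse_model(
    """
begin parameters
  k 1
end parameters
begin molecule types
  A(x,y~U~P)
  B(x)
end molecule types
begin seed species
  A(x,y~U) 0
  B(x) 0
end seed species
"""
)


def random_mixture(rng, n_max=12):
    mix = Mixture(MIX_SPEC)
    n = int(rng.integers(2, n_max + 1))
    for _ in range(n):
        t = "A" if rng.random() < 0.6 else "B"
        m = mix.add_molecule(
            parse_pattern(f"A(x,y~{'U' if rng.random() < 0.5 else 'P'})" if t == "A" else "B(x)").molecules[0]
        )
    # random bonds between free x components
    mols = list(mix.molecules)
    rng.shuffle(mols)
    free = [m for m in mols if m.bonds[0] is None]
    for a, b in zip(free[::2], free[1::2]):
        if rng.random() < 0.6:
            xa = 0
            xb = 0
            a.bonds[xa] = (b, xb)
            b.bonds[xb] = (a, xa)
    mix.check_invariants()
    return mix


PATTERNS = [
    "A(x)",
    "A(x!+)",
    "A(y~P)",
    "A(y~P,x!?)",
    "B(x)",
    "A(x!1).B(x!1)",
    "A(x!1).A(x!1)",
    "A(y~U,x!1).A(x!1)",
]


class TestEmbeddings:
    def test_free_molecules_count(self):
        mix = Mixture(MIX_SPEC)
        for _ in range(3):
            mix.add_molecule(parse_pattern("A(x,y~U)").molecules[0])
        assert count_embeddings(mix, parse_pattern("A(x)")) == 3

    def test_bound_pair_counts_once(self):
        mix = Mixture(MIX_SPEC)
        a = mix.add_molecule(parse_pattern("A(x,y~U)").molecules[0])
        b = mix.add_molecule(parse_pattern("B(x)").molecules[0])
        a.bonds[0] = (b, 0)
        b.bonds[0] = (a, 0)
        assert count_embeddings(mix, parse_pattern("A(x!+)")) == 1
        assert count_embeddings(mix, parse_pattern("A(x!1).B(x!1)")) == 1

    def test_symmetric_homodimer_symmetry_correction(self):
        mix = Mixture(MIX_SPEC)
        a1 = mix.add_molecule(parse_pattern("A(x,y~U)").molecules[0])
        a2 = mix.add_molecule(parse_pattern("A(x,y~U)").molecules[0])
        a1.bonds[0] = (a2, 0)
        a2.bonds[0] = (a1, 0)
        dimer = parse_pattern("A(x!1).A(x!1)")
        assert count_embeddings(mix, dimer, symmetry_corrected=False) == 2
        assert count_embeddings(mix, dimer, symmetry_corrected=True) == 1

    def test_agrees_with_brute_force_on_random_mixtures(self):
        rng = np.random.Generator(np.random.PCG64(5))
        for trial in range(30):
            mix = random_mixture(rng)
            for pat_text in PATTERNS:
                pat = parse_pattern(pat_text)
                assert (
                    count_embeddings(mix, pat, symmetry_corrected=False)
                    == brute_force_embeddings(mix, pat)
                ), f"trial {trial}, pattern {pat_text}"

    def test_unknown_type_raises(self):
        mix = Mixture(MIX_SPEC)
        with pytest.raises(KeyError):
            count_embeddings(mix, parse_pattern("Z(q)"))


class TestPropensity:
    def test_unimolecular(self):
        spec = parse_model(
            """
begin parameters
  k 0.5
end parameters
begin molecule types
  A(y~U~P)
end molecule types
begin seed species
  A(y~U) 10
end seed species
begin reaction rules
  flip: A(y~U) -> A(y~P) k
end reaction rules
"""
        )
        mix = Mixture.from_seed_species(spec)
        assert rule_propensity(spec.rules[0], mix) == pytest.approx(5.0)

    def test_bimolecular_pair_enumeration(self, binding_spec):
        from dataclasses import replace

        spec = replace(binding_spec, parameters={"k_on": 2.0, "k_off": 0.1})
        mix = Mixture(spec)
        for _ in range(3):
            mix.add_molecule(parse_pattern("A(b)").molecules[0])
        for _ in range(4):
            mix.add_molecule(parse_pattern("B(a)").molecules[0])
        bind = next(r for r in spec.rules if r.name == "bind")
        assert rule_propensity(bind, mix) == pytest.approx(24.0)

    def test_zero_matches_zero_propensity(self, binding_spec):
        mix = Mixture(binding_spec)  # empty mixture
        for rule in binding_spec.rules:
            assert rule_propensity(rule, mix) == 0.0

    def test_same_type_overlap_subtracted(self):
        # kinase form and substrate form overlap on molecules matching both
        spec = parse_model(
            """
begin parameters
  k 1
end parameters
begin molecule types
  A(y~U~P,z~U~P)
end molecule types
begin seed species
  A(y~U,z~U) 4
end seed species
begin reaction rules
  trans: A(z~U) + A(y~U) -> A(z~U) + A(y~P) k
end reaction rules
"""
        )
        mix = Mixture.from_seed_species(spec)
        # all 4 molecules match both sides: ordered pairs = 4*4 - 4 = 12
        assert rule_propensity(spec.rules[0], mix) == pytest.approx(12.0)


class TestStep:
    def test_single_possible_event_fires(self, minimal_spec):
        from dataclasses import replace

        spec = replace(
            minimal_spec,
            seed_species=(replace(minimal_spec.seed_species[0], count=1),),
        )
        mix = Mixture.from_seed_species(spec)
        engine = RuleEngine(spec, mix)
        rng = np.random.Generator(np.random.PCG64(0))
        tau, fired = step(engine, rng)
        assert fired == 0
        assert mix.molecules[0].states[0] == "P"
        assert tau > 0

    def test_quiescent_mixture_raises(self, minimal_spec):
        from dataclasses import replace

        spec = replace(minimal_spec, rules=())
        mix = Mixture.from_seed_species(spec)
        engine = RuleEngine(spec, mix)
        with pytest.raises(QuiescentMixture):
            step(engine, np.random.Generator(np.random.PCG64(0)))

    def test_rule_selection_proportional_to_propensity(self):
        # two competing rules with rates 1 and 3 from the same single molecule
        spec = parse_model(
            """
begin parameters
  k1 1
  k2 3
end parameters
begin molecule types
  A(y~U~P,z~U~P)
end molecule types
begin seed species
  A(y~U,z~U) 1
end seed species
begin reaction rules
  slow: A(y~U) -> A(y~P) k1
  fast: A(z~U) -> A(z~P) k2
end reaction rules
"""
        )
        rng = np.random.Generator(np.random.PCG64(1234))
        n_trials = 4000
        fast = 0
        for _ in range(n_trials):
            mix = Mixture.from_seed_species(spec)
            engine = RuleEngine(spec, mix)
            _, fired = step(engine, rng)
            fast += fired == 1
        p_hat = fast / n_trials
        se = (0.75 * 0.25 / n_trials) ** 0.5
        assert abs(p_hat - 0.75) < 3 * se


class TestSimulate:
    def test_no_rule_model_constant_observables(self, minimal_spec):
        from dataclasses import replace

        spec = replace(minimal_spec, rules=())
        proto = SimProtocol(t_eq=10.0, grid=(0.0, 5.0, 15.0), n_runs=1, seed=0)
        traj = simulate(spec, proto, seed=0)
        assert np.array_equal(traj.counts["A_P"], [0, 0, 0])

    def test_decay_matches_exponential(self, decay_spec):
        proto = SimProtocol(t_eq=1e-9, grid=(0.0, 10.0), n_runs=50, seed=3)
        trajs = simulate_runs(decay_spec, proto)
        frac = np.mean([t.counts["A_P"][1] for t in trajs]) / 1000.0
        expected = np.exp(-0.1 * 10.0)
        se = np.sqrt(expected * (1 - expected) / 1000.0 / 50)
        assert abs(frac - expected) < 3 * se

    def test_reversible_binding_matches_ode_equilibrium(self, binding_spec):
        # ODE oracle: dx/dt = k_on (A0-x)(B0-x) - k_off x
        k_on, k_off, a0, b0 = 0.01, 0.1, 30, 40
        sol = solve_ivp(
            lambda t, x: [k_on * (a0 - x[0]) * (b0 - x[0]) - k_off * x[0]],
            (0, 60.0), [0.0], rtol=1e-8, atol=1e-10, dense_output=True,
        )
        ode_eq = sol.y[0][-1]
        proto = SimProtocol(t_eq=1e-9, grid=(0.0, 40.0, 60.0), n_runs=30, seed=9)
        trajs = simulate_runs(binding_spec, proto)
        values = np.array([t.counts["AB"][1:] for t in trajs], dtype=float)
        mean = values.mean()
        se = values.mean(axis=1).std(ddof=1) / np.sqrt(len(trajs))
        assert abs(mean - ode_eq) < 3 * max(se, 0.5)

    def test_fixed_seed_bit_identical(self, binding_spec):
        proto = SimProtocol(t_eq=5.0, grid=(0.0, 5.0, 15.0), n_runs=1, seed=42)
        t1 = simulate(binding_spec, proto, seed=42)
        t2 = simulate(binding_spec, proto, seed=42)
        assert t1 == t2

    def test_conservation_of_molecules(self, binding_spec):
        proto = SimProtocol(t_eq=20.0, grid=(0.0, 30.0), n_runs=1, seed=7)
        mix = equilibrate(binding_spec, proto, seed=7)
        assert mix.counts_by_type() == {"A": 30, "B": 40}
        mix.check_invariants()


class TestEquilibrate:
    def test_no_rule_model_returns_seed_mixture(self, minimal_spec):
        from dataclasses import replace

        spec = replace(minimal_spec, rules=())
        proto = SimProtocol(t_eq=10.0, n_runs=1, seed=0)
        mix = equilibrate(spec, proto, seed=0)
        assert mix.counts_by_type() == {"A": 10}
        assert all(m.states[0] == "U" for m in mix.molecules)

    def test_stimulus_in_seed_species_rejected(self, minimal_spec):
        proto = SimProtocol(t_eq=10.0, n_runs=1, seed=0, stimulus={"A": 5})
        with pytest.raises(ValueError, match="stimulus"):
            equilibrate(minimal_spec, proto, seed=0)

    def test_constitutive_cycle_reaches_stationarity(self):
        spec = parse_model(
            """
begin parameters
  kf 0.05
  kb 0.05
end parameters
begin molecule types
  A(y~U~P)
end molecule types
begin seed species
  A(y~U) 200
end seed species
begin observables
  Molecules A_P A(y~P)
end observables
begin reaction rules
  f: A(y~U) -> A(y~P) kf
  b: A(y~P) -> A(y~U) kb
end reaction rules
"""
        )
        # doubling the equilibration time leaves the t=0 observation unchanged
        def t0_mean(t_eq, seed0):
            proto = SimProtocol(t_eq=t_eq, grid=(0.0, 1.0), n_runs=25, seed=seed0)
            trajs = simulate_runs(spec, proto)
            return np.mean([t.counts["A_P"][0] for t in trajs])

        m1 = t0_mean(120.0, 100)
        m2 = t0_mean(240.0, 200)
        se = np.sqrt(200 * 0.25 / 25)  # binomial sd at p=0.5 over 25 runs
        assert abs(m1 - m2) < 3 * se * np.sqrt(2)
        assert abs(m1 - 100.0) < 3 * se


class TestAverageRuns:
    def _traj(self, values, seed=0):
        from tcr_phosdyn.nf_sim import Trajectory

        return Trajectory(
            times=np.array([0.0, 5.0]),
            counts={"X": np.array(values)},
            seed=seed,
        )

    def test_mean_and_sd(self):
        df = average_runs([self._traj([2, 2]), self._traj([4, 4], seed=1)])
        x = df[df["observable"] == "X"]
        assert np.allclose(x["mean"], 3.0)
        assert np.allclose(x["sd"], np.sqrt(2.0))
        assert (x["n_runs"] == 2).all()

    def test_single_run_sd_zero(self):
        df = average_runs([self._traj([5, 7])])
        x = df[df["observable"] == "X"]
        assert np.allclose(x["mean"], [5, 7])
        assert np.allclose(x["sd"], 0.0)

    def test_mismatched_grids_rejected(self):
        from tcr_phosdyn.nf_sim import Trajectory

        t1 = self._traj([1, 2])
        t2 = Trajectory(times=np.array([0.0, 9.0]), counts={"X": np.array([1, 2])}, seed=0)
        with pytest.raises(ValueError, match="mismatched"):
            average_runs([t1, t2])

    def test_decay_mean_tracks_analytic_curve(self, decay_spec):
        proto = SimProtocol(t_eq=1e-9, grid=(0.0, 5.0, 10.0, 20.0), n_runs=100, seed=21)
        df = average_runs(simulate_runs(decay_spec, proto))
        times, means = mean_course(df, "A_P")
        for t, m in zip(times, means):
            expected = 1000.0 * np.exp(-0.1 * t)
            p = expected / 1000.0
            se = np.sqrt(max(p * (1 - p), 1e-9) * 1000.0 / 100)
            assert abs(m - expected) < 3 * max(se, 0.5), f"t={t}"


class TestProtocolFiles:
    def test_round_trip(self):
        proto = SimProtocol(t_eq=80.0, grid=(0.0, 5.0, 15.0), n_runs=7, seed=3,
                            stimulus={"Ligand": 150})
        assert read_protocol(write_protocol(proto)) == proto

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown key"):
            read_protocol("t_eq 10\nvolume 1\n")

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SimProtocol(t_eq=10.0, grid=(0.0, 5.0, 5.0), n_runs=1, seed=0)
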