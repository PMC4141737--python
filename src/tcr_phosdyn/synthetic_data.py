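"""Synthetic datasets with known ground truth.

Two generators:

* :func:`generate_ratio_table` emulates a SILAC phosphopeptide ratio table —
  3 biological replicates, ratios at 5/15/30/60 s vs 0 s, multiplicative
  log-normal measurement noise, independent per-replicate detection dropout
  (partial replicate overlap), and four planted temporal archetypes
  (fast-up, slow-up, down, transient) on a regulated subset.  Peptide
  metadata (phospho-group and proline counts, an occasional extra
  more-phosphorylated peptide per site) exercises the upstream pipeline
  stages.

* :func:`generate_truth_dataset` simulates a rule-based model at known
  parameters and degrades the relative courses with log-normal noise, for
  parameter-recovery experiments.

Defaults are the study-like conditions: 700 sites, ~26% regulated (about
138 sites carry a >= 2-fold change at 60 s: the transient archetype has
relaxed below threshold by then), sigma = 0.3 log2 units, detection
probability 0.8 per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nf_sim import SimProtocol, average_runs, mean_course, simulate
from .rule_model import ModelSpec

__all__ = [
    "ArchetypeProfile",
    "GeneratorConfig",
    "DEFAULT_ARCHETYPES",
    "generate_ratio_table",
    "generate_truth_dataset",
    "toy_phospho_model",
    "toy_protocol",
]

_TIMES = (5.0, 15.0, 30.0, 60.0)
_TIME_COLUMNS = ("t5", "t15", "t30", "t60")
_AMINO_ACIDS = "ACDEFGHIKLMNQRSTVWY"  # proline added separately


@dataclass(frozen=True)
class ArchetypeProfile:
    """A canonical temporal pattern in mean log2-ratio units at 5/15/30/60 s."""

    name: str
    log2_means: tuple[float, float, float, float]

    @property
    def peak_fold_change(self) -> float:
        return float(2.0 ** np.max(np.abs(self.log2_means)))


#: Regulated archetypes reach >= 2-fold: fast-up by 5 s, slow-up by 30 s,
#: down crosses 1/2 by 30 s, transient rises early then relaxes below
#: threshold by 60 s.  The unregulated profile stays within (1/2, 2).
DEFAULT_ARCHETYPES: dict[str, ArchetypeProfile] = {
    "fast-up": ArchetypeProfile("fast-up", (1.3, 1.6, 1.7, 1.8)),
    "slow-up": ArchetypeProfile("slow-up", (0.2, 0.6, 1.2, 1.6)),
    "down": ArchetypeProfile("down", (-0.5, -0.9, -1.3, -1.5)),
    "transient": ArchetypeProfile("transient", (1.4, 1.7, 0.8, 0.3)),
    "unregulated": ArchetypeProfile("unregulated", (0.0, 0.0, 0.0, 0.0)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-like conditions for the synthetic ratio table."""

    n_sites: int = 700
    fraction_regulated: float = 0.263
    archetype_weights: Mapping[str, float] = field(
        default_factory=lambda: {"fast-up": 0.25, "slow-up": 0.25, "down": 0.25, "transient": 0.25}
    )
    n_replicates: int = 3
    sigma: float = 0.3  # log2 units of multiplicative noise
    detection_probability: float = 0.8  # independent per replicate and site
    extra_peptide_fraction: float = 0.1  # sites also covered by a doubly-phospho peptide
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_regulated <= 1.0:
            raise ValueError("fraction_regulated must lie in [0, 1]")
        if not 0.0 <= self.detection_probability <= 1.0:
            raise ValueError("detection_probability must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        w = self.archetype_weights
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("archetype weights must sum to 1")
        if set(w) - (set(DEFAULT_ARCHETYPES) - {"unregulated"}):
            raise ValueError("unknown archetype in weights")


def _random_sequence(rng: np.random.Generator, length: int, n_proline: int) -> str:
    letters = [
        _AMINO_ACIDS[i] for i in rng.integers(0, len(_AMINO_ACIDS), size=length - n_proline)
    ]
    letters += ["P"] * n_proline
    rng.shuffle(letters)  # type: ignore[arg-type]
    return "".join(letters)


def generate_ratio_table(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize a phosphopeptide ratio table plus its ground truth.

    Returns ``(table, truth)``.  ``table`` has one row per (peptide,
    replicate) with columns protein, residues, sequence, n_phospho,
    n_proline, replicate, t5..t60 (NaN rows for dropped replicate
    detections).  ``truth`` has one row per site: protein, residues,
    archetype, regulated, and the noiseless ratio at each time point.
    Deterministic for a fixed config (seed included).
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    names = sorted(set(config.archetype_weights))
    weights = np.array([config.archetype_weights[n] for n in names])

    table_rows: list[dict] = []
    truth_rows: list[dict] = []
    n_regulated = int(round(config.n_sites * config.fraction_regulated))

    for i in range(config.n_sites):
        protein = f"SYNP{i:04d}"
        residue = int(rng.integers(20, 900))
        regulated = i < n_regulated
        if regulated:
            archetype = names[int(rng.choice(len(names), p=weights))]
        else:
            archetype = "unregulated"
        profile = np.array(DEFAULT_ARCHETYPES[archetype].log2_means)
        true_ratios = 2.0 ** profile

        n_proline = int(rng.integers(0, 4))
        length = int(rng.integers(8, 18))
        sequence = _random_sequence(rng, length, n_proline)
        peptides = [(sequence, 1, n_proline)]
        if rng.random() < config.extra_peptide_fraction:
            extra_pro = int(rng.integers(0, 4))
            peptides.append(
                (_random_sequence(rng, length + 3, extra_pro), 2, extra_pro)
            )

        truth_rows.append(
            {"protein": protein, "residues": str(residue), "archetype": archetype,
             "regulated": regulated,
             **{c: r for c, r in zip(_TIME_COLUMNS, true_ratios)}}
        )

        for seq, n_phos, n_pro in peptides:
            # the secondary (more-phosphorylated) peptide reports attenuated
            # dynamics: site collapse must prefer the least-modified one
            atten = 1.0 if n_phos == 1 else 0.6
            for rep in range(1, config.n_replicates + 1):
                detected = rng.random() < config.detection_probability
                row = {
                    "protein": protein, "residues": str(residue), "sequence": seq,
                    "n_phospho": n_phos, "n_proline": n_pro, "replicate": rep,
                }
                if detected:
                    noise = rng.normal(0.0, config.sigma, size=4)
                    vals = 2.0 ** (atten * profile + noise)
                    row.update({c: float(v) for c, v in zip(_TIME_COLUMNS, vals)})
                else:
                    row.update({c: np.nan for c in _TIME_COLUMNS})
                table_rows.append(row)

    table = pd.DataFrame(table_rows)
    truth = pd.DataFrame(truth_rows)
    return table, truth


def generate_truth_dataset(
    spec: ModelSpec,
    protocol: SimProtocol,
    sigma: float,
    seed: int,
    sites: Optional[Sequence[str]] = None,
    n_runs: Optional[int] = None,
    eps: float = 0.5,
) -> dict[str, np.ndarray]:
    """Simulated "measured" relative time courses with log-normal noise.

    Simulates ``spec`` under ``protocol`` (``n_runs`` runs, seeds
    ``protocol.seed + i``), converts each observable to a relative course
    (baseline-normalized, pseudocount ``eps`` when the baseline is zero) and
    multiplies post-baseline values by 2**Normal(0, sigma).  Returns
    observable -> ratio array on the protocol grid (value 1 at t=0).
    """
    runs = n_runs if n_runs is not None else protocol.n_runs
    trajs = [simulate(spec, protocol, seed=protocol.seed + i, run_index=i) for i in range(runs)]
    averaged = average_runs(trajs)
    rng = np.random.Generator(np.random.PCG64(seed))
    names = sites or sorted({o.name for o in spec.observables})
    out: dict[str, np.ndarray] = {}
    for name in names:
        _, values = mean_course(averaged, name)
        v0 = values[0]
        rel = (values + eps) / (v0 + eps) if v0 == 0 else values / v0
        noisy = rel.copy()
        if sigma > 0:
            noisy[1:] = rel[1:] * 2.0 ** rng.normal(0.0, sigma, size=len(rel) - 1)
        noisy[0] = 1.0
        out[name] = noisy
    return out


def toy_phospho_model(
    k_phos: float = 0.002,
    k_dephos: float = 0.05,
    k_basal: float = 0.002,
    n_substrate: int = 200,
) -> ModelSpec:
    """Ligand-induced phosphorylation/dephosphorylation cycle (2 free parameters).

    A stimulus S injected at t=0 drives phosphorylation of substrate A at
    rate ``k_phos`` per (S, A) pair; ``k_dephos`` is the first-order
    dephosphorylation constant; a small constitutive rate ``k_basal``
    (held fixed in recovery experiments) gives the unstimulated baseline.
    Observables count the phosphorylated (``A_P``) and unphosphorylated
    (``A_U``) substrate; fitting both relative courses pins the absolute
    baseline fraction, which a single ratio-normalized course cannot.
    """
    from .rule_model import parse_model

    text = f"""
begin parameters
  k_phos {k_phos:.12g}
  k_dephos {k_dephos:.12g}
  k_basal {k_basal:.12g}
end parameters
begin molecule types
  S(a)
  A(y~U~P)
end molecule types
begin seed species
  A(y~U) {n_substrate}
end seed species
begin observables
  Molecules A_P A(y~P)
  Molecules A_U A(y~U)
end observables
begin reaction rules
  stim_phos: S(a) + A(y~U) -> S(a) + A(y~P) k_phos
  dephos: A(y~P) -> A(y~U) k_dephos
  basal_phos: A(y~U) -> A(y~P) k_basal
end reaction rules
"""
    return parse_model(text)


def toy_protocol(n_runs: int = 20, seed: int = 0, n_stimulus: int = 50) -> SimProtocol:
    """Default protocol for the toy cycle: 50 s equilibration, S injected at t=0."""
    return SimProtocol(
        t_eq=50.0,
        grid=(0.0, 5.0, 15.0, 30.0, 60.0),
        n_runs=n_runs,
        seed=seed,
        stimulus={"S": n_stimulus},
    )
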