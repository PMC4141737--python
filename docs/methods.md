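# Methods

This note documents the models, algorithms and conventions implemented in
`tcr-phosdyn`, the defaults they ship with, and what the synthetic-data
experiments do and do not demonstrate.

## Rule-based model representation

Models are expressed as molecule types with named components — binding
domains (no states), motifs, and phosphotyrosine sites with the fixed state
alphabet {U, P} — plus seed species with integer copy numbers, named rate
parameters, reaction rules and pattern-count observables.  A rule carries
exactly one elementary transformation: form a bond, break a bond, or flip
one component state, under elementary mass action.  The text dialect is a
BNGL subset restricted to the five standard blocks; compartments, functional
rate laws, synthesis/degradation arrows and reversible arrows are rejected
with an error rather than skipped, because a silently subsetted kinetics
language produces silently wrong models.  The writer emits canonical
(alphabetical) ordering, which makes `parse(write(m)) == m.canonical()` an
exact, testable round trip.

## Network-free stochastic simulation

The simulator tracks every molecule instance (a site graph: per-component
states and symmetric bonds) and never enumerates a reaction network.
Stepping is the Gillespie direct method: the waiting time is exponential in
the total propensity and the rule to fire is chosen proportionally to its
propensity.  Rule propensities come from embedding counts of the reactant
patterns in the current mixture:

* a pattern's match count is its embedding count divided by the order of its
  automorphism group, so a symmetric dimer pattern counts each physical
  dimer once (the mass-action convention);
* bimolecular rules use k·M₁·M₂ over the two match counts, with k·M·(M−1)
  when the two patterns are identical; distinct single-molecule patterns of
  the same molecule type have molecules matching both sides subtracted from
  the pair count, and for multi-molecule patterns the rare overlapping pair
  is rejected at firing time as a null event (the clock still advances);
* because every multi-molecule pattern must be connected through bond
  labels, an embedding anchored at a molecule is forced by following actual
  bonds, which makes incremental bookkeeping cheap: after an event only the
  neighborhoods (graph radius = pattern size − 1) of the touched molecules
  are re-matched.

The model lives in one well-mixed volume.  Bimolecular rate constants are
given directly in events·s⁻¹ per reactant pair (copy-number units); no
volume conversion exists because none is defined for the system.  Membrane/
cytosol location tags on molecule types are annotations only.

A simulation protocol specifies an equilibration time `t_eq`, an observation
grid (default {0, 5, 15, 30, 60} s), the stimulus species injected at t = 0,
a run count and a seed.  Equilibration runs the stimulus-free model to its
unstimulated steady state; the t = 0 observation is taken from that mixture
before injection.  Observation uses exact-time sampling: the state recorded
at a grid time is the state in force there (the next event's waiting time is
re-drawn, which is statistically identical by memorylessness).  When total
propensity reaches zero the clock jumps to the next observation time.
Per-run seeds are `seed + run_index`; a fixed (model, protocol, seed) gives
a bit-identical trajectory.  Run averaging is the arithmetic mean (and SD)
per observable per grid time.

## The TCR/CD28 network

The shipped network covers 10 measured proteins carrying 16 phosphotyrosine
site observables, plus 7 regulatory proteins (CD3E, CD3G, CD28, NCK1, GRAP2,
CSK, RASA1) and a stimulus crosslinker species with anti-CD3E, anti-CD3G and
anti-CD28 arms.  The mechanisms, as encoded:

* **Receptor-independent ("class 1") phosphorylation** — LCK constitutively
  docks on CD28; on ligand-engaged CD28 it phosphorylates CD3G Y171 and
  trans-autophosphorylates LCK Y394 without requiring prior ITAM
  phosphorylation.
* **ITAM-dependent ("class 2") cascade** — active LCK (Y394~P, Y505~U)
  phosphorylates CD3E Y188 (only when the overlapping proline-rich sequence
  is unoccupied); ZAP70 binds phospho-Y188 via its SH2 domain and is
  phosphorylated at Y493/Y292; active ZAP70 phosphorylates LAT (Y191, Y226)
  and LCP2 (Y128, Y145); LAT recruits GRAP2, GRAP2 recruits LCP2,
  phospho-LCP2 recruits NCK1 (SH2–pY128) and PLCG1 (SH2–pY145), and
  recruited PLCG1 is phosphorylated at Y771/Y783.
* **Shortcut to WAS** — NCK1's N-terminal SH3 binds the CD3E PRS while Y188
  is unphosphorylated (mutual exclusion both ways); its C-terminal SH3
  constitutively binds WAS; WAS anchored through either route (CD3E or
  phospho-LCP2) is phosphorylated at Y291 by active LCK.  Because the
  NCK1–CD3E complex pre-forms during equilibration, WAS responds before the
  ITAM cascade engages; as Y188 phosphorylation accumulates the shortcut
  disengages and the LCP2-dependent route takes over.
* **Negative regulation and the phosphatase loops ("class 3") ** — PAG1 Y163
  (phosphorylated by open LCK) recruits CSK, which phosphorylates the
  inhibitory LCK Y505; Y505 is cleared by a constitutive pseudo-first-order
  phosphatase activity folded into `k_y505_off`.  LCK Y192, DOK1 Y449 and
  DOK2 Y299 carry basal phosphorylation (ambient kinase activity folded into
  `k_basal_on`); DOK1 binds CSK and DOK2 binds RASA1.  Active LCK
  phosphorylates PTPN6 Y566; active PTPN6 dephosphorylates LCK Y192, PAG1
  Y163, DOK1 Y449 and DOK2 Y299.  Stripping PAG1 releases CSK, Y505 falls,
  more LCK opens — the positive feedback that makes the phosphatase an
  accelerator early in signaling.  PTPN6's action on Y505 is therefore
  indirect by default; a `ptpn6_direct_y505` toggle adds the direct rule.

Knockdowns set a protein's seed copy number to zero and touch nothing else;
the operation is idempotent.  Derived readouts: relative time courses
(observable counts divided by the t = 0 baseline, with pseudocount ε = 0.5
added to numerator and denominator when the baseline is zero), trapezoidal
cumulative phosphorylation over a window (default 0–60 s), endpoint scaling
(value 1 at 60 s), and interpolated half-rise times.

**Parameters.**  The shipped table is reconstructed, not the original fitted
table (which is not reproducible here).  Association constants are
~5·10⁻³–10⁻² s⁻¹·pair⁻¹ with dissociation 0.05–0.1 s⁻¹; catalytic constants
are chosen so the cascade unfolds across the 60 s window; copy numbers are
80–150 per species — a deliberately scaled-down cell so that multi-genotype,
multi-run Monte Carlo averaging is cheap.  The package's claims about this
network are directional (orderings, increase/decrease under knockdown) and
are insensitive to this scale; absolute counts are not calibrated to a real
cell.  Defaults were tuned once so that all four directional families hold
robustly (wild-type WAS-before-ZAP70 ordering, the four PTPN6-knockdown
directions, LCP2-knockdown selectivity, shortcut disengagement) and are
fixed thereafter.  The "WAS retains its response under LCP2 knockdown"
statement is operationalized as retaining at least 50% of the wild-type
cumulative response — a repository convention.

## Phosphoproteomic pipeline

Input is a tidy phosphopeptide table: one row per (peptide, replicate) with
abundance ratios at 5/15/30/60 s relative to unstimulated cells.

* **Proline correction** — in heavy-arginine SILAC cultures,
  arginine-to-proline conversion deflates measured ratios of
  proline-containing peptides; with converted fraction f each ratio is
  multiplied by (1−f)^(−n_proline).  The functional form is a
  reconstruction; the default f = 0 leaves data untouched so the step is
  auditable and off unless configured.
* **Least-modified collapse** — among peptides covering a site, the one with
  the fewest phospho groups is kept (ties: shortest, then lexicographically
  smallest sequence), so multiply-phosphorylated peptides do not dilute
  single-site dynamics.
* **Replicate averaging** — arithmetic mean over available replicates per
  time point; missing values are skipped, never imputed; SD is reported for
  n ≥ 2.
* **Regulation filter** — a site is regulated iff its mean ratio is ≥ θ or
  ≤ 1/θ at ≥ 1 time point (θ = 2).  The boundary comparator is ≥ by default
  and configurable to strict >, since both conventions appear in practice.
  Direction (up/down/mixed) and the earliest qualifying time are reported.
  The regulated set is monotonically non-increasing in θ.
* **Clustering** — fuzzy c-means (Bezdek alternating optimization; c = 4,
  fuzzifier m = 2, tolerance 10⁻⁶, ≤ 500 iterations, seeded initialization)
  on standardized courses: each course is prepended with its baseline point
  (ratio 1 at t = 0), log2-transformed and z-scored.  Anchoring at the
  baseline is deliberate: z-scoring bare 4-point courses erases sign and
  rise-timing information and collapses down-regulated onto transient
  shapes; with the anchor the four archetypes separate cleanly.  Memberships
  sum to 1 per site; the hard label is the argmax.
* **Dynamical classes** — model-site courses are assigned to three classes
  by PCA on the standardized log2 courses followed by seeded k-means (k = 3)
  in the first two components; the cluster with the lowest mean log2 course
  is the dephosphorylated class 3, and of the two rising clusters the one
  reaching the larger fraction of its final rise at the first time point is
  the receptor-independent class 1.  The k-means operationalization of the
  class boundary is a repository convention.
* **Enrichment** — per cluster, a one-sided Fisher exact test of term
  membership against the detected-but-unregulated protein background,
  Benjamini–Hochberg adjustment across the cluster's terms, and reporting
  only terms occurring ≥ 2 times in the cluster with adjusted p < 0.05.
  Annotations are user-supplied (protein, term) tables; no live ontology
  retrieval.

## Parameter estimation

Parameters are classed as literature-fixed (never varied), derived
(arithmetic expressions evaluated in topological order; cycles are reported
as errors naming the cycle) or fitted.  The objective is the sum over sites
and post-baseline grid times of squared log2 differences between simulated
mean relative phosphorylation and measured mean ratios — log2 so up- and
down-regulation weigh symmetrically.  Common random numbers (the same
per-run seed stream at every evaluation) make the Monte Carlo objective a
deterministic function of the parameters.

Fitting is two-stage: an exhaustive coarse grid search (ties break to the
first point in enumeration order), then bounded quasi-Newton
(variable-metric) refinement from the grid optimum via L-BFGS-B —
positivity-only parameters move in log10 space, box bounds are enforced
directly.  Gradients are finite differences; for the Monte Carlo objective a
coarse step (0.05 in log10 units) is essential because the CRN objective is
deterministic but jagged at fine scales, and a fine-step gradient reads the
jaggedness instead of the trend.  The refined result is safeguarded never to
exceed the grid objective.

The recovery experiment fits the 2-parameter stimulus-driven
phosphorylation cycle (200 substrate copies, 50 stimulus copies, basal rate
fixed) to data simulated at known parameters with σ = 0.1 log2 noise, using
a 5×5 half-decade grid (neither true value lies on it) and a 60-run
objective; both constants are recovered within 25%.  An identifiability
point matters here: a single baseline-normalized phospho course loses the
absolute baseline fraction, leaving the two rates identified only through
their ratio — a flat valley that noise at σ = 0.1 can shift by a factor
~1.5.  The experiment therefore fits the relative courses of both the
phosphorylated and the unphosphorylated form; the pair pins the baseline
fraction and restores a well-conditioned minimum.  The full 16-site network
fit uses the same machinery (`tcr-phosdyn fit`) but is not part of the
default experiments because no reference fitted values exist to compare
against.

## Synthetic data

`generate_ratio_table` emulates the statistical structure of a SILAC
phosphotyrosine time-course experiment: 3 biological replicates, 4 time
points, multiplicative log-normal noise (σ = 0.3 log2 units — a convention
chosen to visually match typical replicate scatter of such experiments, not
a measured value), independent per-replicate detection dropout (p = 0.8,
producing the partial replicate-overlap structure of real detection), and
four planted temporal archetypes — fast-up (≥ 2-fold by 5 s), slow-up (by
30 s), down (≤ ½ by 30 s) and transient (up early, relaxed below threshold
by 60 s) — on a regulated fraction of sites (default 0.263 of 700 sites,
which leaves about 138 sites regulated at 60 s because the transient
archetype has relaxed by then).  A fraction of sites also carries a second,
doubly-phosphorylated peptide with attenuated dynamics to exercise the
least-modified collapse.  Everything is deterministic given the config seed.

What passing recovery tests shows: the pipeline implementation is correct
(at σ = 0 recovery of the planted regulated set and partition is exact, and
it remains essentially exact at the default noise), and its sensitivity
degrades monotonically with noise.  What it does not show: performance on
real spectra — the generator has no intensity-dependent missingness, no
site-localization ambiguity, no correlated peptide noise, and its archetypes
are cleaner than biology.

`generate_truth_dataset` simulates any model at known parameters, converts
to relative courses and applies log-normal noise — the ground truth for
parameter-recovery experiments.

## Numerical and degenerate-case conventions

* ε = 0.5 pseudocount for zero baselines in relative courses (both numerator
  and denominator), so knockdown and wild-type courses stay comparable.
* Zero-variance courses z-score to zeros rather than dividing by zero;
  all-identical clustering input is rejected as degenerate.
* Squared distances in fuzzy c-means are floored at 10⁻¹² before the
  membership update.
* Half-rise times are linearly interpolated between grid points and NaN for
  courses that never rise above baseline.
* Null events (rejected overlapping bimolecular pairs) advance the clock
  without transforming the mixture; they are rare in practice and absent
  from all shipped models' common paths.
* Seeds: every stochastic entry point takes an explicit seed; per-run seeds
  are derived additively.

## Problem sizes of the default experiments

Defaults are sized for a laptop-class single core: the network experiments
average 12–16 runs per genotype over a 100 s equilibration plus 60 s
stimulation window; the synthetic table holds 700 sites × 3 replicates; the
recovery fit evaluates a 5×5 grid plus ≤ 120 refinement evaluations of a
60-run objective.  All counts are configurable upward; directional
conclusions were verified stable across independent seed sets at these
sizes.

## Known limitations

* The network is a reconstruction: the site roster and rate table are
  rebuilt from the mechanism narrative, not from the original supplementary
  tables, and copy numbers are scaled down; only directional claims are
  supported.
* One representative ITAM tyrosine per CD3 chain is modeled (CD3E Y188
  explicitly, because the PRS overlap requires it); the full complement of
  TCR ITAM tyrosines, downstream Ras/MAPK/calcium signaling, receptor
  clustering and kinetic proofreading are out of scope.
* The simulator targets models of this family (tens of rules, hundreds of
  molecules); it is a clear, tested reference implementation, not a
  performance-parity engine.
* Enrichment requires user-supplied annotation tables; no ontology is
  bundled.
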