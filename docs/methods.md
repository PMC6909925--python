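# Methods

## Model

`fcmsim` iterates a fuzzy-cognitive-map (FCM) style update on a signed
weighted digraph of biological concepts. States live in [−1, 1]; one step is

    x(t+1) = tanh( g · ( W x(t) + μ x(t) ) ),

followed by clamp enforcement. The update makes three assumptions worth
stating explicitly:

- **Qualitative semantics.** Activations are relative to a cell-type
  baseline, not concentrations: +1 is "strongly on / elevated", −1
  "absent / suppressed", 0 "baseline". Only directions of change are
  interpreted; the expression-calling threshold (≥ 0 ⇒ expressed) encodes
  exactly this.
- **Synchronous discrete time.** All concepts update together; there is no
  continuous-time or stochastic-kinetic semantics, and no learning of
  weights.
- **Clamp supremacy.** A held concept takes its clamp value *after*
  squashing, so a knockout (−1), a fractional inhibition (−f), or a
  continuously present drug/transgene (+1) is exact at every iteration.
  Reprogramming-factor pulses are initial-only: set at t = 0, then released,
  so downstream programs must latch through the network's own feedback.

### Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `memory_coefficient` μ | 0.5 | weight of the self-memory term. μ = 0 makes each state a pure image of its inflow; μ = 1 saturates every driven node near ±0.95 (the map x ↦ tanh(d + x) has its fixed point almost independent of the drive d), which flattens dose–response curves to near-binary outcomes and makes pulse-only nodes decay as ~1/√t. μ = 0.5 preserves a graded relationship between steady state and net input and gives geometric convergence. Exposed in `SimulationConfig`. |
| `squash_gain` g | 1.0 | slope of the squashing function at 0; higher gains push the system toward binary/oscillatory behavior (used in tests to construct limit cycles). |
| `convergence_tol` ε | 1e−4 | max-norm step threshold (states span [−1, 1], so this is 0.005 % of the range). |
| `convergence_window` k | 5 | consecutive sub-ε steps required; guards against declaring convergence inside a slow oscillation. |
| `max_iterations` | 1000 | horizon of the "overtraining" check: after convergence the run may be continued to 1000 iterations, and a fixed point requires the step criterion to hold throughout. The step criterion is used rather than an ε-ball around the converged state because under geometric convergence at rate λ the residual drift after the first sub-ε step is ≈ ελ/(1−λ), which exceeds ε for λ > 0.5 — an ε-ball test would misclassify ordinary convergence. |
| `noise_sigma` | 0.05 | half-width of the uniform jitter applied to unclamped initial values in replicate ensembles (`noise_target="weights"` jitters the non-zero weights instead). Because the default dynamics are contractive around the reached attractor, initial-state jitter often decays below machine precision: replicate SEMs can legitimately be 0. Weight jitter produces persistent between-replicate spread. |
| dead-band δ | 0.05 | |Δmean| below which a genotype comparison is called "unchanged" (5 % of the half-range). |

### Convergence and attractors

Convergence is the first iteration t such that the last k max-norm steps are
all < ε. Attractors are classified on the recorded trajectory: `fixed_point`
if converged and every subsequent step stays < ε; `limit_cycle` if the last
two periods repeat within ε for some smallest period p ≥ 2; otherwise
`non_convergent`. Published iteration counts for the original full-scale
platform depend on an unavailable update rule and convergence criterion and
are therefore logged but never asserted.

## The curated IOPD network

The full-scale knowledge base this package emulates (thousands of concepts,
~8 in/out edges per node, 66 % positive edges) is proprietary. The bundled
fixture is a deliberately small surrogate: 57 concepts, 68 relations,
designed so that the *directions* of the published steady-state calls are
reproduced — not iteration counts, not profile magnitudes, and not network
scale. Every relation carries a provenance note: `anchored:` edges
paraphrase a specific literature statement (e.g. GAA ⊣ lysosomal glycogen,
VDCC → intracellular calcium, glycogen ⊣ phospho-mTORC1); `curated: closure
edge` marks wiring we inferred to close the dynamics (e.g. the
pluripotency/myogenic mutual antagonism, calcium → calpain →
mitochondrial-dysfunction coupling, basal fibroblast GAA expression). Tests
distinguish the two classes.

Design choices inside the fixture:

- **Two latching programs.** A pluripotency hub and a myogenic hub inhibit
  each other; the OSKM pulse decides the winner in reprogramming runs, while
  MyoD1 + doxycycline alone let the myogenic program win in
  transdifferentiation runs. Exogenous MyoD1 (a held transgene) and
  endogenous MyoD1 are distinct concepts, so "transient MyoD1 expression
  without sustained endogenous expression" in pluripotent runs is
  representable.
- **Feed-forward disease axis with one cut-able loop.** GAA loss drives
  glycogen accumulation, glucose deprivation, mTORC1 suppression, VDCC/
  calcium/calpain activation, mitochondrial dysfunction, bioenergetic
  failure, autophagy/mitophagy induction and cell death. The only feedback
  cycle in the axis (calcium → calpain → VDCC → calcium) passes through
  both screening targets, so clamping either VDCC or calpain cuts it —
  fractional inhibition of either target yields monotone, graded
  dose–response in all four readouts.
- **Deliberate absences.** TRA-1-60, Park2, FIS1, OPA1, COX4l1 and
  mitochondrial calcium are not in the network (the emulated platform
  version lacked them); lysosomal calcium is present but disconnected, so
  its "not different from WT" call falls out of the dead-band comparison.
- Weights are ±1 where only the sign is known, with smaller magnitudes for
  curated modulatory edges; no principled weighting scheme exists for the
  original platform, so weights are config-visible data, not code.

## Statistics

- **Bias-adjusted binomial.** The network's positive-edge fraction (0.66)
  is the pretest probability that a prediction is positive. The default
  `uniform` mode gives every feature chance 0.66 — the mode consistent with
  published values of the form 0.66^N — and `poisson_binomial` mode gives
  expected-up features 0.66 and expected-down features 0.34 (exact DP
  convolution). One-sided p is P(X ≥ agreements); two-sided follows the
  method of small likelihoods. No normal approximation anywhere.
- **Exact Mann–Whitney.** Midranks for ties; the permutation null of the
  rank sum is enumerated by dynamic programming over doubled midranks
  (exact for n+m ≤ 40; all counts stay below 2⁵³ so float64 arithmetic is
  exact). The two-sided p sums all outcomes at least as far from nm/2 as
  observed. Larger samples raise with a pointer to asymptotic methods —
  deliberately out of scope.
- **Replicate summaries.** SEM = sd/√n, confidence half-widths from the t
  distribution with n−1 d.f. (99 % by default).

## Biomarker discovery

Candidates are ranked by exact Mann–Whitney p between genotype ensembles
(|Δmean| as tie-break). The classifier is a one-variable logistic
discriminant — the published full-scale analysis evolved a single linear
term, so the hypothesis class is preserved while the evolutionary search
heuristic is not; coefficient magnitudes are dataset-dependent and only the
sign (negative slope for a disease-elevated marker when Normal is the
positive outcome) and the metric behavior are meaningful. Evaluation is
stratified 10-fold cross-validation with pooled held-out predictions;
AUC uses the rank formulation on held-out scores and therefore equals
U/(n₁n₂) from the exact test — a cross-module identity under test.

### Synthetic labeled profiles

`generate_profile_dataset` draws each marker from a class-conditional
Gaussian truncated to [−1, 1]. Defaults: n = 75 with a 36 Normal / 39
disease split (the minimal composition consistent with published
confusion-derived precision/recall for such a dataset — an inference,
configurable); class means mirroring the fixture's steady-state separation
(calpain ≈ −0.90 in WT vs +0.95 in disease, weaker effects for the other
calcium/mitochondrial markers, a null lysosomal-calcium marker); sd 0.25 as
a plausible biological-plus-simulation variability. What the generator does
*not* emulate: inter-marker correlation (markers are drawn independently,
whereas simulated profiles are strongly coupled), heavy tails, batch
structure, or label noise. Recovery and cross-validation results on it
therefore show that the pipeline identifies a planted dominant marker and
that its metrics are internally consistent — not that real expression data
would yield the published operating point.

## Problem sizes

Bundled analyses run at small scale by design: 57-concept network, 3
replicates for profiles (15 per genotype for the separation statistic),
single-replicate noise-free sweeps over the published dose grids, 100
seeded datasets of 30 rows for marker recovery, one 75-row dataset for
cross-validation. The full acceptance run completes in seconds.

## Known limitations

- The exact update rule, squashing function and convergence criterion of
  the emulated platform are unpublished; ours are explicit, config-visible
  choices, and quantities that depend on them (iteration counts, steady-state
  magnitudes such as a specific glycogen level) are not comparable.
- The fixture is sized for directional fidelity; degree statistics of the
  full-scale network are emulated only by the random-network generator.
- Binomial feature counts follow the published suites; where a published
  total mixes directional calls with improvement/no-change findings the
  package recomputes each ingredient rather than asserting the printed
  aggregate.
- No multiple-testing correction is applied (none was in the emulated
  analyses); the exact tests make no asymptotic claims but are limited to
  n+m ≤ 40.
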