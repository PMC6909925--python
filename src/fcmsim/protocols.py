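"""Experiment grammar: reprogramming recipes, knockouts, fractional inhibition,
two-phase treatments, dose-response sweeps, and genotype comparisons.

A :class:`Recipe` is a declarative intervention set: fibroblast context
concepts held on, reprogramming-factor pulses (initial-only +1), transgenes
and drugs held on (+1), and gene deletions held off (-1).  Recipes may be
written in the compact table style used for study models, e.g.::

    Fibroblast + OKSM + Dox + MYOD1 - GAA

where ``OKSM`` expands to the four reprogramming-factor pulses and a leading
``-`` marks a deletion.  Therapeutic interventions are fractional: a target
"variably locked off" at -f for an inhibition fraction f in [0, 1], either
from the start of the run or after the disease phenotype has reached steady
state (two-phase treatment).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import (
    ClampSpec,
    SimulationConfig,
    SteadyStateProfile,
    run_replicates,
    run_simulation,
)
from .network import ConceptNetwork
from .stats import exact_mann_whitney

__all__ = [
    "Recipe",
    "TreatmentSpec",
    "DoseResponseResult",
    "make_recipe",
    "standard_recipes",
    "apply_knockout",
    "apply_fractional_inhibition",
    "run_two_phase_treatment",
    "dose_response_sweep",
    "compare_genotypes",
    "DEFAULT_READOUTS",
    "DEFAULT_PHENOTYPE_SET",
]

#: Default therapeutic readouts for dose-response screens.
DEFAULT_READOUTS = ("intracellular_calcium", "ROS", "mitochondrial_dysfunction", "cell_death")

#: Concepts whose positive activation defines an established disease phenotype.
DEFAULT_PHENOTYPE_SET = (
    "lysosomal_glycogen",
    "intracellular_calcium",
    "mitochondrial_dysfunction",
    "cell_death",
)

#: The four reprogramming-factor pulse concepts behind the OKSM/OSKM token.
OSKM_FACTORS = ("OCT4_exo", "SOX2_exo", "KLF4", "cMYC")

SCHEDULE_FROM_START = "from_start"
SCHEDULE_TWO_PHASE = "after_disease_steady_state"


class RecipeError(ValueError):
    """Malformed or contradictory intervention specifications."""


@dataclass(frozen=True)
class Recipe:
    name: str
    base_context: tuple[str, ...] = ()
    factors: tuple[ClampSpec, ...] = ()
    deletions: tuple[str, ...] = ()
    treatments: tuple[ClampSpec, ...] = ()
    label: str = "WT"

    def __post_init__(self):
        factor_ids = {c.concept.lower() for c in self.factors} | {c.lower() for c in self.base_context}
        overlap = factor_ids & {d.lower() for d in self.deletions}
        if overlap:
            raise RecipeError(f"deletions overlap factor concepts: {sorted(overlap)}")

    def clamps(self) -> list[ClampSpec]:
        out = [ClampSpec(c, "hold", 1.0) for c in self.base_context]
        out.extend(self.factors)
        out.extend(ClampSpec(d, "hold", -1.0) for d in self.deletions)
        out.extend(self.treatments)
        return out

    def intervention_signature(self):
        """Clamp set as a canonical frozenset - recipes with equal signatures
        drive identical simulations regardless of name/label."""
        return frozenset(
            (c.concept.lower(), c.mode, c.value, c.active_from) for c in self.clamps()
        )


@dataclass(frozen=True)
class TreatmentSpec:
    """Fractional inhibition: the target is held at -f."""

    target: str
    inhibition_fraction: float
    schedule: str = SCHEDULE_TWO_PHASE

    def __post_init__(self):
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise RecipeError(
                f"inhibition_fraction {self.inhibition_fraction} outside [0, 1]"
            )
        if self.schedule not in (SCHEDULE_FROM_START, SCHEDULE_TWO_PHASE):
            raise RecipeError(f"unknown schedule {self.schedule!r}")


@dataclass
class DoseResponseResult:
    """Terminal readout means per inhibition fraction, plus phenotype flags."""

    target: str
    fractions: list[float]
    readout_means: pd.DataFrame   # index: fraction, columns: readouts
    readout_sems: pd.DataFrame
    phenotype_established: dict[float, bool]
    schedule: str

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for f in self.fractions:
            for r in self.readout_means.columns:
                rows.append({
                    "fraction": f,
                    "readout": r,
                    "mean": self.readout_means.loc[f, r],
                    "sem": self.readout_sems.loc[f, r],
                    "phenotype_established": self.phenotype_established[f],
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recipe construction
# ---------------------------------------------------------------------------

_TOKEN_SPLIT = re.compile(r"\s*([+–−-])\s*")


def _tokenize(recipe_string: str):
    """Yield (op, token) pairs, op in {'+', '-'}; the first token defaults to '+'."""
    parts = _TOKEN_SPLIT.split(recipe_string.strip())
    op = "+"
    expecting_token = True
    for part in parts:
        if not part:
            continue
        if part in "+-–−":
            op = "+" if part == "+" else "-"
            expecting_token = True
        else:
            yield op, part.strip()
            op = "+"
    if expecting_token and not parts:
        raise RecipeError("empty recipe string")


def make_recipe(
    declaration,
    net: ConceptNetwork,
    name: str | None = None,
    label: str | None = None,
) -> Recipe:
    """Build a recipe from a table-style declaration.

    ``declaration`` is either the recipe string itself or a mapping with keys
    ``recipe`` (the string), ``name`` and ``label``.  Token semantics:
    ``Fibroblast`` joins the held-on base context, ``OKSM``/``OSKM`` expands
    to the four reprogramming-factor pulses (initial-only +1), ``Dox`` and
    ``MYOD1`` (the exogenous transgene) become hold clamps at +1, and a
    ``-``-prefixed token is a deletion (hold at -1).  All referenced concepts
    must exist in the target network.
    """
    if isinstance(declaration, str):
        recipe_string = declaration
    else:
        decl = dict(declaration)
        recipe_string = decl["recipe"]
        name = name or decl.get("name")
        label = label or decl.get("label")

    context: list[str] = []
    factors: list[ClampSpec] = []
    deletions: list[str] = []
    for op, token in _tokenize(recipe_string):
        low = token.lower()
        if op == "-":
            deletions.append(net.resolve(token))
        elif low == "fibroblast":
            context.append(net.resolve(token))
        elif low in ("oksm", "oskm"):
            for f in OSKM_FACTORS:
                factors.append(ClampSpec(net.resolve(f), "initial_only", 1.0))
        elif low in ("myod1", "myod1_exo"):
            factors.append(ClampSpec(net.resolve("MYOD1_exo"), "hold", 1.0))
        else:
            factors.append(ClampSpec(net.resolve(token), "hold", 1.0))

    if label is None:
        label = "disease" if deletions else "WT"
    return Recipe(
        name=name or recipe_string,
        base_context=tuple(context),
        factors=tuple(factors),
        deletions=tuple(deletions),
        label=label,
    )


#: Table-style declarations of the four evaluated study models.
STANDARD_MODELS = {
    "aiPSC_WT": {"recipe": "Fibroblast + OKSM + Dox + MYOD1", "label": "WT"},
    "aiPSC_IOPD": {"recipe": "Fibroblast + OKSM + Dox + MYOD1 - GAA", "label": "disease"},
    "aiSkMC_WT": {"recipe": "Fibroblast + MYOD1 + Dox", "label": "WT"},
    "aiSkMC_IOPD": {"recipe": "Fibroblast + MYOD1 + Dox - GAA", "label": "disease"},
}


def standard_recipes(net: ConceptNetwork) -> dict[str, Recipe]:
    """The four study models: pluripotent and skeletal-muscle, WT and disease."""
    return {
        name: make_recipe(decl, net, name=name) for name, decl in STANDARD_MODELS.items()
    }


def apply_knockout(recipe: Recipe, concept: str, name: str | None = None) -> Recipe:
    """Add a gene deletion (hold at -1); idempotent.

    Knocking out a concept the recipe holds positively is contradictory and
    raises.
    """
    low = concept.lower()
    if low in {d.lower() for d in recipe.deletions}:
        return recipe
    positive = {c.lower() for c in recipe.base_context}
    positive |= {c.concept.lower() for c in recipe.factors if c.value > 0 and c.mode == "hold"}
    if low in positive:
        raise RecipeError(f"cannot knock out {concept!r}: held on by the recipe")
    return replace(
        recipe,
        name=name or f"{recipe.name} - {concept}",
        deletions=recipe.deletions + (concept,),
        label="disease",
    )


def apply_fractional_inhibition(recipe: Recipe, treatment: TreatmentSpec) -> Recipe:
    """Add a hold clamp at -f for the treatment target.

    f = 1 is a full knockout (identical trajectories); f = 0 silences the
    target to neutral, which is *not* "no treatment" - dose grids use an
    explicit no-treatment sentinel for their baseline point instead.
    """
    low = treatment.target.lower()
    value = -treatment.inhibition_fraction
    positive = {c.lower() for c in recipe.base_context}
    positive |= {c.concept.lower() for c in recipe.factors if c.value > 0 and c.mode == "hold"}
    if low in positive:
        raise RecipeError(f"cannot inhibit {treatment.target!r}: held on by the recipe")
    for c in recipe.treatments:
        if c.concept.lower() == low:
            if c.value == value:
                return recipe
            raise RecipeError(f"conflicting clamp for {treatment.target!r}")
    return replace(
        recipe,
        treatments=recipe.treatments + (ClampSpec(treatment.target, "hold", value),),
    )


# ---------------------------------------------------------------------------
# treatment protocols
# ---------------------------------------------------------------------------

def _phase_clamps(recipe: Recipe, keep_pulses: bool) -> list[ClampSpec]:
    clamps = recipe.clamps()
    if keep_pulses:
        return clamps
    return [c for c in clamps if c.mode == "hold"]


def run_two_phase_treatment(
    net: ConceptNetwork,
    disease_recipe: Recipe,
    treatment: TreatmentSpec,
    config: SimulationConfig | None = None,
    n_replicates: int = 3,
) -> tuple[SteadyStateProfile, SteadyStateProfile]:
    """Disease first, then treat: phase 1 runs the disease recipe to steady
    state; phase 2 continues from that state with the treatment clamp added.

    Factor pulses are not re-applied in phase 2 (the cell is already
    reprogrammed); hold clamps persist.  A non-convergent phase 1 is an
    error.
    """
    if treatment.schedule != SCHEDULE_TWO_PHASE:
        raise RecipeError(
            "run_two_phase_treatment requires schedule 'after_disease_steady_state'"
        )
    config = config or SimulationConfig()
    treated = apply_fractional_inhibition(disease_recipe, treatment)
    phase2_clamps = _phase_clamps(treated, keep_pulses=False)

    terms1, terms2, bad1, bad2, it1, it2 = [], [], [], [], [], []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        t1 = run_simulation(net, disease_recipe.clamps(), config, rng=rng)
        if not t1.converged:
            raise RuntimeError(
                f"phase 1 (disease establishment) did not converge in replicate {r}: "
                f"attractor={t1.attractor_class}, period={t1.cycle_period}"
            )
        t2 = run_simulation(net, phase2_clamps, config, x0=t1.terminal)
        terms1.append(t1.terminal)
        terms2.append(t2.terminal)
        it1.append(t1.iterations_to_convergence)
        it2.append(t2.iterations_to_convergence)
        if not t2.converged:
            bad2.append(r)
    mk = lambda terms, bad, its: SteadyStateProfile(
        concept_ids=net.concept_ids,
        terminal_values=np.array(terms),
        n_replicates=n_replicates,
        non_convergent_replicates=bad,
        iterations=its,
        network=net,
    )
    return mk(terms1, bad1, it1), mk(terms2, bad2, it2)


def _phenotype_established_from_start(traj, net, phenotype_set, dead_band) -> bool:
    idx = [net.index_of(c) for c in phenotype_set]
    return bool(np.all(traj.states[:, idx].max(axis=0) > dead_band))


def dose_response_sweep(
    net: ConceptNetwork,
    disease_recipe: Recipe,
    target: str,
    grid,
    readouts=DEFAULT_READOUTS,
    config: SimulationConfig | None = None,
    schedule: str = SCHEDULE_TWO_PHASE,
    n_replicates: int = 3,
    phenotype_set=DEFAULT_PHENOTYPE_SET,
    dead_band: float = 0.05,
) -> DoseResponseResult:
    """One treatment run per inhibition fraction in ``grid``.

    The f = 0 grid point is the explicit no-treatment baseline (no clamp at
    all).  ``phenotype_established`` records whether the disease phenotype
    concepts all activated: at phase-1 steady state for the two-phase
    schedule, or at any pre-reversal iteration when treating from the start.
    """
    grid = sorted(float(f) for f in grid)
    if not grid:
        raise RecipeError("dose grid must be non-empty")
    if any(f < 0 or f > 1 for f in grid):
        raise RecipeError("grid fractions must lie in [0, 1]")
    if not readouts:
        raise RecipeError("readout set must be non-empty")
    config = config or SimulationConfig()
    readout_ids = [net.resolve(r) for r in readouts]
    target_id = net.resolve(target)

    means, sems, established = {}, {}, {}
    for f in grid:
        if schedule == SCHEDULE_TWO_PHASE:
            if f == 0.0:
                profile = run_replicates(net, disease_recipe.clamps(), config, n_replicates)
                if not profile.all_converged:
                    raise RuntimeError("untreated disease run did not converge")
                phase2 = profile
                established[f] = all(
                    profile.value(c) > dead_band for c in phenotype_set
                )
            else:
                treatment = TreatmentSpec(target_id, f, SCHEDULE_TWO_PHASE)
                phase1, phase2 = run_two_phase_treatment(
                    net, disease_recipe, treatment, config, n_replicates
                )
                established[f] = all(
                    phase1.value(c) > dead_band for c in phenotype_set
                )
        elif schedule == SCHEDULE_FROM_START:
            recipe = (
                disease_recipe if f == 0.0
                else apply_fractional_inhibition(
                    disease_recipe, TreatmentSpec(target_id, f, SCHEDULE_FROM_START)
                )
            )
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
            traj = run_simulation(net, recipe.clamps(), config, rng=rng,
                                  stop_on_convergence=True)
            established[f] = _phenotype_established_from_start(
                traj, net, phenotype_set, dead_band
            )
            phase2 = run_replicates(net, recipe.clamps(), config, n_replicates)
        else:
            raise RecipeError(f"unknown schedule {schedule!r}")
        means[f] = [phase2.value(r) for r in readout_ids]
        sems[f] = [
            float(phase2.sem[phase2.concept_ids.index(r)]) for r in readout_ids
        ]

    mean_df = pd.DataFrame.from_dict(means, orient="index", columns=list(readout_ids)).sort_index()
    sem_df = pd.DataFrame.from_dict(sems, orient="index", columns=list(readout_ids)).sort_index()
    return DoseResponseResult(
        target=target_id,
        fractions=grid,
        readout_means=mean_df,
        readout_sems=sem_df,
        phenotype_established=established,
        schedule=schedule,
    )


def compare_genotypes(
    profile_wt: SteadyStateProfile,
    profile_disease: SteadyStateProfile,
    dead_band: float = 0.05,
    with_test: bool = True,
) -> pd.DataFrame:
    """Per-concept disease-minus-WT comparison.

    ``direction`` is up/down/unchanged with a dead-band on the mean
    difference; when both profiles carry replicate ensembles small enough for
    exact enumeration, the exact Mann-Whitney U and two-sided p per concept
    are included (NaN otherwise).
    """
    if profile_wt.concept_ids != profile_disease.concept_ids:
        raise ValueError("profiles cover different concept universes")
    rows = []
    n, m = profile_wt.n_replicates, profile_disease.n_replicates
    feasible = with_test and n >= 2 and m >= 2 and n + m <= 40
    for i, concept in enumerate(profile_wt.concept_ids):
        delta = float(profile_disease.mean[i] - profile_wt.mean[i])
        if delta > dead_band:
            direction = "up"
        elif delta < -dead_band:
            direction = "down"
        else:
            direction = "unchanged"
        u = p = float("nan")
        if feasible:
            u, p = exact_mann_whitney(
                profile_disease.terminal_values[:, i], profile_wt.terminal_values[:, i]
            )
        rows.append({
            "concept": concept,
            "mean_wt": float(profile_wt.mean[i]),
            "mean_disease": float(profile_disease.mean[i]),
            "delta": delta,
            "direction": direction,
            "u": u,
            "p": p,
        })
    return pd.DataFrame(rows)
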