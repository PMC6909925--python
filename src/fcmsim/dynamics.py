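"""Iterated squashed-map dynamics on signed concept networks.

The state vector x(t) holds one activation in [-1, 1] per concept.  One
iteration computes

    x(t+1) = tanh( gain * ( W @ x(t) + mu * x(t) ) )

where ``W[i, j]`` is the weight of the relation j -> i and ``mu`` is a
self-memory coefficient, after which *hold* clamps overwrite their entries
exactly (modelling gene deletion at -1, fractional pharmacological
inhibition at -f, or a transgene/drug held at +1).  *Initial-only* clamps
(reprogramming-factor pulses) set entries at t = 0 and then release them.

Convergence is declared when the max-norm step stays below ``convergence_tol``
for ``convergence_window`` consecutive iterations; an "overtraining" check
continues iterating to ``max_iterations`` and verifies no oscillation or
divergence re-emerges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .network import ConceptNetwork
from .stats import replicate_summary

__all__ = [
    "ClampSpec",
    "SimulationConfig",
    "StateTrajectory",
    "SteadyStateProfile",
    "squash",
    "step",
    "run_simulation",
    "assess_convergence",
    "classify_attractor",
    "run_replicates",
]

FIXED_POINT = "fixed_point"
LIMIT_CYCLE = "limit_cycle"
NON_CONVERGENT = "non_convergent"


@dataclass(frozen=True)
class ClampSpec:
    """An intervention on one concept.

    mode ``initial_only``: set the entry to ``value`` at t = 0, then release
    (a transcription-factor pulse that is "turned on" but not locked).
    mode ``hold``: overwrite the entry with ``value`` at every iteration
    >= ``active_from`` ("locked off/on").
    """

    concept: str
    mode: str
    value: float
    active_from: int = 0

    def __post_init__(self):
        if self.mode not in ("initial_only", "hold"):
            raise ValueError(f"unknown clamp mode {self.mode!r}")
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"clamp value {self.value} outside [-1, 1]")
        if self.active_from < 0:
            raise ValueError("active_from must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of the update rule and the replicate protocol.

    ``memory_coefficient`` (mu) weights the self-memory term: 0 makes each
    state a pure squashed image of its inflow, 1 full persistence.  The
    default 0.5 yields graded steady states and geometric convergence.
    ``noise_sigma`` is the half-width of the uniform jitter applied to the
    initial values of unclamped concepts in replicate ensembles
    (``noise_target='weights'`` jitters non-zero weights instead).
    """

    max_iterations: int = 1000
    convergence_tol: float = 1e-4
    convergence_window: int = 5
    memory_coefficient: float = 0.5
    squash_gain: float = 1.0
    noise_sigma: float = 0.05
    noise_target: str = "initial_state"
    seed: int = 0

    def __post_init__(self):
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.convergence_window < 1:
            raise ValueError("convergence_window must be >= 1")
        if self.max_iterations < self.convergence_window:
            raise ValueError("max_iterations must be >= convergence_window")
        if not 0.0 <= self.memory_coefficient <= 1.0:
            raise ValueError("memory_coefficient must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_target not in ("initial_state", "weights"):
            raise ValueError("noise_target must be 'initial_state' or 'weights'")

    @classmethod
    def from_mapping(cls, mapping) -> "SimulationConfig":
        return cls(**{k: v for k, v in dict(mapping or {}).items()})

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data.get("simulation", data))


@dataclass
class StateTrajectory:
    """Recorded states plus convergence/attractor metadata."""

    states: np.ndarray            # (T+1, N); row 0 is the initial state
    concept_ids: list[str]
    converged: bool = False
    iterations_to_convergence: int | None = None
    attractor_class: str = NON_CONVERGENT
    cycle_period: int | None = None

    @property
    def terminal(self) -> np.ndarray:
        return self.states[-1]

    @property
    def n_iterations(self) -> int:
        return self.states.shape[0] - 1

    def series(self, concept: str) -> np.ndarray:
        return self.states[:, self.concept_ids.index(concept)]

    def as_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.concept_ids)
        df.insert(0, "iteration", np.arange(self.states.shape[0]))
        return df


@dataclass
class SteadyStateProfile:
    """Terminal concept values across replicates with dispersion summaries."""

    concept_ids: list[str]
    terminal_values: np.ndarray   # (n_replicates, N)
    n_replicates: int
    ci_level: float = 0.99
    non_convergent_replicates: list[int] = field(default_factory=list)
    iterations: list[int | None] = field(default_factory=list)
    network: ConceptNetwork | None = None

    def __post_init__(self):
        self.terminal_values = np.atleast_2d(np.asarray(self.terminal_values, dtype=float))
        self.mean = self.terminal_values.mean(axis=0)
        if self.n_replicates >= 2:
            sd = self.terminal_values.std(axis=0, ddof=1)
            sd[np.ptp(self.terminal_values, axis=0) == 0] = 0.0  # exact ties
            self.sem = sd / np.sqrt(self.n_replicates)
            from scipy.stats import t as _t

            self.ci_half = _t.ppf(0.5 + self.ci_level / 2, self.n_replicates - 1) * self.sem
        else:
            self.sem = np.zeros_like(self.mean)
            self.ci_half = np.zeros_like(self.mean)

    @property
    def all_converged(self) -> bool:
        return not self.non_convergent_replicates

    def resolve(self, name: str) -> str | None:
        if name in self.concept_ids:
            return name
        if self.network is not None and name in self.network:
            cid = self.network.resolve(name)
            if cid in self.concept_ids:
                return cid
        return None

    def value(self, concept: str) -> float:
        cid = self.resolve(concept)
        if cid is None:
            raise KeyError(f"unknown concept {concept!r}")
        return float(self.mean[self.concept_ids.index(cid)])

    def values_by_concept(self) -> dict[str, float]:
        return dict(zip(self.concept_ids, map(float, self.mean)))

    def replicate_values(self, concept: str) -> np.ndarray:
        cid = self.resolve(concept)
        if cid is None:
            raise KeyError(f"unknown concept {concept!r}")
        return self.terminal_values[:, self.concept_ids.index(cid)]

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "concept": self.concept_ids,
            "mean": self.mean,
            "sem": self.sem,
            "ci99_low": self.mean - self.ci_half,
            "ci99_high": self.mean + self.ci_half,
        })


# ---------------------------------------------------------------------------
# core update
# ---------------------------------------------------------------------------

def squash(v, gain: float = 1.0):
    """Odd, strictly increasing squashing into (-1, 1); squash(0) = 0."""
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("squash requires finite input")
    out = np.tanh(gain * arr)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def _resolve_clamps(net: ConceptNetwork, clamps) -> list[tuple[int, ClampSpec]]:
    out = []
    for c in clamps:
        idx = net.index_of(c.concept)  # raises for unknown concepts
        out.append((idx, c))
    return out


def step(x, net: ConceptNetwork, clamps=(), config: SimulationConfig | None = None, t: int = 0):
    """One deterministic iteration; hold clamps overwrite after squashing."""
    config = config or SimulationConfig()
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_concepts,):
        raise ValueError(f"state dimension {x.shape} does not match {net.n_concepts} concepts")
    W = net.weight_matrix()
    resolved = _resolve_clamps(net, clamps)
    return _step(x, W, resolved, config, t)


def _step(x, W, resolved_clamps, config, t):
    new = np.tanh(config.squash_gain * (W @ x + config.memory_coefficient * x))
    for idx, c in resolved_clamps:
        if c.mode == "hold" and t + 1 >= c.active_from:
            new[idx] = c.value
    return new


def run_simulation(
    net: ConceptNetwork,
    clamps=(),
    config: SimulationConfig | None = None,
    x0=None,
    stop_on_convergence: bool = True,
    rng: np.random.Generator | None = None,
) -> StateTrajectory:
    """Iterate from an all-zero state (or ``x0``) under the given clamps.

    Initial-only clamps set their entries at t = 0; hold clamps are enforced
    from their ``active_from`` iteration on.  When ``rng`` is given and
    ``config.noise_sigma > 0`` the unclamped initial entries (or the weights,
    per ``config.noise_target``) receive uniform jitter - the replicate noise
    model.  With ``stop_on_convergence`` the run ends once the convergence
    window is satisfied, otherwise it continues to ``max_iterations`` so the
    attractor (and any late oscillation) can be classified.
    """
    config = config or SimulationConfig()
    n = net.n_concepts
    W = net.weight_matrix()
    resolved = _resolve_clamps(net, clamps)

    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
    if x.shape != (n,):
        raise ValueError("x0 dimension mismatch")
    clamped_idx = {idx for idx, _ in resolved}
    if rng is not None and config.noise_sigma > 0:
        if config.noise_target == "initial_state":
            jitter = rng.uniform(-config.noise_sigma, config.noise_sigma, size=n)
            free = np.array([i not in clamped_idx for i in range(n)])
            x = np.clip(x + jitter * free, -1.0, 1.0)
        else:  # weights
            mask = W != 0
            W = np.clip(W + rng.uniform(-config.noise_sigma, config.noise_sigma, size=W.shape) * mask, -1.0, 1.0)
    for idx, c in resolved:
        if c.mode == "initial_only" or (c.mode == "hold" and c.active_from == 0):
            x[idx] = c.value

    states = [x.copy()]
    eps, k = config.convergence_tol, config.convergence_window
    run_of_small_steps = 0
    converged_at = None
    for t in range(config.max_iterations):
        x = _step(x, W, resolved, config, t)
        states.append(x.copy())
        if np.max(np.abs(states[-1] - states[-2])) < eps:
            run_of_small_steps += 1
        else:
            run_of_small_steps = 0
        if converged_at is None and run_of_small_steps >= k:
            converged_at = t + 1
            if stop_on_convergence:
                break

    traj = StateTrajectory(
        states=np.array(states),
        concept_ids=net.concept_ids,
        converged=converged_at is not None,
        iterations_to_convergence=converged_at,
    )
    traj.attractor_class, traj.cycle_period = classify_attractor(traj, eps)
    return traj


def assess_convergence(traj, eps: float, k: int) -> tuple[bool, int | None]:
    """First iteration t at which the last ``k`` max-norm steps are all < eps."""
    states = traj.states if hasattr(traj, "states") else np.asarray(traj, dtype=float)
    if states.ndim == 1:
        states = states[:, None]
    if states.shape[0] == 0:
        raise ValueError("empty trajectory")
    diffs = np.max(np.abs(np.diff(states, axis=0)), axis=1)
    run = 0
    for t, d in enumerate(diffs, start=1):
        run = run + 1 if d < eps else 0
        if run >= k:
            return True, t
    return False, None


def classify_attractor(traj, eps: float) -> tuple[str, int | None]:
    """Classify terminal behavior as fixed point, limit cycle, or neither.

    A fixed point requires the max-norm step to stay below ``eps`` from the
    first convergence window through the end of the recorded trajectory (the
    overtraining check: no oscillation or divergence re-emerges).  A limit
    cycle is the smallest period p >= 2 such that the last two periods of
    the trajectory repeat within ``eps``.
    """
    states = traj.states if hasattr(traj, "states") else np.asarray(traj, dtype=float)
    if states.ndim == 1:
        states = states[:, None]
    T = states.shape[0] - 1
    if T < 1:
        return NON_CONVERGENT, None
    diffs = np.max(np.abs(np.diff(states, axis=0)), axis=1)
    conv = getattr(traj, "converged", None)
    it = getattr(traj, "iterations_to_convergence", None)
    if conv is None or it is None:
        window = min(5, T)
        conv, it = assess_convergence(states, eps, window)
    if conv and np.all(diffs[it - 1:] < eps):
        return FIXED_POINT, None
    for p in range(2, T // 2 + 1):
        tail = states[-p:]
        prev = states[-2 * p:-p]
        if np.max(np.abs(tail - prev)) < eps:
            return LIMIT_CYCLE, p
    return NON_CONVERGENT, None


def run_replicates(
    net: ConceptNetwork,
    clamps=(),
    config: SimulationConfig | None = None,
    n_replicates: int = 3,
    x0=None,
    stop_on_convergence: bool = True,
) -> SteadyStateProfile:
    """Replicate ensemble: per-replicate seed derived from (config.seed, r).

    Non-convergent replicates are flagged in the profile, never dropped.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    config = config or SimulationConfig()
    terminals, bad, iters = [], [], []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        traj = run_simulation(
            net, clamps, config, x0=x0, stop_on_convergence=stop_on_convergence, rng=rng
        )
        terminals.append(traj.terminal)
        iters.append(traj.iterations_to_convergence)
        if not traj.converged:
            bad.append(r)
    return SteadyStateProfile(
        concept_ids=net.concept_ids,
        terminal_values=np.array(terminals),
        n_replicates=n_replicates,
        non_convergent_replicates=bad,
        iterations=iters,
        network=net,
    )


def summarize_concept(profile: SteadyStateProfile, concept: str, level: float = 0.99):
    """(mean, SEM, CI half-width) of one concept across replicates."""
    return replicate_summary(profile.replicate_values(concept), level=level)
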