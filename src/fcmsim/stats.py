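"""Expression calling and validation statistics.

Terminal concept activations in [-1, 1] are thresholded at zero into
expressed/upregulated versus repressed/absent calls.  Agreement of those
calls with a literature expectation profile is scored by a *bias-adjusted*
binomial test: the network's pretest probability of predicting a positive
outcome (the fraction of positive relations, 0.66 in the emulated platform)
replaces the naive 0.5 chance-success probability.  Two null models are
provided:

``uniform``
    every feature succeeds by chance with probability ``p0`` - the mode that
    reproduces published p-values of the form ``p0**N`` for all-correct
    all-up profiles;
``poisson_binomial``
    expected-up features succeed with probability ``p0`` and expected-down
    features with ``1 - p0`` (exact Poisson-binomial null for mixed profiles).

Group comparisons use an exact Mann-Whitney U test computed by full
enumeration of the permutation null (midranks for ties), not a normal
approximation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionCall",
    "LiteratureProfile",
    "ValidationResult",
    "call_expression",
    "biased_binomial_test",
    "validate_profile",
    "exact_mann_whitney",
    "replicate_summary",
]

EXPRESSED = "expressed_up"
REPRESSED = "repressed_absent"

_DIRECTION_SYNONYMS = {
    "up": "up", "present": "up", "up/present": "up", "expressed": "up",
    "down": "down", "absent": "down", "down/absent": "down", "repressed": "down",
    "unchanged": "unchanged", "no_change": "unchanged",
}


@dataclass(frozen=True)
class ExpressionCall:
    concept: str
    value: float
    call: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "call", EXPRESSED if self.value >= 0 else REPRESSED)


@dataclass(frozen=True)
class LiteratureProfile:
    """Expected direction per concept, with a provenance note per entry."""

    entries: tuple[tuple[str, str, str], ...]  # (concept, expected, provenance)
    name: str = ""

    def __post_init__(self):
        seen = set()
        norm = []
        for concept, expected, prov in self.entries:
            key = expected.strip().lower()
            if key not in _DIRECTION_SYNONYMS:
                raise ValueError(f"unknown expected direction {expected!r} for {concept!r}")
            if concept in seen:
                raise ValueError(f"duplicate concept {concept!r} in profile")
            seen.add(concept)
            norm.append((concept, _DIRECTION_SYNONYMS[key], prov))
        object.__setattr__(self, "entries", tuple(norm))

    @property
    def n(self) -> int:
        """Feature count entering the binomial test (directional entries only)."""
        return sum(1 for _, e, _ in self.entries if e != "unchanged")

    @property
    def directional(self) -> tuple[tuple[str, str, str], ...]:
        return tuple(e for e in self.entries if e[1] != "unchanged")

    @classmethod
    def from_csv(cls, path, name: str = "") -> "LiteratureProfile":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if rows and rows[0][0].lower() == "concept":
            rows = rows[1:]
        entries = tuple(
            (r[0].strip(), r[1].strip(), (r[2].strip() if len(r) > 2 else ""))
            for r in rows if r and r[0].strip()
        )
        return cls(entries=entries, name=name)


@dataclass(frozen=True)
class ValidationResult:
    N: int
    agreements: int
    pretest_positive: float
    p_one_sided: float
    p_two_sided: float
    mode: str
    table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "N": self.N,
            "agreements": self.agreements,
            "pretest_positive": self.pretest_positive,
            "p_one_sided": self.p_one_sided,
            "p_two_sided": self.p_two_sided,
            "mode": self.mode,
        }
        if self.table is not None:
            out["features"] = self.table.to_dict(orient="records")
        return out


def call_expression(profile) -> list[ExpressionCall]:
    """Threshold terminal values at zero (>= 0 means expressed/upregulated).

    Accepts a ``SteadyStateProfile``, a mapping concept -> value, or an
    iterable of (concept, value) pairs.
    """
    if hasattr(profile, "values_by_concept"):
        items = list(profile.values_by_concept().items())
    elif hasattr(profile, "items"):
        items = list(profile.items())
    else:
        items = list(profile)
    if not items:
        raise ValueError("cannot call expression on an empty profile")
    return [ExpressionCall(concept=str(c), value=float(v)) for c, v in items]


def _null_pmf(N: int, probs) -> np.ndarray:
    """Exact pmf of the number of chance agreements (Poisson-binomial DP)."""
    pmf = np.zeros(N + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= 1 - p
    return pmf


def biased_binomial_test(
    agreements: int,
    N: int,
    expected_directions: LiteratureProfile | None = None,
    p0_positive: float = 0.66,
    mode: str = "uniform",
) -> ValidationResult:
    """Exact bias-adjusted binomial test of prediction/literature agreement.

    ``p_one_sided`` is P(X >= agreements) under the chance null;
    ``p_two_sided`` follows the method of small likelihoods (sum of all
    outcome probabilities no larger than that of the observed count).  No
    normal approximation is used.
    """
    if not 0 < p0_positive < 1:
        raise ValueError("p0_positive must lie strictly between 0 and 1")
    if N < 1:
        raise ValueError("N must be at least 1")
    if not 0 <= agreements <= N:
        raise ValueError(f"agreements {agreements} outside [0, {N}]")
    if mode == "uniform":
        probs = np.full(N, p0_positive)
    elif mode == "poisson_binomial":
        if expected_directions is None:
            raise ValueError("poisson_binomial mode requires an expectation profile")
        directional = expected_directions.directional
        if len(directional) != N:
            raise ValueError(
                f"profile has {len(directional)} directional features, N={N}"
            )
        probs = np.array(
            [p0_positive if e == "up" else 1 - p0_positive for _, e, _ in directional]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pmf = _null_pmf(N, probs)
    p_one = float(pmf[agreements:].sum())
    cutoff = pmf[agreements] * (1 + 1e-12)
    p_two = float(pmf[pmf <= cutoff].sum())
    return ValidationResult(
        N=N,
        agreements=agreements,
        pretest_positive=p0_positive,
        p_one_sided=min(p_one, 1.0),
        p_two_sided=min(max(p_two, p_one), 1.0),
        mode=mode,
    )


def validate_profile(
    profile,
    literature: LiteratureProfile,
    p0_positive: float = 0.66,
    mode: str = "uniform",
) -> ValidationResult:
    """Score a steady-state profile against a literature expectation profile.

    Directional entries (up/down) are compared with the zero-threshold calls;
    ``unchanged`` entries are carried in the per-feature table but excluded
    from the binomial count, which matches how genotype-comparison dead-bands
    are assessed separately.
    """
    values = profile.values_by_concept() if hasattr(profile, "values_by_concept") else dict(profile)
    resolve = getattr(profile, "resolve", None)
    rows = []
    agreements = 0
    for concept, expected, prov in literature.entries:
        key = concept if concept in values else None
        if key is None and resolve is not None:
            key = resolve(concept)
        if key is None or key not in values:
            raise KeyError(f"concept {concept!r} absent from the profile under validation")
        value = float(values[key])
        call = EXPRESSED if value >= 0 else REPRESSED
        if expected == "unchanged":
            agree = None
        else:
            agree = (expected == "up") == (call == EXPRESSED)
            agreements += int(agree)
        rows.append({
            "concept": concept, "expected": expected, "value": value,
            "call": call, "agree": agree, "provenance": prov,
        })
    table = pd.DataFrame(rows)
    base = biased_binomial_test(
        agreements, literature.n, expected_directions=literature,
        p0_positive=p0_positive, mode=mode,
    )
    return ValidationResult(
        N=base.N, agreements=base.agreements, pretest_positive=base.pretest_positive,
        p_one_sided=base.p_one_sided, p_two_sided=base.p_two_sided, mode=base.mode,
        table=table,
    )


def exact_mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by full permutation enumeration.

    Midranks are used for ties and the null distribution of the rank sum is
    enumerated by dynamic programming over the tied pooled ranks, so the
    p-value is exact in the presence of ties.  Returns ``(U_a, p_two_sided)``
    where ``U_a`` counts pairs won by ``sample_a`` (ties count 1/2).
    Complete separation of equal groups of size n gives p = 2 / C(2n, n).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    N = n + m
    if N > 40:
        raise ValueError(
            f"exact enumeration supported for n+m <= 40 (got {N}); "
            "use an asymptotic test for larger samples"
        )
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)          # midranks
    r2 = np.rint(2 * ranks).astype(int)   # doubled midranks are integers
    ra2 = int(r2[:n].sum())
    u_obs = ra2 / 2 - n * (n + 1) / 2

    # counts[j, s] = number of j-subsets of the pooled doubled-ranks with sum s
    total = r2.sum()
    counts = np.zeros((n + 1, total + 1))
    counts[0, 0] = 1.0
    for r in r2:
        counts[1:, r:] += counts[:-1, :-r or None].copy()
    dist = counts[n]                      # over doubled rank sums; total C(N, n)
    n_subsets = comb(N, n)

    s = np.nonzero(dist)[0]
    u_vals = s / 2 - n * (n + 1) / 2
    center = n * m / 2
    d_obs = abs(u_obs - center)
    extreme = np.abs(u_vals - center) >= d_obs - 1e-9
    p = float(dist[s][extreme].sum() / n_subsets)
    return float(u_obs), min(p, 1.0)


def replicate_summary(values, level: float = 0.99):
    """Mean, SEM and t-based confidence half-width across replicate values.

    With a single value the dispersion terms are ``None``.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    mean = float(v.mean())
    if v.size < 2:
        return mean, None, None
    sem = 0.0 if np.ptp(v) == 0 else float(v.std(ddof=1) / sqrt(v.size))
    half = float(sps.t.ppf(0.5 + level / 2, v.size - 1) * sem)
    return mean, sem, half
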