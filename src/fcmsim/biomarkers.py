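"""Single-marker biomarker discovery with cross-validated evaluation.

Candidate markers are ranked by genotype separation (exact Mann-Whitney p,
mean difference as tie-break).  The classifier is deliberately minimal - a
one-variable logistic discriminant whose linear score ``a*x + b`` predicts
the Normal/WT class when non-negative - evaluated by stratified ten-fold
cross-validation with pooled held-out predictions.  AUC is computed from the
held-out scores by the rank (Mann-Whitney) formulation, so it coincides with
U/(n1*n2) from the exact test on the same scores.

A seeded generator of labeled synthetic expression profiles (truncated
Gaussians per class in [-1, 1]) supports parameter-recovery experiments; its
default effect sizes mirror the steady-state separation the curated disease
network produces for the calcium-axis concepts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, truncnorm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .stats import exact_mann_whitney

__all__ = [
    "ProfileDataset",
    "LinearDiscriminant",
    "CVMetrics",
    "DEFAULT_MARKER_EFFECTS",
    "generate_profile_dataset",
    "rank_candidate_biomarkers",
    "fit_linear_discriminant",
    "crossvalidate",
    "rank_auc",
]

NORMAL = "WT"
DISEASE = "IOPD"

#: (mean_wt, mean_disease, sd) per marker; means echo the curated network's
#: steady states (calpain strongly separated, lysosomal calcium null).
DEFAULT_MARKER_EFFECTS = {
    "calpain": (-0.90, 0.95, 0.25),
    "intracellular_calcium": (-0.60, 0.60, 0.25),
    "VDCC": (-0.55, 0.55, 0.25),
    "mitochondrial_dysfunction": (-0.55, 0.55, 0.25),
    "ROS": (-0.50, 0.50, 0.25),
    "cell_death": (-0.45, 0.45, 0.25),
    "ATP": (0.45, -0.45, 0.25),
    "lysosomal_calcium": (0.0, 0.0, 0.25),
}


@dataclass
class ProfileDataset:
    """Labeled expression profiles: values in [-1, 1], label WT or IOPD."""

    frame: pd.DataFrame  # columns: markers + 'label'

    def __post_init__(self):
        if "label" not in self.frame.columns:
            raise ValueError("dataset frame requires a 'label' column")

    @property
    def markers(self) -> list[str]:
        return [c for c in self.frame.columns if c != "label"]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    def values(self, marker: str) -> np.ndarray:
        return self.frame[marker].to_numpy()

    def split(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        """(WT values, disease values) for one marker."""
        v = self.frame[marker]
        return (
            v[self.labels == NORMAL].to_numpy(),
            v[self.labels == DISEASE].to_numpy(),
        )


@dataclass(frozen=True)
class LinearDiscriminant:
    """Predict Normal/WT iff a*x + b >= 0."""

    marker: str
    slope: float
    intercept: float

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("a fitted discriminant requires a non-zero slope")

    def score(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def predict(self, x) -> np.ndarray:
        return np.where(self.score(x) >= 0, NORMAL, DISEASE)


@dataclass(frozen=True)
class CVMetrics:
    precision: float
    recall: float
    f_measure: float
    auc: float
    folds: int
    fold_confusions: tuple[tuple[int, int, int, int], ...]  # (tp, fp, fn, tn)
    held_out_scores: tuple[float, ...] = ()
    held_out_labels: tuple[int, ...] = ()  # 1 = Normal/WT

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "folds": self.folds,
        }


def generate_profile_dataset(
    n_rows: int = 75,
    class_fractions: tuple[float, float] = (36 / 75, 39 / 75),
    marker_effects: dict | None = None,
    seed: int = 0,
) -> ProfileDataset:
    """Seeded synthetic dataset of WT and disease profiles.

    Each marker is drawn from a class-specific Gaussian truncated to
    [-1, 1].  ``class_fractions`` is (WT fraction, disease fraction); the
    default 36:39 split at n = 75 is the minimal composition consistent with
    published confusion-derived precision/recall for such a dataset.
    """
    if n_rows < 4:
        raise ValueError("need at least 4 rows")
    if abs(sum(class_fractions) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    effects = dict(marker_effects or DEFAULT_MARKER_EFFECTS)
    for marker, (mu_wt, mu_d, sd) in effects.items():
        if sd < 0:
            raise ValueError(f"negative sd for marker {marker!r}")
    n_wt = int(round(n_rows * class_fractions[0]))
    n_wt = min(max(n_wt, 1), n_rows - 1)
    n_disease = n_rows - n_wt
    rng = np.random.default_rng(seed)

    def draw(mu, sd, size):
        if sd == 0:
            return np.full(size, float(np.clip(mu, -1, 1)))
        a, b = (-1 - mu) / sd, (1 - mu) / sd
        return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)

    cols = {}
    for marker, (mu_wt, mu_d, sd) in effects.items():
        cols[marker] = np.concatenate([draw(mu_wt, sd, n_wt), draw(mu_d, sd, n_disease)])
    frame = pd.DataFrame(cols)
    frame["label"] = [NORMAL] * n_wt + [DISEASE] * n_disease
    return ProfileDataset(frame=frame)


def rank_candidate_biomarkers(
    wt_ensemble: pd.DataFrame,
    disease_ensemble: pd.DataFrame,
    candidate_set,
    alpha_flag: float = 1e-4,
) -> pd.DataFrame:
    """Rank candidates by exact Mann-Whitney p (mean difference as tie-break).

    The ensembles are replicate-by-concept tables (e.g. terminal states of
    independent simulation runs).  Rows are sorted by ascending p, then by
    descending |delta|; ``significant`` flags p below ``alpha_flag``.
    """
    candidates = list(candidate_set)
    if not candidates:
        raise ValueError("candidate set is empty")
    for c in candidates:
        if c not in wt_ensemble.columns or c not in disease_ensemble.columns:
            raise KeyError(f"candidate {c!r} absent from the profile ensembles")
    rows = []
    for c in candidates:
        a = disease_ensemble[c].to_numpy(dtype=float)
        b = wt_ensemble[c].to_numpy(dtype=float)
        u, p = exact_mann_whitney(a, b)
        delta = float(a.mean() - b.mean())
        rows.append({"concept": c, "delta_mean": delta, "u": u, "p": p,
                     "significant": p < alpha_flag})
    df = pd.DataFrame(rows)
    df["abs_delta"] = df["delta_mean"].abs()
    df = (
        df.sort_values(["p", "abs_delta", "concept"], ascending=[True, False, True])
        .drop(columns="abs_delta")
        .reset_index(drop=True)
    )
    return df


def fit_linear_discriminant(data: ProfileDataset, marker: str) -> LinearDiscriminant:
    """One-variable logistic discriminant; Normal/WT is the positive outcome.

    When the disease class carries the higher marker values the fitted slope
    is negative.
    """
    x = data.values(marker)
    y = (data.labels == NORMAL).to_numpy(dtype=int)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to fit")
    if np.ptp(x) == 0:
        raise ValueError(f"marker {marker!r} is constant")
    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=10_000)
    clf.fit(x.reshape(-1, 1), y)
    return LinearDiscriminant(
        marker=marker, slope=float(clf.coef_[0, 0]), intercept=float(clf.intercept_[0])
    )


def rank_auc(scores_positive, scores_negative) -> float:
    """AUC by the rank (Mann-Whitney) formulation with midranks for ties."""
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def crossvalidate(
    data: ProfileDataset, marker: str, folds: int = 10, seed: int = 0
) -> CVMetrics:
    """Stratified k-fold cross-validation of the single-marker discriminant.

    Precision/recall/F are pooled over held-out predictions with Normal/WT as
    the positive class; AUC uses the pooled held-out linear scores.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > data.n_rows:
        raise ValueError("more folds than rows")
    x = data.values(marker)
    y = (data.labels == NORMAL).to_numpy(dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    score = np.empty(len(y), dtype=float)
    confusions = []
    for train, test in skf.split(x.reshape(-1, 1), y):
        sub = ProfileDataset(frame=data.frame.iloc[train].reset_index(drop=True))
        model = fit_linear_discriminant(sub, marker)
        s = model.score(x[test])
        score[test] = s
        pred[test] = (s >= 0).astype(int)
        tp = int(np.sum((pred[test] == 1) & (y[test] == 1)))
        fp = int(np.sum((pred[test] == 1) & (y[test] == 0)))
        fn = int(np.sum((pred[test] == 0) & (y[test] == 1)))
        tn = int(np.sum((pred[test] == 0) & (y[test] == 0)))
        confusions.append((tp, fp, fn, tn))
    tp = sum(c[0] for c in confusions)
    fp = sum(c[1] for c in confusions)
    fn = sum(c[2] for c in confusions)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    auc = rank_auc(score[y == 1], score[y == 0])
    return CVMetrics(
        precision=precision, recall=recall, f_measure=f, auc=auc,
        folds=folds, fold_confusions=tuple(confusions),
        held_out_scores=tuple(map(float, score)), held_out_labels=tuple(map(int, y)),
    )
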