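"""Condition-stratified phenotype profiling and cross-condition aggregation.

The interphenotype pipeline fixes one microenvironment condition at a
time (a *condition level*: a pH value, a perfusion state, a hydrogel
class, or a gelatin/alginate content level — 12 levels in total), pools
both cell lines' records at that level, and then:

1. clusters the 16 markers (z-scored, no environment variables) with
   k-means at K = 2 and scores the split by silhouette;
2. compares the unsupervised split to the true cell-line labels via an
   accuracy-maximizing cluster-to-label alignment (confusion matrix,
   invasive = positive class);
3. ranks markers by mutual information with the true labels and retains
   those scoring strictly above tau;
4. re-clusters on the retained markers and re-evaluates silhouette and
   confusion, validating that the reduced panel separates phenotypes.

Per-level results are aggregated across all levels into a combined
feature-importance table (sum of MI scores, plus retention counts).

The intraphenotype analysis instead asks, within a single cell line,
how many distinct microenvironment-driven behaviors the markers support,
selecting the cluster count by the least-drop silhouette rule.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering_core import (
    KMeansResult,
    backward_eliminate,
    kmeans,
    select_num_clusters,
    silhouette,
    standardize,
)
from .data_model_io import (
    CELL_LINES,
    DYNAMIC,
    HYDROGEL_CLASSES,
    INVASIVE,
    MARKER_NAMES,
    STATIC,
    MarkerTable,
    Microenvironment,
    build_condition_grid,
)
from .feature_importance import DEFAULT_TAU, FeatureRanking, rank_features


@dataclass(frozen=True)
class ConditionLevel:
    """One fixed microenvironment condition, e.g. pH = 6.5 or hydrogel = St-H."""

    variable: str  # pH | perfusion | hydrogel | gelatin_content | alginate_content
    level: str | float

    @property
    def name(self) -> str:
        return f"{self.variable}={self.level}"


def condition_levels() -> list[ConditionLevel]:
    """The full stratification set, in fixed order (12 levels)."""
    return [
        ConditionLevel("pH", 7.4),
        ConditionLevel("pH", 6.5),
        ConditionLevel("perfusion", STATIC),
        ConditionLevel("perfusion", DYNAMIC),
        *[ConditionLevel("hydrogel", h) for h in HYDROGEL_CLASSES],
        ConditionLevel("gelatin_content", "low"),
        ConditionLevel("gelatin_content", "high"),
        ConditionLevel("alginate_content", "low"),
        ConditionLevel("alginate_content", "high"),
    ]


def environments_at_level(level: ConditionLevel) -> list[Microenvironment]:
    """Environments of the 12-condition grid belonging to a level."""
    grid = build_condition_grid()
    if level.variable == "pH":
        return [e for e in grid if e.pH == level.level]
    if level.variable == "perfusion":
        return [e for e in grid if e.perfusion == level.level]
    if level.variable == "hydrogel":
        return [e for e in grid if e.hydrogel_class == level.level]
    if level.variable == "gelatin_content":
        want = 1.0 if level.level == "low" else 3.0
        return [e for e in grid if e.gelatin == want]
    if level.variable == "alginate_content":
        want = 1.5 if level.level == "low" else 3.0
        return [e for e in grid if e.alginate == want]
    raise ValueError(f"unknown stratification variable {level.variable!r}")


def derive_seed(master_seed: int, *parts: str) -> int:
    """Stable stage seed from the master seed and stage/level names.

    CRC-32 of the joined identifier keeps every derived seed below 2^31
    and independent of Python's per-process hash randomization; adding
    stages never perturbs existing ones.
    """
    key = ":".join([str(master_seed), *parts]).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


@dataclass
class ConfusionMatrix2x2:
    """Counts after cluster-to-label alignment; invasive = positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def errors(self) -> int:
        return self.fp + self.fn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


def align_clusters(
    assignments: np.ndarray, truth: np.ndarray
) -> tuple[dict[int, int], ConfusionMatrix2x2]:
    """Map two unsupervised clusters onto the two true classes.

    Both possible cluster-to-class mappings are evaluated and the one
    maximizing accuracy is returned (identity preferred on a tie), along
    with the confusion matrix under that mapping.  By construction the
    aligned accuracy is >= 0.5.
    """
    assignments = np.asarray(assignments)
    truth = np.asarray(truth)
    if set(np.unique(assignments)) - {0, 1} or set(np.unique(truth)) - {0, 1}:
        raise ValueError("assignments and truth must be binary (0/1)")
    if len(np.unique(truth)) < 2:
        raise ValueError("both true classes must be present")
    identity_acc = float(np.mean(assignments == truth))
    swap_acc = float(np.mean((1 - assignments) == truth))
    if identity_acc >= swap_acc:
        mapping = {0: 0, 1: 1}
        pred = assignments
    else:
        mapping = {0: 1, 1: 0}
        pred = 1 - assignments
    cm = ConfusionMatrix2x2(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
    )
    return mapping, cm


@dataclass
class ConditionProfile:
    level: ConditionLevel
    n_records: int
    silhouette_pre: float
    confusion_pre: ConfusionMatrix2x2
    ranking: FeatureRanking
    silhouette_post: float | None
    confusion_post: ConfusionMatrix2x2 | None
    no_features: bool = False


def profile_condition(
    table: MarkerTable,
    level: ConditionLevel,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
    estimator: str = "knn",
    restarts: int = 20,
) -> ConditionProfile:
    """Run the four-stage interphenotype pipeline at one condition level.

    The feature matrix holds the 16 markers only — the remaining
    microenvironment variables are deliberately excluded even though the
    level's subset still varies in them.  If no marker clears tau the
    profile is returned with the ``no_features`` flag instead of a
    post-reduction stage.
    """
    env_ids = {e.env_id for e in environments_at_level(level)}
    mask = np.array([r.env_id in env_ids for r in table.records])
    if not mask.any():
        raise ValueError(f"no records at level {level.name}")
    sub = table.subset(mask)
    labels = sub.labels()
    for cls, lab in ((INVASIVE, 1), (CELL_LINES[1], 0)):
        if np.sum(labels == lab) < 2:
            raise ValueError(
                f"level {level.name}: need >= 2 records of cell line {cls!r}"
            )
    X = sub.marker_matrix()
    Xz = standardize(X)

    pre = kmeans(Xz, 2, seed=derive_seed(seed, "pre", level.name), restarts=restarts)
    sil_pre = silhouette(Xz, pre.assignments).global_score
    _, cm_pre = align_clusters(pre.assignments, labels)

    ranking = rank_features(
        X,
        labels,
        list(table.marker_names),
        estimator=estimator,
        tau=tau,
        seed=derive_seed(seed, "mi", level.name),
    )

    if ranking.empty_retained:
        return ConditionProfile(
            level=level,
            n_records=len(sub),
            silhouette_pre=sil_pre,
            confusion_pre=cm_pre,
            ranking=ranking,
            silhouette_post=None,
            confusion_post=None,
            no_features=True,
        )

    keep = [list(table.marker_names).index(m) for m in ranking.retained]
    Xr = standardize(X[:, keep])
    post = kmeans(Xr, 2, seed=derive_seed(seed, "post", level.name), restarts=restarts)
    sil_post = silhouette(Xr, post.assignments).global_score
    _, cm_post = align_clusters(post.assignments, labels)
    return ConditionProfile(
        level=level,
        n_records=len(sub),
        silhouette_pre=sil_pre,
        confusion_pre=cm_pre,
        ranking=ranking,
        silhouette_post=sil_post,
        confusion_post=cm_post,
    )


def run_all_conditions(
    table: MarkerTable,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
    estimator: str = "knn",
    restarts: int = 20,
) -> list[ConditionProfile]:
    """Profile every condition level (12 profiles, fixed order).

    Each level consumes an independent seed derived from the master seed
    and the level name, so levels can be reproduced in isolation.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    profiles = []
    for level in condition_levels():
        try:
            profiles.append(
                profile_condition(
                    table, level, tau=tau, seed=seed, estimator=estimator,
                    restarts=restarts,
                )
            )
        except ValueError as exc:
            raise ValueError(f"profiling failed at level {level.name}: {exc}") from exc
    return profiles


@dataclass
class AggregateImportance:
    combined_score: dict[str, float]
    mean_score: dict[str, float]
    times_retained: dict[str, int]
    order: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.order,
                "combined_score": [self.combined_score[m] for m in self.order],
                "mean_score": [self.mean_score[m] for m in self.order],
                "times_retained": [self.times_retained[m] for m in self.order],
            }
        )


def aggregate_importance(profiles: Sequence[ConditionProfile]) -> AggregateImportance:
    """Combine per-level rankings into an overall importance table.

    The headline combined score is the SUM of a marker's MI scores over
    all levels; the mean score and the number of levels where the marker
    cleared the retention threshold are reported alongside so either
    convention can be recovered.  Order is descending combined score,
    ties by canonical marker index.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    markers = list(MARKER_NAMES)
    # fsum: exactly-rounded sums keep aggregation invariant to profile order
    combined = {
        m: math.fsum(p.ranking.scores[m] for p in profiles) for m in markers
    }
    mean = {m: combined[m] / len(profiles) for m in markers}
    times = {m: sum(m in p.ranking.retained for p in profiles) for m in markers}
    order = sorted(markers, key=lambda m: (-combined[m], markers.index(m)))
    return AggregateImportance(
        combined_score=combined, mean_score=mean, times_retained=times, order=order
    )


@dataclass
class IntraphenotypeResult:
    cell_line: str
    k_star: int
    scores: dict[int, float]
    clustering: KMeansResult
    retained_features: list[str]
    low_confidence: bool
    assignments_frame: pd.DataFrame = field(repr=False, default=None)


def intraphenotype_behaviors(
    table: MarkerTable,
    cell_line: str,
    k_max: int = 6,
    epsilon: float = 0.01,
    seed: int = 0,
    eliminate_features: bool = False,
    restarts: int = 20,
    confidence_floor: float = 0.25,
) -> IntraphenotypeResult:
    """Count microenvironment-driven behaviors within one cell line.

    Restricts the table to the cell line across all environments,
    z-scores the markers, selects the cluster count by the least-drop
    rule, and optionally prunes features by greedy silhouette-guided
    elimination at the chosen k.  If even the best silhouette stays below
    ``confidence_floor`` the separation is flagged low-confidence (a flat
    silhouette profile means the minimal-k rule, not structure, chose k).
    """
    mask = np.array([r.cell_line == cell_line for r in table.records])
    sub = table.subset(mask)
    if len(sub) <= k_max:
        raise ValueError(f"need more than k_max={k_max} records of {cell_line!r}")
    names = list(table.marker_names)
    X = standardize(sub.marker_matrix())
    k_star, scores = select_num_clusters(
        X, k_max=k_max, epsilon=epsilon,
        seed=derive_seed(seed, "select", cell_line), restarts=restarts,
    )
    retained = names
    if eliminate_features:
        retained, _ = backward_eliminate(
            X, names, k_star, seed=derive_seed(seed, "eliminate", cell_line),
            restarts=restarts,
        )
        X = X[:, [names.index(m) for m in retained]]
    result = kmeans(
        X, k_star, seed=derive_seed(seed, "final", cell_line), restarts=restarts
    )
    env_by_id = {e.env_id: e for e in build_condition_grid()}
    frame = pd.DataFrame(
        {
            "env_id": sub.env_ids(),
            "hydrogel": [env_by_id[i].hydrogel_class for i in sub.env_ids()],
            "pH": [env_by_id[i].pH for i in sub.env_ids()],
            "perfusion": [env_by_id[i].perfusion for i in sub.env_ids()],
            "replicate": [r.replicate for r in sub.records],
            "cluster": result.assignments,
        }
    )
    return IntraphenotypeResult(
        cell_line=cell_line,
        k_star=k_star,
        scores=scores,
        clustering=result,
        retained_features=list(retained),
        low_confidence=max(scores.values()) < confidence_floor,
        assignments_frame=frame,
    )
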