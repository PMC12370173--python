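"""Run configuration, report assembly and serialization.

A full profiling run produces one JSON report documenting every stage —
per-cell-line correlation matrices, per-cell-line intraphenotype
clustering, the 12 condition profiles, and the aggregated importance
table — plus tidy CSV exports per stage.  Every artifact embeds the
master seed and a hash of the configuration, so re-running with the same
config reproduces all numeric outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation_stats import correlation_matrix
from .data_model_io import CELL_LINES, MarkerTable, normalize_proliferation
from .feature_importance import DEFAULT_TAU
from .profiling_pipeline import (
    AggregateImportance,
    ConditionProfile,
    IntraphenotypeResult,
    aggregate_importance,
    derive_seed,
    intraphenotype_behaviors,
    run_all_conditions,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a profiling run depends on; exactly one input source."""

    input_path: str | None = None
    synthetic_config_path: str | None = None
    seed: int = 0
    tau: float = DEFAULT_TAU
    k_max: int = 6
    epsilon: float = 0.01
    estimator: str = "knn"
    estimator_params: dict = field(default_factory=dict)
    restarts: int = 20
    normalize_proliferation: bool = False
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic_config_path is None):
            raise ValueError(
                "exactly one of input_path / synthetic_config_path must be set"
            )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _ranking_dict(profile: ConditionProfile) -> dict:
    return {
        "level": profile.level.name,
        "n_records": profile.n_records,
        "silhouette_pre": profile.silhouette_pre,
        "confusion_pre": profile.confusion_pre.as_dict(),
        "scores": profile.ranking.scores,
        "retained": profile.ranking.retained,
        "no_features": profile.no_features,
        "silhouette_post": profile.silhouette_post,
        "confusion_post": (
            profile.confusion_post.as_dict() if profile.confusion_post else None
        ),
    }


def _intra_dict(res: IntraphenotypeResult) -> dict:
    return {
        "cell_line": res.cell_line,
        "k_star": res.k_star,
        "silhouette_by_k": {str(k): v for k, v in res.scores.items()},
        "low_confidence": res.low_confidence,
        "retained_features": res.retained_features,
    }


def run_report(table: MarkerTable, config: RunConfig) -> dict:
    """Execute the full pipeline and return the report document."""
    if config.normalize_proliferation:
        table = normalize_proliferation(table)
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_records": len(table),
    }
    t0 = time.time()
    corr = {}
    for line in CELL_LINES:
        m = correlation_matrix(table, line)
        corr[line] = {
            "labels": m.labels,
            "values": np.where(np.isnan(m.values), None, m.values).tolist(),
        }
        logger.info("correlation matrix (%s): %d labels", line, len(m.labels))
    report["correlation"] = corr

    intra = {}
    for line in CELL_LINES:
        res = intraphenotype_behaviors(
            table,
            line,
            k_max=config.k_max,
            epsilon=config.epsilon,
            seed=derive_seed(config.seed, "intraphenotype"),
            restarts=config.restarts,
        )
        intra[line] = _intra_dict(res)
        logger.info(
            "intraphenotype (%s): k*=%d silhouette=%.3f%s",
            line, res.k_star, res.scores[res.k_star],
            " [low confidence]" if res.low_confidence else "",
        )
    report["intraphenotype"] = intra

    profiles = run_all_conditions(
        table,
        tau=config.tau,
        seed=derive_seed(config.seed, "conditions"),
        estimator=config.estimator,
        restarts=config.restarts,
    )
    for p in profiles:
        logger.info(
            "level %-22s n=%2d retained=%2d errors pre=%d post=%s",
            p.level.name, p.n_records, len(p.ranking.retained),
            p.confusion_pre.errors,
            p.confusion_post.errors if p.confusion_post else "n/a",
        )
    report["profiles"] = [_ranking_dict(p) for p in profiles]
    report["aggregate"] = _aggregate_dict(aggregate_importance(profiles))
    # wall time is logged, not embedded: reports must be byte-reproducible
    logger.info("full pipeline in %.2fs", time.time() - t0)
    return report


def _aggregate_dict(agg: AggregateImportance) -> dict:
    return {
        "order": agg.order,
        "combined_score": agg.combined_score,
        "mean_score": agg.mean_score,
        "times_retained": agg.times_retained,
    }


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the JSON report plus tidy CSVs; returns the report path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))

    rows = []
    for p in report["profiles"]:
        for marker, score in p["scores"].items():
            rows.append(
                {
                    "level": p["level"],
                    "marker": marker,
                    "score": score,
                    "retained": marker in p["retained"],
                }
            )
    pd.DataFrame(rows).to_csv(out / "feature_scores.csv", index=False)

    agg = report["aggregate"]
    pd.DataFrame(
        {
            "marker": agg["order"],
            "combined_score": [agg["combined_score"][m] for m in agg["order"]],
            "mean_score": [agg["mean_score"][m] for m in agg["order"]],
            "times_retained": [agg["times_retained"][m] for m in agg["order"]],
        }
    ).to_csv(out / "aggregate_importance.csv", index=False)

    for line, m in report["correlation"].items():
        pd.DataFrame(m["values"], index=m["labels"], columns=m["labels"]).to_csv(
            out / f"correlation_{line}.csv"
        )
    return report_path
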