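"""Pearson correlation maps between markers and environment features.

For each cell line separately, the sample Pearson coefficient is
computed between every pair of markers and between each marker and each
numeric microenvironment feature (stiffness, gelatin, alginate, pH,
perfusion), giving a (16 + 5) x (16 + 5) correlation map.  Zero-variance
columns yield mathematically undefined coefficients; these are surfaced
as an explicit NaN sentinel (and logged) rather than silently coerced
to 0, since "no linear relation" and "no variation" are different
statements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model_io import (
    ENV_FEATURE_NAMES,
    MarkerTable,
    build_condition_grid,
    encode_environment,
)

logger = logging.getLogger(__name__)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation coefficient.

    Computed as the centered cross-product over the product of centered
    norms; lies in [-1, 1].  Zero-variance input is an error — the
    coefficient is undefined, not zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.clip((ac * bc).sum() / denom, -1.0, 1.0))


@dataclass
class CorrelationMatrix:
    """Symmetric correlation map over markers + environment features."""

    labels: list[str]
    values: np.ndarray  # (n+m) x (n+m); NaN marks undefined entries
    cell_line: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    def lookup(self, row: str, col: str) -> float:
        return float(self.values[self.labels.index(row), self.labels.index(col)])


def correlation_matrix(
    table: MarkerTable,
    cell_line: str,
    encoding_scheme: str = "numeric_default",
) -> CorrelationMatrix:
    """Marker-marker and marker-environment correlation map for one cell line.

    Environment feature vectors are expanded per record from the numeric
    encoding of that record's microenvironment, so each record carries a
    (16 + 5)-dimensional joint observation.  Constant columns produce NaN
    rows/columns (diagonal kept at 1).
    """
    mask = np.array([r.cell_line == cell_line for r in table.records])
    if mask.sum() < 2:
        raise ValueError(f"need at least 2 records of cell line {cell_line!r}")
    sub = table.subset(mask)
    if len(np.unique(sub.env_ids())) < 2:
        raise ValueError("records must span at least 2 environments")
    env_by_id = {e.env_id: e for e in build_condition_grid()}
    U = np.array(
        [encode_environment(env_by_id[r.env_id], encoding_scheme) for r in sub.records]
    )
    joint = np.hstack([sub.marker_matrix(), U])
    labels = list(table.marker_names) + list(ENV_FEATURE_NAMES)
    p = joint.shape[1]
    values = np.eye(p)
    constant = joint.std(axis=0) == 0
    for name, is_const in zip(labels, constant):
        if is_const:
            logger.warning(
                "column %r is constant for cell line %s: correlations undefined",
                name,
                cell_line,
            )
    for i in range(p):
        for j in range(i + 1, p):
            if constant[i] or constant[j]:
                values[i, j] = values[j, i] = np.nan
            else:
                values[i, j] = values[j, i] = pearson(joint[:, i], joint[:, j])
    return CorrelationMatrix(labels=labels, values=values, cell_line=cell_line)
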