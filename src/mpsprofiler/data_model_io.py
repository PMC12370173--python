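"""Dataset schema, condition grid, environment encoding and CSV I/O.

The experimental design crosses two human breast-cancer cell lines
(invasive MDA-MB-231-like vs non-invasive MCF-7-like) with 12
microphysiological-system (MPS) microenvironments: four alginate/gelatin
hydrogel classes (soft/stiff x low/high gelatin), each cultured at
pH 7.4 static, pH 6.5 static, and pH 7.4 dynamic (perfused).  For every
(cell line, environment, replicate) combination a fixed panel of 16
marker readouts is recorded: four proliferation time points, eight
cancer-stem-cell markers (CD44/CD24/CD44v6/ALDH as MFI or %-positive),
and four epithelial-mesenchymal-transition markers (Vimentin and
E-cadherin, MFI and %-positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INVASIVE = "invasive"  # MDA-MB-231-like
NONINVASIVE = "noninvasive"  # MCF-7-like
CELL_LINES = (INVASIVE, NONINVASIVE)

HYDROGEL_CLASSES = ("So-L", "So-H", "St-L", "St-H")

#: Mean Young's modulus (kPa) per hydrogel class.
YOUNG_MODULUS_KPA = {"So-L": 1.8, "So-H": 2.4, "St-L": 6.1, "St-H": 10.1}
#: Alginate content (% w/v): soft gels 1.5, stiff gels 3.
ALGINATE_PCT = {"So-L": 1.5, "So-H": 1.5, "St-L": 3.0, "St-H": 3.0}
#: Gelatin content (% w/v): low 1, high 3.
GELATIN_PCT = {"So-L": 1.0, "So-H": 3.0, "St-L": 1.0, "St-H": 3.0}

STATIC = "static"
DYNAMIC = "dynamic"

#: The fixed 16-marker panel, in canonical column order.
MARKER_NAMES: tuple[str, ...] = (
    "Proliferation day1",
    "Proliferation day4",
    "Proliferation day7",
    "Proliferation day14",
    "CD44 MFI",
    "CD24 MFI",
    "CD44v6 MFI",
    "CD44+%",
    "CD24+%",
    "CD44+/CD24-%",
    "CD44v6+%",
    "ALDH+%",
    "Vimentin MFI",
    "E-cadherin MFI",
    "Vimentin+%",
    "E-cadherin+%",
)

PROLIFERATION_MARKERS = MARKER_NAMES[:4]
#: Markers reported as median fluorescence intensity (strictly positive scale).
MFI_MARKERS = ("CD44 MFI", "CD24 MFI", "CD44v6 MFI", "Vimentin MFI", "E-cadherin MFI")
#: Markers reported as percent-positive cells (bounded to [0, 100]).
PERCENT_MARKERS = (
    "CD44+%",
    "CD24+%",
    "CD44+/CD24-%",
    "CD44v6+%",
    "ALDH+%",
    "Vimentin+%",
    "E-cadherin+%",
)

META_COLUMNS = ("cell_line", "env_id", "replicate")


@dataclass(frozen=True)
class Microenvironment:
    """One of the 12 MPS culture conditions.

    Attributes
    ----------
    env_id : int
        1-based index in the canonical grid order.
    hydrogel_class : str
        One of ``So-L``, ``So-H``, ``St-L``, ``St-H``.
    young_modulus : float
        Mean Young's modulus of the hydrogel, kPa.
    alginate, gelatin : float
        Matrix composition, % w/v.
    pH : float
        Buffered extracellular pH of the medium (7.4 healthy / 6.5 tumoral).
    perfusion : str
        ``static`` or ``dynamic`` (bioreactor interstitial flow).
    """

    env_id: int
    hydrogel_class: str
    young_modulus: float
    alginate: float
    gelatin: float
    pH: float
    perfusion: str

    def __post_init__(self) -> None:
        if self.hydrogel_class not in HYDROGEL_CLASSES:
            raise ValueError(f"unknown hydrogel class {self.hydrogel_class!r}")
        if self.pH == 6.5 and self.perfusion == DYNAMIC:
            raise ValueError("pH 6.5 with dynamic perfusion is not part of the design")


def build_condition_grid() -> list[Microenvironment]:
    """Return the canonical 12-environment grid.

    For each hydrogel class (So-L, So-H, St-L, St-H) three culture
    conditions are produced in order: pH 7.4 static, pH 6.5 static,
    pH 7.4 dynamic.  The function is pure and deterministic.
    """
    grid: list[Microenvironment] = []
    env_id = 1
    for gel in HYDROGEL_CLASSES:
        for pH, perfusion in ((7.4, STATIC), (6.5, STATIC), (7.4, DYNAMIC)):
            grid.append(
                Microenvironment(
                    env_id=env_id,
                    hydrogel_class=gel,
                    young_modulus=YOUNG_MODULUS_KPA[gel],
                    alginate=ALGINATE_PCT[gel],
                    gelatin=GELATIN_PCT[gel],
                    pH=pH,
                    perfusion=perfusion,
                )
            )
            env_id += 1
    return grid


#: Names of the numeric environment features produced by :func:`encode_environment`.
ENV_FEATURE_NAMES: tuple[str, ...] = (
    "stiffness kPa",
    "gelatin %",
    "alginate %",
    "pH",
    "perfusion",
)


def encode_environment(env: Microenvironment, scheme: str = "numeric_default") -> np.ndarray:
    """Encode a microenvironment as a numeric feature vector.

    Under ``numeric_default`` the vector is
    ``(Young's modulus kPa, gelatin % w/v, alginate % w/v, pH, perfusion 0/1)``.
    Stiffness enters as the mean modulus in kPa rather than a soft/stiff
    binary; note alginate is collinear with stiffness in this design
    (soft gels 1.5%, stiff gels 3%).
    """
    if scheme != "numeric_default":
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    return np.array(
        [
            env.young_modulus,
            env.gelatin,
            env.alginate,
            env.pH,
            0.0 if env.perfusion == STATIC else 1.0,
        ]
    )


@dataclass(frozen=True)
class MarkerRecord:
    """A single profiled sample: one cell line in one environment, one replicate."""

    cell_line: str
    env_id: int
    replicate: int
    markers: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise ValueError(f"unknown cell line {self.cell_line!r}")
        if len(self.markers) != len(MARKER_NAMES):
            raise ValueError(
                f"expected {len(MARKER_NAMES)} marker values, got {len(self.markers)}"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass
class MarkerTable:
    """Wide marker table: one row per (cell line, environment, replicate).

    All records share the marker ordering of :data:`MARKER_NAMES`; ``meta``
    carries free-form provenance (source file, generator seed/config).
    """

    records: list[MarkerRecord]
    marker_names: tuple[str, ...] = MARKER_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.marker_names) != MARKER_NAMES:
            raise ValueError("marker_names must match the canonical 16-marker panel")
        valid_ids = {e.env_id for e in build_condition_grid()}
        for rec in self.records:
            if rec.env_id not in valid_ids:
                raise ValueError(f"record references unknown env_id {rec.env_id}")

    def __len__(self) -> int:
        return len(self.records)

    # -- convenience views -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with metadata columns followed by marker columns."""
        rows = [
            {
                "cell_line": r.cell_line,
                "env_id": r.env_id,
                "replicate": r.replicate,
                **dict(zip(self.marker_names, r.markers)),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(self.marker_names))

    def marker_matrix(self) -> np.ndarray:
        """N x 16 float matrix of the marker values."""
        return np.array([r.markers for r in self.records], dtype=float)

    def labels(self) -> np.ndarray:
        """Binary phenotype labels: 1 = invasive, 0 = non-invasive."""
        return np.array([1 if r.cell_line == INVASIVE else 0 for r in self.records])

    def env_ids(self) -> np.ndarray:
        return np.array([r.env_id for r in self.records])

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "MarkerTable":
        recs = [r for r, keep in zip(self.records, mask) if keep]
        return MarkerTable(records=recs, marker_names=self.marker_names, meta=dict(self.meta))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: Mapping | None = None) -> "MarkerTable":
        records = [
            MarkerRecord(
                cell_line=str(row["cell_line"]),
                env_id=int(row["env_id"]),
                replicate=int(row["replicate"]),
                markers=tuple(float(row[m]) for m in MARKER_NAMES),
            )
            for _, row in df.iterrows()
        ]
        return cls(records=records, meta=dict(meta or {}))


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


def read_marker_table(path: str | Path, schema_check: bool = True) -> MarkerTable:
    """Read a wide marker CSV into a :class:`MarkerTable`.

    The file must carry the three metadata columns (cell_line, env_id,
    replicate) and all 16 marker columns.  Rows with any missing marker
    value are rejected with a logged diagnostic naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = list(META_COLUMNS) + list(MARKER_NAMES)
    if schema_check:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    marker_block = df[list(MARKER_NAMES)]
    non_numeric = marker_block.apply(
        lambda col: pd.to_numeric(col, errors="coerce")
    )
    bad_cells = non_numeric.isna() & marker_block.notna()
    if bad_cells.any().any():
        row, col = next(
            (i, c) for c in bad_cells.columns for i in bad_cells.index[bad_cells[c]]
        )
        raise SchemaError(f"non-numeric marker value at row {row}, column {col!r}")
    incomplete = non_numeric.isna().any(axis=1)
    if incomplete.any():
        for idx in df.index[incomplete]:
            logger.warning("dropping row %d: missing marker value(s)", idx)
        df = df.loc[~incomplete]
    df = df.assign(**{m: pd.to_numeric(df[m]) for m in MARKER_NAMES})
    table = MarkerTable.from_frame(df, meta={"source": str(path)})
    return table


def write_marker_table(table: MarkerTable, path: str | Path) -> None:
    """Write the table as RFC-4180 CSV (UTF-8, '.' decimal separator)."""
    df = table.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")


def normalize_proliferation(table: MarkerTable) -> MarkerTable:
    """Normalize proliferation readings by each record's day-1 intensity.

    Day 4/7/14 values are divided elementwise by the same record's day-1
    value and the day-1 column becomes the constant 1; every other marker
    is untouched.  A non-positive day-1 value is an error (it would make
    the fold change meaningless).
    """
    day_idx = [MARKER_NAMES.index(m) for m in PROLIFERATION_MARKERS]
    d1 = day_idx[0]
    new_records = []
    for pos, rec in enumerate(table.records):
        base = rec.markers[d1]
        if base <= 0:
            raise ValueError(
                f"record {pos} ({rec.cell_line}, env {rec.env_id}, rep {rec.replicate}): "
                f"day-1 proliferation {base} is not positive"
            )
        markers = list(rec.markers)
        for j in day_idx[1:]:
            markers[j] = markers[j] / base
        markers[d1] = 1.0
        new_records.append(replace(rec, markers=tuple(markers)))
    meta = dict(table.meta)
    meta["proliferation_normalized"] = True
    return MarkerTable(records=new_records, marker_names=table.marker_names, meta=meta)
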