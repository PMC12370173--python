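"""Seeded synthetic marker tables with planted discriminative structure.

The generator emulates the study design the analysis pipeline assumes:
two cell lines x 12 microenvironments x R replicates, with the 16-marker
panel split into three discriminability tiers,

* **high** — mesenchymal / CD44-family markers (Vimentin MFI and %,
  CD44 MFI, CD44+%, CD44v6 MFI, CD44v6+%): strongly separated between
  cell lines in every environment;
* **moderate** — CD24-type and epithelial markers (CD24 MFI/%,
  CD44+/CD24-%, E-cadherin MFI/%): separated only under tumor-like
  stress conditions (acidic pH 6.5 or dynamic perfusion);
* **low** — proliferation time points and ALDH+%: no phenotype effect.

Effects are planted on a latent Gaussian scale and pushed through link
functions (exponential for MFI-type markers, logistic scaled to [0, 100]
for percent-positive markers), so observation-scale range constraints
hold by construction while "standardized effect size" keeps its usual
meaning.  A shared environment response (both cell lines shift together
under stress conditions) plants two environment-driven regimes within
each cell line, mimicking the stress-response axis (proliferation down,
ALDH up) seen under acidic/perfused culture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .data_model_io import (
    CELL_LINES,
    DYNAMIC,
    INVASIVE,
    MARKER_NAMES,
    MFI_MARKERS,
    NONINVASIVE,
    PERCENT_MARKERS,
    PROLIFERATION_MARKERS,
    MarkerRecord,
    MarkerTable,
    Microenvironment,
    build_condition_grid,
)

HIGH_TIER = (
    "Vimentin MFI",
    "Vimentin+%",
    "CD44 MFI",
    "CD44+%",
    "CD44v6 MFI",
    "CD44v6+%",
)
MODERATE_TIER = (
    "CD24 MFI",
    "CD24+%",
    "CD44+/CD24-%",
    "E-cadherin MFI",
    "E-cadherin+%",
)
LOW_TIER = (
    "Proliferation day1",
    "Proliferation day4",
    "Proliferation day7",
    "Proliferation day14",
    "ALDH+%",
)

DEFAULT_TIER_MAP: dict[str, str] = {
    **{m: "high" for m in HIGH_TIER},
    **{m: "moderate" for m in MODERATE_TIER},
    **{m: "low" for m in LOW_TIER},
}

DEFAULT_EFFECT_SIZE: dict[str, float] = {"high": 4.0, "moderate": 2.5, "low": 0.0}

#: Direction of the invasive-line shift; negative for markers biologically
#: depressed in invasive cells (epithelial E-cadherin, CD24).
EFFECT_DIRECTION: dict[str, float] = {
    **{m: 1.0 for m in MARKER_NAMES},
    "CD24 MFI": -1.0,
    "CD24+%": -1.0,
    "E-cadherin MFI": -1.0,
    "E-cadherin+%": -1.0,
}

#: Latent shift applied to both cell lines in stress environments
#: (pH 6.5 or dynamic perfusion): proliferation drops, ALDH+ and the
#: mesenchymal CSC fraction rise.
DEFAULT_STRESS_RESPONSE: dict[str, float] = {
    "Proliferation day4": -3.0,
    "Proliferation day7": -3.0,
    "Proliferation day14": -3.0,
    "ALDH+%": 3.0,
    "CD44+/CD24-%": 3.0,
}

MFI_SCALE = 100.0  # median-fluorescence scale factor on the observation axis
#: Link steepness: log-MFI units per latent standard deviation.  With unit
#: latent noise this yields a replicate-level MFI coefficient of variation
#: of ~25%, typical of isotype-normalized median-fluorescence readouts.
MFI_LOG_SCALE = 0.25
#: Logit units per latent standard deviation for percent-positive markers;
#: gives replicate SDs of roughly 5-12 percentage points away from the
#: gating extremes.
PERCENT_LOGIT_SCALE = 0.5


def is_stress_environment(env: Microenvironment) -> bool:
    """Tumor-like stress condition: acidic medium or perfused culture."""
    return env.pH == 6.5 or env.perfusion == DYNAMIC


def default_env_response() -> dict[tuple[str, int], float]:
    """Default shared environment response: stress shift per (marker, env_id)."""
    out: dict[tuple[str, int], float] = {}
    for env in build_condition_grid():
        if is_stress_environment(env):
            for marker, shift in DEFAULT_STRESS_RESPONSE.items():
                out[(marker, env.env_id)] = shift
    return out


class ConfigError(ValueError):
    """Raised for an invalid synthetic-data configuration."""


@dataclass
class SyntheticConfig:
    """Generator configuration.

    ``effect_size`` maps each tier to the standardized latent mean
    separation between the two cell lines; the moderate tier is active
    only in stress environments.  ``env_response`` maps (marker, env_id)
    to a latent shift shared by both cell lines.  ``noise_sd`` is the
    per-marker latent standard deviation.
    """

    replicates: int = 3
    seed: int = 0
    tier_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TIER_MAP))
    effect_size: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZE)
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in MARKER_NAMES}
    )
    env_response: dict[tuple[str, int], float] = field(
        default_factory=default_env_response
    )
    raw_proliferation: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if set(self.tier_map) != set(MARKER_NAMES):
            extra = set(self.tier_map) - set(MARKER_NAMES)
            missing = set(MARKER_NAMES) - set(self.tier_map)
            raise ConfigError(
                f"tier_map must cover the 16 markers exactly "
                f"(missing: {sorted(missing)}, unknown: {sorted(extra)})"
            )
        bad = {m: t for m, t in self.tier_map.items() if t not in self.effect_size}
        if bad:
            raise ConfigError(f"tiers without an effect size: {bad}")
        if any(v < 0 for v in self.effect_size.values()):
            raise ConfigError("effect sizes must be >= 0")

    # -- persistence -------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "replicates": self.replicates,
            "seed": self.seed,
            "tier_map": self.tier_map,
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "env_response": [
                {"marker": m, "env_id": e, "shift": s}
                for (m, e), s in sorted(self.env_response.items())
            ],
            "raw_proliferation": self.raw_proliferation,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        doc = yaml.safe_load(Path(path).read_text())
        env_response = {
            (d["marker"], int(d["env_id"])): float(d["shift"])
            for d in doc.get("env_response", [])
        }
        return cls(
            replicates=int(doc.get("replicates", 3)),
            seed=int(doc.get("seed", 0)),
            tier_map=dict(doc.get("tier_map", DEFAULT_TIER_MAP)),
            effect_size={k: float(v) for k, v in doc.get(
                "effect_size", DEFAULT_EFFECT_SIZE).items()},
            noise_sd={k: float(v) for k, v in doc.get(
                "noise_sd", {m: 1.0 for m in MARKER_NAMES}).items()},
            env_response=env_response,
            raw_proliferation=bool(doc.get("raw_proliferation", False)),
        )


def _marker_effect(config: SyntheticConfig, marker: str, env: Microenvironment) -> float:
    """Planted between-line separation for a marker in one environment."""
    tier = config.tier_map[marker]
    effect = config.effect_size[tier]
    if tier == "moderate" and not is_stress_environment(env):
        return 0.0
    return effect


def _to_observation(marker: str, latent: float, config: SyntheticConfig) -> float:
    if marker in PERCENT_MARKERS:
        return 100.0 / (1.0 + np.exp(-PERCENT_LOGIT_SCALE * latent))
    if marker in MFI_MARKERS:
        return MFI_SCALE * float(np.exp(MFI_LOG_SCALE * latent))
    # proliferation fold change relative to day 1
    return float(np.exp(MFI_LOG_SCALE * latent))


def generate_dataset(config: SyntheticConfig) -> MarkerTable:
    """Draw a full synthetic marker table under the configured design.

    Produces ``2 x 12 x replicates`` records in a fixed order (cell line,
    then environment, then replicate).  Each record's random stream is
    derived from ``(seed, line index, env_id, replicate)``, so increasing
    ``replicates`` extends the table without reshuffling existing rows.

    By default proliferation columns are emitted on the day-1-normalized
    scale (day 1 identically 1, later days as fold change); with
    ``raw_proliferation`` the pre-normalization intensities are emitted
    instead (day 1 varies), which round-trip through
    :func:`~mpsprofiler.data_model_io.normalize_proliferation`.
    """
    grid = build_condition_grid()
    records: list[MarkerRecord] = []
    for line_idx, cell_line in enumerate(CELL_LINES):
        for env in grid:
            for rep in range(1, config.replicates + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(line_idx, env.env_id, rep)
                    )
                )
                values: dict[str, float] = {}
                for marker in MARKER_NAMES:
                    latent = config.env_response.get((marker, env.env_id), 0.0)
                    if cell_line == INVASIVE:
                        latent += EFFECT_DIRECTION[marker] * _marker_effect(
                            config, marker, env
                        )
                    latent += rng.normal(0.0, config.noise_sd[marker])
                    values[marker] = _to_observation(marker, latent, config)
                if config.raw_proliferation:
                    day1 = float(np.exp(rng.normal(1.0, 0.2)))
                    values["Proliferation day1"] = day1
                    for m in PROLIFERATION_MARKERS[1:]:
                        values[m] = values[m] * day1
                else:
                    values["Proliferation day1"] = 1.0
                records.append(
                    MarkerRecord(
                        cell_line=cell_line,
                        env_id=env.env_id,
                        replicate=rep,
                        markers=tuple(values[m] for m in MARKER_NAMES),
                    )
                )
    meta = {
        "generator": "mpsprofiler.synthetic_data",
        "seed": config.seed,
        "replicates": config.replicates,
        "raw_proliferation": config.raw_proliferation,
    }
    return MarkerTable(records=records, meta=meta)


def planted_truth(config: SyntheticConfig, condition_level) -> set[str]:
    """Markers recoverable as discriminative at a stratification level.

    Returns the markers whose planted between-line effect is strictly
    positive in *every* environment belonging to the level — the set a
    perfect feature selector restricted to that level could recover
    uniformly.  ``condition_level`` is a
    :class:`~mpsprofiler.profiling_pipeline.ConditionLevel`.
    """
    from .profiling_pipeline import environments_at_level  # local: avoid cycle

    envs = environments_at_level(condition_level)
    if not envs:
        raise ValueError(f"unknown or empty condition level: {condition_level}")
    return {
        marker
        for marker in MARKER_NAMES
        if all(_marker_effect(config, marker, env) > 0 for env in envs)
    }


def planted_truth_table(config: SyntheticConfig) -> dict[str, list[str]]:
    """Planted recoverable marker set per stratification level (JSON-ready)."""
    from .profiling_pipeline import condition_levels

    return {
        level.name: sorted(planted_truth(config, level))
        for level in condition_levels()
    }
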