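"""Synthetic HerbVar-style damage surveys with known ground truth.

The standardized survey design is ~30 conspecific plants per survey with ~10
leaves per plant, proportion damage visually estimated at 0.5% resolution
(values rounded to the grid, with atoms at exactly 0 and occasional 1s).

Besides the purely neutral branch (every leaf an independent draw from the
truncated compound-Poisson simulator) two non-neutral contaminations with a
known sign signature are available:

* ``plant_sigma > 0`` — among-plant heterogeneity: each plant draws a
  mean-one lognormal multiplier on the attack rate, inflating among-plant
  variance relative to the neutral and shuffled baselines;
* ``regularize > 0`` — within-plant regularization (an induced-defence
  caricature): positive leaf damages on a plant are contracted toward their
  within-plant mean by this fraction, evening out damage among leaves while
  preserving the zero pattern and the plant's mean damage on damaged leaves.

Both contaminations are this package's own constructions: they reproduce the
qualitative deviation signatures reported for field data, not any specific
biological mechanism.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .events import EventParams
from .exceptions import ParameterError
from .neutral import NeutralModel, simulate_damage

__all__ = [
    "SynthConfig",
    "generate_survey",
    "generate_surveys",
    "apply_inclusion_filters",
    "FilterResult",
    "plant_means",
    "median_leaves",
    "write_survey",
    "read_survey",
]

SURVEY_COLUMNS = ("survey_id", "plant_id", "leaf_id", "prop_damage")


@dataclass(frozen=True)
class SynthConfig:
    """Survey-generator settings; defaults are the standardized design."""

    n_plants: int = 30
    leaves_per_plant: int = 10
    lam: float = 2.0
    plant_sigma: float = 0.0
    regularize: float = 0.0
    record_resolution: float = 0.005
    round_values: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_plants < 1 or self.leaves_per_plant < 1:
            raise ParameterError("need at least one plant and one leaf per plant")
        if self.lam < 0 or self.plant_sigma < 0:
            raise ParameterError("rates must be >= 0")
        if not (0.0 <= self.regularize < 1.0):
            raise ParameterError("regularize must be in [0, 1)")
        if self.record_resolution <= 0:
            raise ParameterError("record_resolution must be > 0")


def _round_damage(x: np.ndarray, res: float) -> np.ndarray:
    """Round to the recording grid; positive values never cross 0."""
    out = np.round(x / res) * res
    pos = x > 0.0
    out[pos] = np.maximum(out[pos], res)
    return np.clip(out, 0.0, 1.0)


def generate_survey(
    cfg: SynthConfig,
    event: EventParams | None = None,
    survey_id: str = "S1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one survey as a long-format table.

    Each plant p draws a rate multiplier ``m_p ~ lognormal(-sigma^2/2, sigma)``
    (mean one); each of its leaves draws damage from the neutral simulator at
    rate ``lam * m_p``; the regularization contraction is applied per plant;
    finally values are rounded to the recording resolution (positive values
    floored at one resolution step).
    """
    event = event or EventParams()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows = []
    for p in range(cfg.n_plants):
        mult = (
            rng.lognormal(-0.5 * cfg.plant_sigma**2, cfg.plant_sigma)
            if cfg.plant_sigma > 0
            else 1.0
        )
        damage = simulate_damage(
            NeutralModel(cfg.lam * mult, event), cfg.leaves_per_plant, rng
        )
        if cfg.regularize > 0.0:
            pos = damage > 0.0
            if pos.sum() >= 2:
                m = damage[pos].mean()
                damage[pos] = m + (1.0 - cfg.regularize) * (damage[pos] - m)
        if cfg.round_values:
            damage = _round_damage(damage, cfg.record_resolution)
        for leaf, d in enumerate(damage):
            rows.append((survey_id, f"P{p + 1:03d}", f"L{leaf + 1:03d}", float(d)))
    return pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))


def generate_surveys(
    n_surveys: int,
    cfg: SynthConfig,
    event: EventParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate several independent surveys with ids S001, S002, ..."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    frames = [
        generate_survey(cfg, event, survey_id=f"S{i + 1:03d}", rng=rng)
        for i in range(n_surveys)
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class FilterResult:
    """Inclusion-filtered views of a survey table plus the exclusion log."""

    among_plant: pd.DataFrame
    among_leaf: pd.DataFrame
    exclusions: pd.DataFrame


def apply_inclusion_filters(
    table: pd.DataFrame, min_plants: int = 15, min_leaves: int = 10
) -> FilterResult:
    """Apply the survey-inclusion rules.

    Surveys with fewer than ``min_plants`` plant records are dropped from the
    among-plant set; plants with fewer than ``min_leaves`` leaf records are
    dropped from the among-leaf set.  Every exclusion is logged with its
    reason and record count.
    """
    log = []
    if table.empty:
        empty = table.copy()
        return FilterResult(empty, empty.copy(),
                            pd.DataFrame(columns=["unit", "id", "reason", "n_records"]))
    plant_counts = table.groupby("survey_id")["plant_id"].nunique()
    keep_surveys = plant_counts[plant_counts >= min_plants].index
    for sid, cnt in plant_counts.items():
        if cnt < min_plants:
            log.append(("survey", sid, f"fewer than {min_plants} plants", int(cnt)))
    among_plant = table[table["survey_id"].isin(keep_surveys)].copy()

    leaf_counts = table.groupby(["survey_id", "plant_id"]).size()
    keep_plants = leaf_counts[leaf_counts >= min_leaves].index
    for (sid, pid), cnt in leaf_counts.items():
        if cnt < min_leaves:
            log.append(("plant", f"{sid}/{pid}", f"fewer than {min_leaves} leaves", int(cnt)))
    idx = pd.MultiIndex.from_frame(table[["survey_id", "plant_id"]])
    among_leaf = table[idx.isin(keep_plants)].copy()
    return FilterResult(
        among_plant, among_leaf,
        pd.DataFrame(log, columns=["unit", "id", "reason", "n_records"]),
    )


def plant_means(table: pd.DataFrame) -> pd.DataFrame:
    """Plant-level damage: the mean over each plant's sampled leaves."""
    out = (
        table.groupby(["survey_id", "plant_id"], sort=True)["prop_damage"]
        .mean()
        .reset_index()
    )
    return out


def median_leaves(table: pd.DataFrame) -> pd.Series:
    """Median leaf count per plant, by survey (half-up rounding to an int)."""
    counts = table.groupby(["survey_id", "plant_id"]).size()
    med = counts.groupby("survey_id").median()
    return med.apply(lambda m: int(math.floor(m + 0.5)))


def write_survey(table: pd.DataFrame, path, sidecar: dict | None = None) -> None:
    """Write a survey table as CSV (UTF-8, header, '.' decimal) plus an
    optional provenance sidecar JSON next to it."""
    table.to_csv(path, index=False)
    if sidecar is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)


def read_survey(path, percent: bool = False) -> pd.DataFrame:
    """Read and validate a survey CSV; ``percent=True`` divides damage by 100."""
    from .exceptions import DataError

    table = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    if percent:
        table = table.assign(prop_damage=table["prop_damage"] / 100.0)
    vals = table["prop_damage"]
    bad = table[~vals.between(0.0, 1.0) | vals.isna()]
    if len(bad):
        raise DataError(
            f"prop_damage outside [0, 1] in rows {bad.index.tolist()[:20]}"
        )
    dup = table.duplicated(subset=["survey_id", "plant_id", "leaf_id"])
    if dup.any():
        raise DataError(
            f"duplicate (survey_id, plant_id, leaf_id) keys in rows "
            f"{table.index[dup].tolist()[:20]}"
        )
    return table


def config_sidecar(cfg: SynthConfig, event: EventParams, n_surveys: int) -> dict:
    from . import __version__

    return {
        "generator": "neutralherb.synth",
        "version": __version__,
        "n_surveys": n_surveys,
        "config": asdict(cfg),
        "event": {"phi_m": event.phi_m, "phi_M": event.phi_M, "alpha": event.alpha},
    }
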