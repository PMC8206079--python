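"""Typed containers and tabular readers/writers shared by the pipeline.

On-disk layouts (UTF-8, '.' decimal separator):

- ``detections.tsv`` — long format: taxon, unit_id, detected, effort
- ``samples.csv``    — sample_id, site_id, year, design, volume_l, rain_mm,
  catchment_km2
- ``cameras.csv``    — site_id, year, trap_days, taxon, n_pictures,
  n_detection_days
- ``costs.csv``      — method, year, reusable, single_use, labour_lab,
  logistics, total, n_units
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAXON_GROUPS = frozenset(
    {"bears", "canids", "felids", "ungulates", "lagomorphs",
     "small_mammals", "bats", "other"}
)
DIETS = frozenset({"carnivore", "omnivore", "herbivore"})
RANKS = frozenset({"species", "genus", "subfamily"})


class SchemaError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass(frozen=True)
class Taxon:
    """A detected taxon at species, genus, or subfamily rank.

    ``group`` follows the higher-taxonomic codes used for reporting
    (bears/canids/felids/ungulates/lagomorphs/small_mammals/bats/other);
    ``diet`` and ``body_mass`` (kg) are the ecological covariates used in
    the detection GLMs; ``camera_detectable`` marks taxa a camera-trap grid
    aimed at medium/large mammals can detect and identify.
    """

    name: str
    rank: str = "species"
    group: str = "other"
    diet: str | None = None
    body_mass: float | None = None
    camera_detectable: bool = True

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise SchemaError(f"unknown rank {self.rank!r} for taxon {self.name!r}")
        if self.group not in TAXON_GROUPS:
            raise SchemaError(f"unknown group {self.group!r} for taxon {self.name!r}")
        if self.diet is not None and self.diet not in DIETS:
            raise SchemaError(f"unknown diet {self.diet!r} for taxon {self.name!r}")
        if self.body_mass is not None and not self.body_mass > 0:
            raise SchemaError(f"body_mass must be > 0 for taxon {self.name!r}")
        # felids are obligate carnivores: reject contradictory metadata
        if self.group == "felids" and self.diet not in (None, "carnivore"):
            raise SchemaError(
                f"taxon {self.name!r}: group 'felids' implies diet 'carnivore', "
                f"got {self.diet!r}"
            )


@dataclass(frozen=True)
class WaterSample:
    """One filtered stream-water sample with its sampling covariates."""

    sample_id: str
    site_id: str
    year: int
    design: str  # 'spatial' or 'catchment'
    volume: float  # litres
    rain_prev_day: float = 0.0  # mm
    catchment_area: float = 1.0  # km^2
    duration: float | None = None  # minutes

    def __post_init__(self) -> None:
        if self.design not in ("spatial", "catchment"):
            raise SchemaError(f"unknown design {self.design!r}")
        if not (math.isfinite(self.volume) and self.volume > 0):
            raise SchemaError(f"sample {self.sample_id!r}: volume must be finite > 0")
        if self.rain_prev_day < 0:
            raise SchemaError(f"sample {self.sample_id!r}: rain must be >= 0")
        if self.catchment_area <= 0:
            raise SchemaError(f"sample {self.sample_id!r}: catchment_area must be > 0")


@dataclass
class CameraDeployment:
    """One camera-trap site-season: effort in trap-days and per-taxon counts.

    ``detections`` counts independent pictures; ``detection_days`` counts
    distinct days with at least one detection (bounded by both).
    """

    site_id: str
    year: int
    trap_days: int
    detections: dict[str, int] = field(default_factory=dict)
    detection_days: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.trap_days <= 0:
            raise SchemaError(f"camera {self.site_id!r}: trap_days must be > 0")
        if any(v < 0 for v in self.detections.values()):
            raise SchemaError(f"camera {self.site_id!r}: negative detection count")
        if self.detection_days is not None:
            for t, d in self.detection_days.items():
                if d > self.trap_days:
                    raise SchemaError(
                        f"camera {self.site_id!r}, taxon {t!r}: "
                        f"detection_days {d} > trap_days {self.trap_days}"
                    )
                if t in self.detections and d > self.detections[t]:
                    raise SchemaError(
                        f"camera {self.site_id!r}, taxon {t!r}: "
                        f"detection_days {d} > independent detections"
                    )


@dataclass
class DetectionMatrix:
    """Binary taxa x sampling-unit matrix with per-unit effort.

    Effort is litres of water filtered (eDNA) or trap-days (cameras).
    """

    taxa: list[Taxon]
    units: list[str]
    effort: np.ndarray  # shape (n_units,)
    y: np.ndarray  # shape (n_taxa, n_units), values in {0, 1}

    def __post_init__(self) -> None:
        self.effort = np.asarray(self.effort, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.shape != (len(self.taxa), len(self.units)):
            raise SchemaError(
                f"matrix shape {self.y.shape} inconsistent with "
                f"{len(self.taxa)} taxa x {len(self.units)} units"
            )
        if self.effort.shape != (len(self.units),):
            raise SchemaError("effort length must equal number of units")
        if not np.all(self.effort > 0):
            bad = [self.units[i] for i in np.flatnonzero(~(self.effort > 0))]
            raise SchemaError(f"non-positive effort for units {bad}")
        if not np.isin(self.y, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.y, (0, 1)))
            rows = [(self.taxa[i].name, self.units[j]) for i, j in bad[:5]]
            raise SchemaError(f"non-binary detection cells at {rows}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    def subset_taxa(self, keep: Sequence[str]) -> "DetectionMatrix":
        """Return a copy restricted to the named taxa (order preserved)."""
        keep_set = set(keep)
        idx = [i for i, t in enumerate(self.taxa) if t.name in keep_set]
        return DetectionMatrix(
            taxa=[self.taxa[i] for i in idx],
            units=list(self.units),
            effort=self.effort.copy(),
            y=self.y[idx, :].copy(),
        )


@dataclass
class CostModel:
    """Per-survey cost breakdown (USD) and the derived per-unit cost.

    ``per_unit`` is the total divided by the number of samples/sites,
    rounded half-up to the nearest dollar.
    """

    method: str  # 'camera' or 'edna'
    year: int
    components: dict[str, float]
    n_units: int
    total: float
    per_unit: int = 0

    COMPONENT_KEYS = ("reusable_equipment", "single_use_equipment",
                      "labour_lab", "logistics")

    def __post_init__(self) -> None:
        if self.method not in ("camera", "edna"):
            raise SchemaError(f"unknown method {self.method!r}")
        if self.n_units <= 0:
            raise SchemaError("n_units must be > 0")
        if any(v < 0 for v in self.components.values()):
            raise SchemaError("negative cost component")
        if self.total < 0:
            raise SchemaError("negative total cost")
        self.per_unit = _round_half_up(self.total / self.n_units)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Detection-matrix IO (long format: taxon, unit_id, detected, effort)
# ---------------------------------------------------------------------------

def read_detection_matrix(
    path: str | Path,
    effort_column: str = "effort",
    taxa: Mapping[str, Taxon] | None = None,
) -> DetectionMatrix:
    """Read a long-format detection table into a :class:`DetectionMatrix`.

    The file must be TSV (or CSV, by extension) with columns
    ``taxon, unit_id, detected`` plus a per-unit effort column. Taxa are
    ordered alphabetically and units by id, so the result is deterministic.
    ``taxa`` optionally supplies full :class:`Taxon` metadata by name;
    otherwise species-rank placeholder taxa are created.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"taxon", "unit_id", "detected", effort_column}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")

    dup = df.duplicated(subset=["taxon", "unit_id"])
    if dup.any():
        rows = df.loc[dup, ["taxon", "unit_id"]].head().to_dict("records")
        raise SchemaError(f"{path.name}: duplicate (taxon, unit) pairs: {rows}")
    if not df["detected"].isin((0, 1)).all():
        rows = df.loc[~df["detected"].isin((0, 1))].head().to_dict("records")
        raise SchemaError(f"{path.name}: non-binary 'detected' values: {rows}")

    eff_by_unit = df.groupby("unit_id")[effort_column].agg(["min", "max"])
    if (eff_by_unit["min"] != eff_by_unit["max"]).any():
        bad = eff_by_unit.index[eff_by_unit["min"] != eff_by_unit["max"]].tolist()
        raise SchemaError(f"{path.name}: inconsistent effort within units {bad}")

    taxon_names = sorted(df["taxon"].unique())
    units = sorted(df["unit_id"].astype(str).unique())
    t_idx = {t: i for i, t in enumerate(taxon_names)}
    u_idx = {u: j for j, u in enumerate(units)}

    y = np.zeros((len(taxon_names), len(units)), dtype=np.int8)
    effort = np.full(len(units), np.nan)
    for row in df.itertuples(index=False):
        i = t_idx[row.taxon]
        j = u_idx[str(row.unit_id)]
        y[i, j] = int(row.detected)
        effort[j] = float(getattr(row, effort_column))
    if np.isnan(effort).any():
        raise SchemaError(f"{path.name}: units with no effort value")

    taxa_list = [
        (taxa[name] if taxa and name in taxa else Taxon(name=name))
        for name in taxon_names
    ]
    return DetectionMatrix(taxa=taxa_list, units=units, effort=effort, y=y)


def write_detection_matrix(m: DetectionMatrix, path: str | Path) -> None:
    """Write a :class:`DetectionMatrix` as long-format TSV (or CSV)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    records = [
        {"taxon": t.name, "unit_id": u, "detected": int(m.y[i, j]),
         "effort": m.effort[j]}
        for i, t in enumerate(m.taxa)
        for j, u in enumerate(m.units)
    ]
    pd.DataFrame.from_records(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Sample / camera / cost tables
# ---------------------------------------------------------------------------

def read_samples(path: str | Path) -> list[WaterSample]:
    df = pd.read_csv(path)
    return [
        WaterSample(
            sample_id=str(r.sample_id),
            site_id=str(r.site_id),
            year=int(r.year),
            design=str(r.design),
            volume=float(r.volume_l),
            rain_prev_day=float(r.rain_mm),
            catchment_area=float(r.catchment_km2),
        )
        for r in df.itertuples(index=False)
    ]


def write_samples(samples: Sequence[WaterSample], path: str | Path) -> None:
    pd.DataFrame.from_records(
        [
            {"sample_id": s.sample_id, "site_id": s.site_id, "year": s.year,
             "design": s.design, "volume_l": s.volume, "rain_mm": s.rain_prev_day,
             "catchment_km2": s.catchment_area}
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_cameras(path: str | Path) -> list[CameraDeployment]:
    """Read long-format camera records into deployments (one per site-year)."""
    df = pd.read_csv(path)
    out: list[CameraDeployment] = []
    for (site, year), grp in df.groupby(["site_id", "year"], sort=True):
        trap_days = int(grp["trap_days"].iloc[0])
        if (grp["trap_days"] != trap_days).any():
            raise SchemaError(f"camera {site!r} year {year}: inconsistent trap_days")
        detections = dict(zip(grp["taxon"], grp["n_pictures"].astype(int)))
        dd = None
        if "n_detection_days" in grp.columns and grp["n_detection_days"].notna().all():
            dd = dict(zip(grp["taxon"], grp["n_detection_days"].astype(int)))
        out.append(
            CameraDeployment(site_id=str(site), year=int(year),
                             trap_days=trap_days, detections=detections,
                             detection_days=dd)
        )
    return out


def write_cameras(deployments: Sequence[CameraDeployment], path: str | Path) -> None:
    records = []
    for d in deployments:
        for taxon, n in sorted(d.detections.items()):
            records.append(
                {"site_id": d.site_id, "year": d.year, "trap_days": d.trap_days,
                 "taxon": taxon, "n_pictures": n,
                 "n_detection_days": (d.detection_days or {}).get(taxon)}
            )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


_COST_COLUMNS = {"reusable": "reusable_equipment",
                 "single_use": "single_use_equipment",
                 "labour_lab": "labour_lab",
                 "logistics": "logistics"}


def read_cost_model(path: str | Path) -> list[CostModel]:
    """Read a survey cost table (one row per method-year).

    The total is the sum of the four components unless an explicit ``total``
    column is present, which then takes precedence (a warning is logged when
    the two disagree by more than $1 — published cost tables occasionally
    carry line items not broken out into the printed components).
    """
    return read_cost_model_frame(pd.read_csv(path))


def read_cost_model_frame(df: pd.DataFrame) -> list[CostModel]:
    """Same as :func:`read_cost_model` from an in-memory table."""
    missing = (set(_COST_COLUMNS) | {"method", "year", "n_units"}) - set(df.columns)
    if missing:
        raise SchemaError(f"cost table missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        components = {full: float(getattr(r, short))
                      for short, full in _COST_COLUMNS.items()}
        if any(v < 0 for v in components.values()):
            raise SchemaError(f"negative cost component in row {r}")
        comp_sum = sum(components.values())
        total = comp_sum
        if "total" in df.columns and not pd.isna(getattr(r, "total")):
            total = float(getattr(r, "total"))
            if abs(total - comp_sum) > 1.0:
                logger.warning(
                    "cost row %s %s: explicit total %s differs from component "
                    "sum %s; using explicit total", r.method, r.year, total, comp_sum
                )
        out.append(
            CostModel(method=str(r.method), year=int(r.year),
                      components=components, n_units=int(r.n_units), total=total)
        )
    return out


def write_cost_model(models: Sequence[CostModel], path: str | Path) -> None:
    rev = {v: k for k, v in _COST_COLUMNS.items()}
    pd.DataFrame.from_records(
        [
            {"method": m.method, "year": m.year,
             **{rev[k]: v for k, v in m.components.items()},
             "total": m.total, "n_units": m.n_units}
            for m in models
        ]
    ).to_csv(path, index=False)
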