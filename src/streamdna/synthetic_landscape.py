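"""Synthetic mammal communities and surveys under the assumed model.

Generates everything the analysis consumes, so the full chain — MOTU
filtering, detection-probability estimation, covariate GLMs, diversity and
cost curves — runs end-to-end with known ground truth:

- a community of taxa with true standardized detection probabilities
  ``p60`` drawn from diet-specific Beta distributions (carnivores lower
  than omnivores/herbivores, matching the food-chain expectation for
  eDNA deposition) and true daily camera detection rates ``lambda``
  drawn log-normal,
- eDNA surveys: detections are Bernoulli with the same complementary
  log-log effort scaling the estimator assumes,
  ``P(detect) = 1 - (1 - p_tj)^(V_j / 60)``, where rain and catchment-area
  effects (if any) shift the cloglog-scale per-60 L probability,
- camera surveys: independent detections per day are Poisson(lambda),
  aggregated to picture totals and detection-days.

Scenario presets ``paper_2018`` (50 spatial samples of ~30 L across 42
sites) and ``paper_2019`` (36 catchment samples of 25-80 L from 2 sites)
encode the two study designs for scaled reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from streamdna.io_schemas import CameraDeployment, DetectionMatrix, Taxon, WaterSample
from streamdna.motu_filtering import Candidate, Motu, MotuTable

# diet -> Beta(a, b) for true p60; carnivores lowest, reflecting that top
# predators must interact with water for DNA deposition
DEFAULT_DIET_EFFECTS: dict[str, tuple[float, float]] = {
    "carnivore": (2.0, 6.0),   # mean 0.25
    "omnivore": (3.5, 4.5),    # mean ~0.44
    "herbivore": (4.0, 4.5),   # mean ~0.47
}

# group -> (proportion, diet, camera_detectable, median body mass kg)
DEFAULT_GROUP_MIX: dict[str, tuple[float, str, bool, float]] = {
    "bears": (0.06, "omnivore", True, 150.0),
    "canids": (0.08, "carnivore", True, 15.0),
    "felids": (0.08, "carnivore", True, 30.0),
    "ungulates": (0.20, "herbivore", True, 150.0),
    "lagomorphs": (0.08, "herbivore", True, 2.0),
    "small_mammals": (0.30, "herbivore", False, 0.05),
    "bats": (0.12, "carnivore", False, 0.01),
    "other": (0.08, "omnivore", True, 5.0),
}


@dataclass(frozen=True)
class TrueCommunity:
    """Ground-truth community: taxa with true p60 and camera rates."""

    taxa: tuple[Taxon, ...]
    true_p60: np.ndarray
    true_lambda: np.ndarray  # expected independent camera detections per day
    beta_rain: float = 0.0   # cloglog-scale effect per mm of rain
    beta_area: float = 0.0   # cloglog-scale effect per log-km2 of catchment
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any((self.true_p60 <= 0) | (self.true_p60 >= 1)):
            raise ValueError("true_p60 must be strictly inside (0, 1)")
        if np.any(self.true_lambda < 0):
            raise ValueError("true_lambda must be >= 0")

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon": [t.name for t in self.taxa],
             "group": [t.group for t in self.taxa],
             "diet": [t.diet for t in self.taxa],
             "body_mass": [t.body_mass for t in self.taxa],
             "camera_detectable": [t.camera_detectable for t in self.taxa],
             "true_p60": self.true_p60,
             "lambda": self.true_lambda}
        )


@dataclass(frozen=True)
class SurveyScenario:
    """Field-design parameters for one synthetic survey season."""

    design: str  # 'spatial' or 'catchment'
    year: int
    n_samples: int
    volumes: tuple[float, ...]  # per-sample litres (cycled if shorter)
    n_sites: int
    rain_max: float = 30.0  # mm; per-sample rain ~ Uniform(0, rain_max)
    catchment_range: tuple[float, float] = (5.0, 1200.0)  # km2, log-uniform
    n_cameras: int = 57
    trap_days: int = 100

    def __post_init__(self) -> None:
        if self.design not in ("spatial", "catchment"):
            raise ValueError(f"unknown design {self.design!r}")
        if min(self.n_samples, self.n_sites, self.n_cameras, self.trap_days) <= 0:
            raise ValueError("scenario sizes must be positive")
        if any(v <= 0 for v in self.volumes):
            raise ValueError("volumes must be positive")


def paper_2018() -> SurveyScenario:
    """Spatial design: 50 samples of ~30 L from 42 scattered stream sites."""
    return SurveyScenario(design="spatial", year=2018, n_samples=50,
                          volumes=(30.0,), n_sites=42,
                          catchment_range=(5.0, 300.0),
                          n_cameras=57, trap_days=100)


def paper_2019() -> SurveyScenario:
    """Catchment design: 36 samples of 25-80 L from 2 watershed outlets."""
    volumes = (75.0, 75.0, 55.0, 55.0, 30.0, 30.0) * 6
    return SurveyScenario(design="catchment", year=2019, n_samples=36,
                          volumes=volumes, n_sites=2,
                          catchment_range=(500.0, 700.0),
                          n_cameras=57, trap_days=100)


def generate_community(
    n_species: int,
    group_mix: dict[str, tuple[float, str, bool, float]] | None = None,
    diet_effects: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    beta_rain: float = 0.0,
    beta_area: float = 0.0,
) -> TrueCommunity:
    """Draw a ground-truth community.

    Group membership follows ``group_mix`` proportions; true p60 comes from
    the group diet's Beta distribution. Daily camera rates are log-normal
    (sigma 0.6) with median proportional to the taxon's detection odds
    p60/(1-p60) — both quantities reflect local abundance and activity, so
    eDNA-detectable taxa are also camera-active — and 0 for taxa a camera
    grid cannot record.
    """
    mix = group_mix or DEFAULT_GROUP_MIX
    diets = diet_effects or DEFAULT_DIET_EFFECTS
    props = np.array([v[0] for v in mix.values()])
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("group proportions must sum to 1")
    rng = np.random.default_rng(seed)
    if n_species == 0:
        return TrueCommunity(taxa=(), true_p60=np.empty(0),
                             true_lambda=np.empty(0), seed=seed,
                             beta_rain=beta_rain, beta_area=beta_area)
    groups = rng.choice(list(mix), size=n_species, p=props)
    taxa = []
    p60 = np.empty(n_species)
    lam = np.empty(n_species)
    for i, g in enumerate(groups):
        _, diet, cam, mass_median = mix[g]
        a, b = diets[diet]
        p = float(np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4))
        mass = float(mass_median * rng.lognormal(0.0, 0.5))
        taxa.append(Taxon(name=f"Taxon_{i:03d}", rank="species", group=g,
                          diet=diet, body_mass=mass, camera_detectable=cam))
        p60[i] = p
        lam[i] = rng.lognormal(np.log(0.1 * p / (1 - p)), 0.6) if cam else 0.0
    return TrueCommunity(taxa=tuple(taxa), true_p60=p60, true_lambda=lam,
                         beta_rain=beta_rain, beta_area=beta_area, seed=seed)


def _cloglog(p: np.ndarray) -> np.ndarray:
    return np.log(-np.log1p(-p))


def _inv_cloglog(eta: np.ndarray) -> np.ndarray:
    return -np.expm1(-np.exp(eta))


def sample_covariates(
    s: SurveyScenario, rng: np.random.Generator
) -> list[WaterSample]:
    """Draw per-sample volumes, rain and catchment areas for a scenario."""
    lo, hi = s.catchment_range
    site_area = np.exp(rng.uniform(np.log(lo), np.log(hi), size=s.n_sites))
    samples = []
    for j in range(s.n_samples):
        site = j % s.n_sites
        samples.append(
            WaterSample(
                sample_id=f"S{s.year}_{j:03d}",
                site_id=f"site_{site:03d}",
                year=s.year,
                design=s.design,
                volume=float(s.volumes[j % len(s.volumes)]),
                rain_prev_day=float(np.round(rng.uniform(0, s.rain_max), 1)),
                catchment_area=float(np.round(site_area[site], 1)),
            )
        )
    return samples


def simulate_edna(
    c: TrueCommunity,
    s: SurveyScenario,
    seed: int = 0,
    unit: float = 60.0,
) -> tuple[DetectionMatrix, list[WaterSample]]:
    """Simulate one eDNA survey season.

    Per taxon t and sample j the detection is Bernoulli with
    ``1 - (1 - p_tj)^(V_j / 60)``, where the cloglog of p_tj is the cloglog
    of the taxon's true p60 shifted by ``beta_rain * rain_j`` and
    ``beta_area * log(area_j / 100 km2)``.
    """
    rng = np.random.default_rng(seed)
    samples = sample_covariates(s, rng)
    n_t = len(c.taxa)
    rain = np.array([x.rain_prev_day for x in samples])
    area = np.array([x.catchment_area for x in samples])
    vol = np.array([x.volume for x in samples])
    eta = (_cloglog(c.true_p60)[:, None]
           + c.beta_rain * rain[None, :]
           + c.beta_area * np.log(area[None, :] / 100.0))
    p_tj = np.clip(_inv_cloglog(eta), 1e-12, 1 - 1e-12)
    prob = 1.0 - np.power(1.0 - p_tj, vol[None, :] / unit)
    y = (rng.uniform(size=prob.shape) < prob).astype(np.int8)
    m = DetectionMatrix(
        taxa=list(c.taxa),
        units=[x.sample_id for x in samples],
        effort=vol,
        y=y,
    )
    return m, samples


def effective_p60(
    c: TrueCommunity, samples: Sequence[WaterSample]
) -> np.ndarray:
    """Survey-average per-60 L detection probability per taxon.

    Covariate effects shift each sample's standardized probability away from
    the baseline true_p60; the pooled estimator targets this average, so
    recovery should be judged against it.
    """
    rain = np.array([x.rain_prev_day for x in samples])
    area = np.array([x.catchment_area for x in samples])
    eta = (_cloglog(c.true_p60)[:, None]
           + c.beta_rain * rain[None, :]
           + c.beta_area * np.log(area[None, :] / 100.0))
    return _inv_cloglog(eta).mean(axis=1)


def simulate_cameras(
    c: TrueCommunity,
    s: SurveyScenario,
    seed: int = 0,
) -> list[CameraDeployment]:
    """Simulate one camera-trap season: daily Poisson(lambda) detections."""
    rng = np.random.default_rng(seed)
    out = []
    for site in range(s.n_cameras):
        detections: dict[str, int] = {}
        detection_days: dict[str, int] = {}
        for t, taxon in enumerate(c.taxa):
            lam = c.true_lambda[t]
            if lam == 0:
                continue
            daily = rng.poisson(lam, size=s.trap_days)
            total = int(daily.sum())
            if total > 0:
                detections[taxon.name] = total
                detection_days[taxon.name] = int((daily > 0).sum())
        out.append(
            CameraDeployment(site_id=f"cam_{site:03d}", year=s.year,
                             trap_days=s.trap_days, detections=detections,
                             detection_days=detection_days)
        )
    return out


def default_membership(
    samples: Sequence[WaterSample],
    deployments: Sequence[CameraDeployment],
    cameras_per_site: int = 3,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Assign each eDNA site an upstream set of cameras (synthetic stand-in
    for the GIS watershed mapping, which is an input, not computed here)."""
    rng = np.random.default_rng(seed)
    cam_ids = [d.site_id for d in deployments]
    sites = sorted({x.site_id for x in samples})
    k = min(cameras_per_site, len(cam_ids))
    return {
        site: set(rng.choice(cam_ids, size=k, replace=False)) for site in sites
    }


def simulate_motu_table(
    m: DetectionMatrix,
    samples: Sequence[WaterSample],
    seed: int = 0,
    mean_reads: float = 2000.0,
    n_contaminants: int = 2,
    n_low_similarity: int = 2,
    tag_jump_rate: float = 0.0001,
) -> MotuTable:
    """Dress a binary detection matrix up as a raw MOTU read-count table.

    Detected cells get negative-binomial read counts; a few contaminant
    MOTUs (flagged in negative controls) and low-similarity MOTUs are
    added, and a small fraction of each taxon's library-wide reads is
    scattered to random samples to emulate tag jumps. Running the filter
    chain on the result should recover the input matrix (up to taxa whose
    every count falls below the tag-jump threshold).
    """
    rng = np.random.default_rng(seed)
    sample_ids = list(m.units)
    libraries = {s: ("L1" if i % 2 == 0 else "L2")
                 for i, s in enumerate(sample_ids)}
    motus: list[Motu] = []
    counts_rows: list[np.ndarray] = []
    for i, taxon in enumerate(m.taxa):
        genus = taxon.name.split()[0] if " " in taxon.name else taxon.name
        cand = Candidate(species=taxon.name, genus=genus,
                         subfamily=f"{genus}inae")
        row = np.zeros(len(sample_ids), dtype=int)
        detected = np.flatnonzero(m.y[i, :] == 1)
        # negative binomial via gamma-Poisson mixture, overdispersion ~ 3
        lam = rng.gamma(3.0, mean_reads / 3.0, size=detected.size)
        row[detected] = rng.poisson(lam) + 1
        # tag jumps: tiny counts leaking into non-detected samples, with
        # intensity proportional to the taxon's reads in the same library
        for lib in set(libraries.values()):
            in_lib = np.array([libraries[s] == lib for s in sample_ids])
            lib_total = row[in_lib].sum()
            leak = np.flatnonzero(in_lib & (m.y[i, :] == 0) & (row == 0))
            if leak.size and lib_total > 0:
                row[leak] = rng.poisson(tag_jump_rate * lib_total,
                                        size=leak.size)
        motus.append(Motu(motu_id=f"MOTU_{i:04d}", candidates=(cand,),
                          best_similarity=float(rng.uniform(0.97, 1.0))))
        counts_rows.append(row)
    for j in range(n_contaminants):
        motus.append(Motu(motu_id=f"MOTU_ctrl_{j}",
                          candidates=(Candidate("Homo sapiens", "Homo",
                                                "Homininae"),),
                          best_similarity=1.0, in_negative_control=True))
        counts_rows.append(rng.poisson(50.0, size=len(sample_ids)))
    for j in range(n_low_similarity):
        motus.append(Motu(motu_id=f"MOTU_low_{j}",
                          candidates=(Candidate(f"Dubium_{j} sp", "Dubium",
                                                "Dubiinae"),),
                          best_similarity=float(rng.uniform(0.80, 0.95))))
        counts_rows.append(rng.poisson(20.0, size=len(sample_ids)))
    counts = pd.DataFrame(np.vstack(counts_rows),
                          index=[mt.motu_id for mt in motus],
                          columns=sample_ids)
    return MotuTable(motus=motus, counts=counts, library_of_sample=libraries)
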