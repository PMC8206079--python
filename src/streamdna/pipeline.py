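"""Stage orchestration: one call reproduces the full analysis.

Stages run in a fixed order — filter-motus, estimate-detection, fit-models,
diversity, cost-curves, compare — each writing its CSV artifacts into a run
directory, plus a ``manifest.json`` recording the package version and every
seed used. No stage mutates its inputs; reruns with the same config are
bit-identical for deterministic stages and summary-identical for seeded
stochastic stages.

The published survey cost table (four rows: camera/eDNA x 2018/2019) ships
as the default cost input so cost-efficiency curves can be produced for
synthetic surveys of the same designs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from streamdna import __version__, covariate_glm, detection_model, diversity_cost
from streamdna import comparison as cmp_mod
from streamdna import io_schemas, motu_filtering, synthetic_landscape

logger = logging.getLogger(__name__)

# Survey cost table (USD): method, year, components, explicit total, n_units.
# Explicit totals take precedence over component sums (see io_schemas).
PUBLISHED_COSTS = pd.DataFrame(
    [
        {"method": "camera", "year": 2018, "reusable": 11970, "single_use": 503,
         "labour_lab": 24800, "logistics": 858, "total": 38273, "n_units": 57},
        {"method": "camera", "year": 2019, "reusable": 840, "single_use": 482,
         "labour_lab": 23600, "logistics": 821, "total": 25922, "n_units": 57},
        {"method": "edna", "year": 2018, "reusable": 1053, "single_use": 4746,
         "labour_lab": 19203, "logistics": 948, "total": 25950, "n_units": 50},
        {"method": "edna", "year": 2019, "reusable": 3498, "single_use": 2721,
         "labour_lab": 13858, "logistics": 441, "total": 20465, "n_units": 36},
    ]
)


@dataclass
class PipelineConfig:
    """Declarative configuration for a full synthetic-analysis run."""

    out_dir: str
    seed: int = 0
    n_species: int = 40
    mcmc: detection_model.McmcConfig | None = None  # None -> grid posterior
    prior: tuple[float, float] = (1.0, 1.0)
    bootstrap_iters: int = 1000
    similarity_threshold: float = 0.96
    tag_jump_freq: float = 0.001
    scenarios: tuple[str, ...] = ("paper_2018", "paper_2019")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mcmc = raw.pop("mcmc", None)
        cfg = cls(**raw)
        if mcmc:
            cfg.mcmc = detection_model.McmcConfig(**mcmc)
        return cfg


def _subseed(seed: int, *path: int) -> int:
    """Derive a child seed (< 2^31) from a root seed and a stage path."""
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % (2**31))


def build_detection_rows(
    m: io_schemas.DetectionMatrix,
    samples: Sequence[io_schemas.WaterSample],
    rates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long per-(taxon x sample) rows for the binomial detection GLM.

    Columns: taxon, sample, detected, volume, rain_prev_day, catchment_area,
    year, group, diet, body_mass, and camera_rate when a rate table (taxon x
    eDNA site) is supplied.
    """
    meta = {s.sample_id: s for s in samples}
    rows = []
    for i, taxon in enumerate(m.taxa):
        for j, unit in enumerate(m.units):
            s = meta[unit]
            row = {
                "taxon": taxon.name, "sample": unit,
                "detected": int(m.y[i, j]), "volume": s.volume,
                "rain_prev_day": s.rain_prev_day,
                "catchment_area": s.catchment_area,
                "year": str(s.year), "group": taxon.group,
                "diet": taxon.diet, "body_mass": taxon.body_mass,
            }
            if rates is not None:
                row["camera_rate"] = (
                    float(rates.loc[taxon.name, s.site_id])
                    if taxon.name in rates.index and s.site_id in rates.columns
                    else 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows)


def build_richness_rows(
    m: io_schemas.DetectionMatrix,
    samples: Sequence[io_schemas.WaterSample],
) -> pd.DataFrame:
    """Per-sample richness with sampling covariates for the Poisson GLM."""
    meta = {s.sample_id: s for s in samples}
    richness, _ = diversity_cost.site_richness(m)
    rows = []
    for j, unit in enumerate(m.units):
        s = meta[unit]
        rows.append(
            {"sample": unit, "richness": int(richness[j]), "volume": s.volume,
             "rain_prev_day": s.rain_prev_day,
             "catchment_area": s.catchment_area, "year": str(s.year)}
        )
    return pd.DataFrame(rows)


def run_all(cfg: PipelineConfig) -> Path:
    """Simulate the study designs and run every analysis stage.

    Returns the output directory. Artifacts: detections/samples/cameras
    tables, ``truth.csv``, ``detection_estimates.csv``,
    ``model_selection.csv``, ``coefficients.csv``, ``curves.csv``,
    ``diversity_summary.csv``, ``accumulation.csv``, ``cost_curves.csv``,
    ``comparisons.csv``, ``manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": []}

    logger.info("[simulate] generating community and surveys")
    community = synthetic_landscape.generate_community(
        cfg.n_species, seed=_subseed(cfg.seed, 0),
        beta_rain=0.02, beta_area=0.15,
    )
    community.truth_frame().to_csv(out / "truth.csv", index=False)

    scenarios = {name: getattr(synthetic_landscape, name)() for name in cfg.scenarios}
    surveys: dict[str, dict] = {}
    for si, (name, scn) in enumerate(scenarios.items()):
        m_true, samples = synthetic_landscape.simulate_edna(
            community, scn, seed=_subseed(cfg.seed, 1, si))
        motus = synthetic_landscape.simulate_motu_table(
            m_true, samples, seed=_subseed(cfg.seed, 2, si))
        cams = synthetic_landscape.simulate_cameras(
            community, scn, seed=_subseed(cfg.seed, 3, si))
        io_schemas.write_samples(samples, out / f"samples_{scn.year}.csv")
        io_schemas.write_cameras(cams, out / f"cameras_{scn.year}.csv")
        motu_filtering.write_motu_table(motus, out / f"motus_{scn.year}.tsv")
        surveys[name] = {"scenario": scn, "samples": samples,
                         "motus": motus, "cameras": cams}
    manifest["stages"].append("simulate")

    logger.info("[filter-motus] applying the filter chain")
    taxa_meta = {t.name: t for t in community.taxa}
    for name, sv in surveys.items():
        m = motu_filtering.apply_filter_chain(
            sv["motus"], sv["samples"],
            similarity_threshold=cfg.similarity_threshold,
            tag_jump_freq=cfg.tag_jump_freq, taxa_meta=taxa_meta)
        sv["edna_matrix"] = m
        io_schemas.write_detection_matrix(
            m, out / f"detections_{sv['scenario'].year}.tsv")
    manifest["stages"].append("filter-motus")

    logger.info("[estimate-detection] posterior detection probabilities")
    all_estimates = []
    for name, sv in surveys.items():
        scn = sv["scenario"]
        method = f"edna_{scn.design}"
        sv["edna_estimates"] = detection_model.estimate_all(
            sv["edna_matrix"], method=method, year=scn.year,
            prior=cfg.prior, cfg=cfg.mcmc)
        cam_matrix = detection_model.camera_detection_matrix(
            sv["cameras"], taxa_meta=taxa_meta)
        sv["camera_matrix"] = cam_matrix
        sv["camera_estimates"] = detection_model.estimate_all(
            cam_matrix, method="camera", year=scn.year,
            prior=cfg.prior, cfg=cfg.mcmc)
        all_estimates += sv["edna_estimates"] + sv["camera_estimates"]
    detection_model.estimates_to_frame(all_estimates).to_csv(
        out / "detection_estimates.csv", index=False)
    manifest["stages"].append("estimate-detection")

    logger.info("[fit-models] GLMs with AICc all-subsets selection")
    rich_rows = pd.concat(
        [build_richness_rows(sv["edna_matrix"], sv["samples"])
         for sv in surveys.values()], ignore_index=True)
    rich_spec = covariate_glm.DesignSpec(
        response="site_richness",
        covariates=(
            covariate_glm.Covariate("catchment_area", transform="log"),
            covariate_glm.Covariate("volume"),
            covariate_glm.Covariate("rain_prev_day"),
            covariate_glm.Covariate("year", kind="factor"),
        ),
    )
    rich_sel = covariate_glm.all_subsets(
        rich_spec, rich_rows, rich_rows["richness"].to_numpy())
    tables = [rich_sel.table.assign(model="richness")]
    coef_frames = [
        rich_sel.best_fit.coefficients_frame().assign(model="richness")]

    det_rows = []
    for sv in surveys.values():
        membership = synthetic_landscape.default_membership(
            sv["samples"], sv["cameras"], seed=_subseed(cfg.seed, 4))
        rates = covariate_glm.camera_rates(sv["cameras"], membership)
        rows = build_detection_rows(sv["edna_matrix"], sv["samples"], rates)
        det_rows.append(rows)
    det_rows = pd.concat(det_rows, ignore_index=True)
    det_rows = det_rows[det_rows["diet"].notna()]
    det_spec = covariate_glm.DesignSpec(
        response="detection",
        covariates=(
            covariate_glm.Covariate("camera_rate"),
            covariate_glm.Covariate("volume"),
            covariate_glm.Covariate("rain_prev_day"),
            covariate_glm.Covariate("catchment_area", transform="log"),
            covariate_glm.Covariate("diet", kind="factor",
                                    reference="carnivore"),
            covariate_glm.Covariate("body_mass", transform="log"),
            covariate_glm.Covariate("year", kind="factor"),
        ),
    )
    det_sel = covariate_glm.all_subsets(
        det_spec, det_rows, det_rows["detected"].to_numpy())
    tables.append(det_sel.table.assign(model="detection"))
    coef_frames.append(
        det_sel.best_fit.coefficients_frame().assign(model="detection"))
    pd.concat(tables, ignore_index=True).to_csv(
        out / "model_selection.csv", index=False)
    pd.concat(coef_frames, ignore_index=True).to_csv(
        out / "coefficients.csv", index=False)

    best_covs = {c.name for c in det_sel.best_fit.covariates}
    if "camera_rate" in best_covs:
        curve_fit = det_sel.best_fit
    else:  # guarantee the curves' x-axis covariate is in the plotted model
        curve_fit = covariate_glm.fit_glm(
            det_spec, det_rows, det_rows["detected"].to_numpy())
    level_cov = "diet" if "diet" in {c.name for c in curve_fit.covariates} else None
    if level_cov:
        grid = np.linspace(0.0, 1.0, 21)
        curves = covariate_glm.detection_curves(
            curve_fit, levels=list(curve_fit.factor_levels["diet"]),
            level_covariate="diet", camera_rate_grid=grid,
            extra={"body_mass": 10.0, "year": "2018"}
            if "body_mass" in {c.name for c in curve_fit.covariates} else
            {"year": "2018"},
        )
        curves.to_csv(out / "curves.csv", index=False)
    manifest["stages"].append("fit-models")

    logger.info("[diversity] turnover and bootstrap accumulation")
    div_rows, acc_frames, cost_frames = [], [], []
    costs = {(c.method, c.year): c
             for c in io_schemas.read_cost_model_frame(PUBLISHED_COSTS)}
    for name, sv in surveys.items():
        scn = sv["scenario"]
        for label, matrix, method in (
            (f"edna_{scn.design}_{scn.year}", sv["edna_matrix"], "edna"),
            (f"camera_{scn.year}", sv["camera_matrix"], "camera"),
        ):
            summ = diversity_cost.turnover(matrix)
            div_rows.append({"survey": label, "gamma": summ.gamma,
                             "alpha_bar": summ.alpha_bar,
                             "turnover": summ.turnover})
            ac = diversity_cost.bootstrap_accumulation(
                matrix, n_iter=cfg.bootstrap_iters,
                seed=_subseed(cfg.seed, 5, hash(label) % 1000))
            acc_frames.append(ac.to_frame(method=label, year=scn.year))
            cost = costs.get((method, scn.year))
            if cost is not None:
                cc = diversity_cost.cost_curve(ac, cost)
                cost_frames.append(cc.to_frame().assign(survey=label))
    pd.DataFrame(div_rows).to_csv(out / "diversity_summary.csv", index=False)
    pd.concat(acc_frames, ignore_index=True).to_csv(
        out / "accumulation.csv", index=False)
    pd.concat(cost_frames, ignore_index=True).to_csv(
        out / "cost_curves.csv", index=False)
    manifest["stages"].append("diversity")
    manifest["stages"].append("cost-curves")

    logger.info("[compare] between-survey regressions")
    names = list(surveys)
    pairs = {}
    if len(names) == 2:
        a, b = surveys[names[0]], surveys[names[1]]
        pairs["edna_2018_vs_edna_2019"] = (
            a["edna_estimates"], b["edna_estimates"], False)
        pairs["camera_2018_vs_camera_2019"] = (
            a["camera_estimates"], b["camera_estimates"], True)
        pairs["camera_2018_vs_edna_2018"] = (
            a["camera_estimates"], a["edna_estimates"], True)
        pairs["camera_2019_vs_edna_2019"] = (
            b["camera_estimates"], b["edna_estimates"], True)
    cmp_mod.compare_surveys(pairs).to_csv(out / "comparisons.csv", index=False)
    manifest["stages"].append("compare")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("run complete: %s", out)
    return out
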