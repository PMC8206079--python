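"""Shared paths, seed and helpers for the numbered analysis scripts."""

from pathlib import Path

import pandas as pd

from streamdna.io_schemas import Taxon

SEED = 1
DATA_DIR = Path("results/data")
OUT_DIR = Path("results")
YEARS = (2018, 2019)

# cloglog-scale covariate effects used by the simulated landscape
BETA_RAIN = 0.02   # per mm of rain the previous day
BETA_AREA = 0.15   # per log(catchment km2 / 100)


def load_taxa_meta(path: Path | None = None) -> dict[str, Taxon]:
    """Rebuild Taxon metadata from the simulated ground-truth table."""
    truth = pd.read_csv(path or DATA_DIR / "truth.csv")
    return {
        r.taxon: Taxon(name=r.taxon, group=r.group, diet=r.diet,
                       body_mass=r.body_mass,
                       camera_detectable=bool(r.camera_detectable))
        for r in truth.itertuples(index=False)
    }
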