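"""Between-year and between-method agreement of detection probabilities.

Regresses paired per-taxon estimates (camera 2018 vs 2019, eDNA spatial vs
catchment, camera vs eDNA within each year) and reports slope, intercept
and R^2 for each pair.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import OUT_DIR, load_taxa_meta

from streamdna.comparison import compare_surveys
from streamdna.detection_model import DetectionEstimate


def load_estimates() -> dict[tuple[str, int], list[DetectionEstimate]]:
    taxa_meta = load_taxa_meta()
    df = pd.read_csv(OUT_DIR / "detection_estimates.csv")
    out: dict[tuple[str, int], list[DetectionEstimate]] = {}
    for r in df.itertuples(index=False):
        est = DetectionEstimate(
            taxon=taxa_meta[r.taxon], method=r.method, year=int(r.year),
            p60_mean=float(r.p60_mean),
            p60_ci=(float(r.ci_low), float(r.ci_high)),
            n_units=int(r.n_units))
        out.setdefault((r.method, int(r.year)), []).append(est)
    return out


def main() -> None:
    by_survey = load_estimates()
    pairs = {
        "camera_2018_vs_camera_2019":
            (by_survey[("camera", 2018)], by_survey[("camera", 2019)], True),
        "edna_spatial_vs_edna_catchment":
            (by_survey[("edna_spatial", 2018)],
             by_survey[("edna_catchment", 2019)], False),
        "camera_2018_vs_edna_spatial":
            (by_survey[("camera", 2018)],
             by_survey[("edna_spatial", 2018)], True),
        "camera_2019_vs_edna_catchment":
            (by_survey[("camera", 2019)],
             by_survey[("edna_catchment", 2019)], True),
    }
    table = compare_surveys(pairs)
    table.to_csv(OUT_DIR / "comparisons.csv", index=False)
    print(table.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
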