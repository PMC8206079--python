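import numpy as np
import pytest

from streamdna.io_schemas import DetectionMatrix, Taxon, WaterSample


@pytest.fixture
def toy_matrix() -> DetectionMatrix:
    """2 taxa x 3 samples with heterogeneous effort (litres)."""
    taxa = [
        Taxon(name="Alces alces", group="ungulates", diet="herbivore",
              body_mass=380.0),
        Taxon(name="Myotis sp", rank="genus", group="bats", diet="carnivore",
              body_mass=0.01, camera_detectable=False),
    ]
    return DetectionMatrix(
        taxa=taxa,
        units=["s1", "s2", "s3"],
        effort=np.array([30.0, 60.0, 80.0]),
        y=np.array([[1, 0, 1], [0, 1, 0]]),
    )


@pytest.fixture
def water_samples() -> list[WaterSample]:
    return [
        WaterSample(sample_id=f"s{i+1}", site_id=f"site{i+1}", year=2018,
                    design="spatial", volume=v, rain_prev_day=r,
                    catchment_area=a)
        for i, (v, r, a) in enumerate([(30.0, 0.0, 50.0),
                                       (60.0, 5.0, 120.0),
                                       (80.0, 12.0, 600.0)])
    ]


def random_detection_matrix(seed: int, n_taxa: int = 8,
                            n_units: int = 12) -> DetectionMatrix:
    """Random binary matrix with at least one detection overall."""
    rng = np.random.default_rng(seed)
    while True:
        y = (rng.uniform(size=(n_taxa, n_units)) < rng.uniform(0.1, 0.7)).astype(int)
        if y.any():
            break
    taxa = [Taxon(name=f"T{i:02d}") for i in range(n_taxa)]
    effort = rng.choice([30.0, 60.0, 90.0], size=n_units)
    return DetectionMatrix(taxa=taxa, units=[f"u{j:02d}" for j in range(n_units)],
                           effort=effort, y=y)
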