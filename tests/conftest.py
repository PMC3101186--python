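import numpy as np
import pandas as pd
import pytest

from snpqc.containers import AlleleFrequencyMatrix, GenotypeMatrix, IntensityMatrix
from snpqc.simulation import synth_population


def make_annotation(n, chromosome="1", array_label="Nsp", prefix="rs"):
    return pd.DataFrame(
        {
            "snp_id": [f"{prefix}{i + 1}" for i in range(n)],
            "chromosome": chromosome,
            "position_bp": np.arange(1, n + 1) * 10_000,
            "array_label": array_label,
        }
    )


@pytest.fixture
def toy_annotation():
    return make_annotation(4)


@pytest.fixture
def toy_genotypes(toy_annotation):
    calls = pd.DataFrame(
        {
            "s1": ["AA", "AB", "BB", "NC"],
            "s2": ["AB", "AB", "AA", "BB"],
            "s3": ["AA", "AB", "AB", "AB"],
        },
        index=toy_annotation["snp_id"],
    )
    return GenotypeMatrix(annotation=toy_annotation, calls=calls)


@pytest.fixture
def toy_af(toy_annotation):
    af = pd.DataFrame(
        {
            "s1": [0.95, 0.52, 0.04, np.nan],
            "s2": [0.49, 0.47, 0.93, 0.06],
            "s3": [0.97, 0.55, 0.51, 0.50],
        },
        index=toy_annotation["snp_id"],
    ).astype(float)
    return AlleleFrequencyMatrix(annotation=toy_annotation, af=af)


@pytest.fixture
def toy_intensities(toy_annotation):
    ia = pd.DataFrame(
        {
            "s1": [100.0, 55.0, 4.0, 20.0],
            "s2": [48.0, 52.0, 95.0, 5.0],
            "s3": [90.0, 60.0, 50.0, 45.0],
        },
        index=toy_annotation["snp_id"],
    )
    ib = pd.DataFrame(
        {
            "s1": [5.0, 50.0, 96.0, 30.0],
            "s2": [50.0, 49.0, 6.0, 80.0],
            "s3": [4.0, 55.0, 52.0, 44.0],
        },
        index=toy_annotation["snp_id"],
    )
    return IntensityMatrix(annotation=toy_annotation, intensity_a=ia, intensity_b=ib)


@pytest.fixture(scope="session")
def small_population():
    """Session-scoped generative parameters for a 200-SNP chromosome."""
    return synth_population(200, seed=12345)
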