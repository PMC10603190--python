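import numpy as np
import pandas as pd
import pytest

from oxbskit.synthgen import (
    AnnotationConfig,
    ConversionModel,
    ImplantSpec,
    generate_annotation,
    generate_true_methylome,
)

# Per-library values printed in the study's QC tables; used as worked-example
# inputs throughout the QC tests.
WGBS_DEPTHS = [27.54, 27.48, 27.43, 30.14, 27.34, 27.33, 33.81, 28.50]
OXWGBS_DEPTHS = [30.57, 29.47, 30.86, 28.68, 28.17, 27.39, 28.22, 28.35]
WGBS_C_RATES = [99.35, 99.35, 99.37, 99.28, 99.31, 99.29, 99.38, 99.32]
OXWGBS_C_RATES = [99.37, 99.42, 99.39, 99.45, 99.41, 99.37, 99.46, 99.39]
OXWGBS_HMC_RATES = [96.52, 96.39, 96.57, 96.56, 96.78, 96.43, 96.56, 96.31]


@pytest.fixture(scope="session")
def small_annotation():
    cfg = AnnotationConfig(
        chrom_sizes={"chrA": 200_000, "chrB": 200_000},
        n_genes=20,
        n_intergenic_cgis=3,
    )
    return generate_annotation(cfg, seed=101)


@pytest.fixture(scope="session")
def flat_truth(small_annotation):
    """Truth methylome with no implants."""
    return generate_true_methylome(small_annotation, [], seed=202)


@pytest.fixture(scope="session")
def default_model():
    return ConversionModel()


def make_counts(chrom, positions, unconverted, total):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "unconverted": unconverted,
            "total": total,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
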