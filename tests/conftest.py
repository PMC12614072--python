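import warnings

import pytest

from rpsubtype import (
    SyntheticSpec,
    filter_genes,
    fit_ensemble,
    generate_expression,
    to_log2tpm,
)

# libsvm's built-in probability calibration is used deliberately (see
# ensemble module); silence sklearn's deprecation chatter in test output.
warnings.filterwarnings("ignore", message="The `probability` parameter")


@pytest.fixture(scope="session")
def small_data():
    """A well-separated 3-class counts cohort exercising the full pipeline."""
    return generate_expression(
        SyntheticSpec(
            n_genes=600,
            class_sizes=(30, 20, 12),
            markers_per_class=15,
            effect_size=3.0,
            noise_sd=0.8,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_log2(small_data):
    X = filter_genes(small_data.expression)
    return to_log2tpm(X, small_data.gene_lengths)


@pytest.fixture(scope="session")
def small_model(small_log2, small_data):
    return fit_ensemble(small_log2, small_data.labels, d=50, M=3, seed=7)
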