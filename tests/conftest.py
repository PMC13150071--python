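import numpy as np
import pandas as pd
import pytest

from attnomics.containers import OmicsMatrix
from attnomics.synthdata import (
    SynthOmicsParams,
    generate_clinical,
    generate_metabolome,
    generate_transcriptome,
)


@pytest.fixture(scope="session")
def metabolome_planted():
    """Small planted metabolome: 2x20 samples, 120 features, 8 planted."""
    params = SynthOmicsParams(n_per_group=20, n_features=120, n_planted=8,
                              effect_shift_sd=1.5, n_high_missing=4, seed=11)
    return generate_metabolome(params)


@pytest.fixture(scope="session")
def transcriptome_planted():
    """Small planted transcriptome: 2x20 samples, 400 genes, 12 planted."""
    params = SynthOmicsParams(n_per_group=20, n_features=400, n_planted=12,
                              effect_log2fc=2.0, seed=12)
    return generate_transcriptome(params)


@pytest.fixture(scope="session")
def clinical_table():
    return generate_clinical(400, seed=13)


def toy_matrix(values, modality="metabolome", groups=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    idx = [f"S{i}" for i in range(n)]
    cols = [f"f{j}" for j in range(p)]
    labels = None
    if groups is not None:
        labels = pd.Series(groups, index=idx)
    return OmicsMatrix(values=pd.DataFrame(values, index=idx, columns=cols),
                       modality=modality, group_labels=labels)
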