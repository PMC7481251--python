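import numpy as np
import pandas as pd
import pytest

from txsig import (
    DesignSpec,
    TranscriptAnnotation,
    ToySpec,
    default_signature,
    generate_multimuscle,
    generate_toy,
)


@pytest.fixture(scope="session")
def toy():
    """Seeded 26-gene x 3-sample toy matrix with truth labels."""
    return generate_toy(ToySpec())


@pytest.fixture(scope="session")
def small_multimuscle():
    """Down-scaled multi-muscle simulation (500 genes) for fast tests."""
    design = DesignSpec(n_genes=500)
    planted = default_signature(design, n_up=25, n_down=25)
    return generate_multimuscle(design, planted, noise_sd=0.3, seed=1)


@pytest.fixture()
def annotation():
    return TranscriptAnnotation(
        pd.DataFrame(
            {
                "transcript_id": ["t1", "t2", "t3", "t4"],
                "gene_id": ["gA", "gA", "gB", "gC"],
                "length": [1000, 2000, 500, 1500],
            }
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
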