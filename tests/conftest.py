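import pandas as pd
import pytest

from chromocline import synth


@pytest.fixture(scope="session")
def study_karyotype() -> synth.Karyotype:
    """Default 51-chromosome karyotype with the X anchored at 21 Mb."""
    return synth.simulate_karyotype(51, 3.97e6, 185e6, 40, seed=1, x_len=21e6)


@pytest.fixture(scope="session")
def default_params() -> synth.ClineParams:
    return synth.ClineParams()


@pytest.fixture(scope="session")
def default_gene_table(study_karyotype, default_params) -> pd.DataFrame:
    """One default-condition gene rate table, reused by read-only tests."""
    return synth.simulate_gene_rates(
        study_karyotype, default_params, genes_per_mb=3.6, seed=99, n_codons=500
    )
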