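import pytest

from chromcouple import (
    SimParams,
    differential_genes,
    make_calls,
    normalize_library,
    promoter_signal_table,
    simulate_dataset,
)
from chromcouple.simulate import COND_MINUS, COND_PLUS


@pytest.fixture(scope="session")
def bundle():
    """One default-condition synthetic bundle shared across tests."""
    return simulate_dataset(SimParams(seed=1))


@pytest.fixture(scope="session")
def analysis(bundle):
    """The bundle pushed through normalization, classification and DE."""
    normalized = {k: normalize_library(t) for k, t in bundle.tracks.items()}
    signal = promoter_signal_table(normalized, bundle.genes)
    calls = make_calls(
        signal[f"H3K4me3_{COND_MINUS}"],
        signal[f"H3K27me3_{COND_MINUS}"],
        signal[f"H3K27me3_{COND_PLUS}"],
    )
    de = differential_genes(bundle.expression, COND_MINUS, COND_PLUS)
    return {"signal": signal, "calls": calls, "de": de}
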