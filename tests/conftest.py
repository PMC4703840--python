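import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from rewirescope import simulate
from rewirescope.diffexpr import de_analysis


@pytest.fixture(scope="session")
def default_study():
    """The full-scale synthetic study at a fixed seed."""
    network, designs, params, truth_info = simulate.default_study(seed=0)
    matrix, true_fc, true_deg = simulate.simulate_rewired_experiment(network, designs, params)
    return {
        "network": network,
        "designs": designs,
        "params": params,
        "truth_info": truth_info,
        "matrix": matrix,
        "true_fc": true_fc,
        "true_deg": true_deg,
    }


@pytest.fixture(scope="session")
def estimated_fc(default_study):
    """Estimated log2FC matrix (genes x constructs) from the DE stage."""
    matrix = default_study["matrix"]
    cols = {c: de_analysis(matrix, c).table["log2fc"] for c in matrix.constructs()}
    return pd.DataFrame(cols)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast structural tests."""
    network, designs, params, truth_info = simulate.default_study(
        seed=11, n_genes=400, n_constructs=30
    )
    matrix, true_fc, true_deg = simulate.simulate_rewired_experiment(network, designs, params)
    return {
        "network": network,
        "designs": designs,
        "params": params,
        "truth_info": truth_info,
        "matrix": matrix,
        "true_fc": true_fc,
        "true_deg": true_deg,
    }
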