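import numpy as np
import pandas as pd
import pytest

from a3ge.panel import PanelSpec, make_panel
from a3ge.simulate import DriftParams, GroupSpec, simulate_expression


@pytest.fixture(scope="session")
def default_panel():
    return make_panel(PanelSpec(), seed=1)


@pytest.fixture(scope="session")
def small_panel():
    return make_panel(PanelSpec(n_genes=20, n_amplicons=30), seed=7)


def tcell_groups(m_wo=0.7071, m_ho=0.5, n_rep=4):
    """Young reference plus two drifting old groups (wild-type and HD)."""
    return [
        GroupSpec("wy", "tcell", "wt", 2.0, n_rep, 1.0, 0.0),
        GroupSpec("wo", "tcell", "wt", 19.0, n_rep, m_wo),
        GroupSpec("ho", "tcell", "hd", 19.0, n_rep, m_ho),
    ]


@pytest.fixture(scope="session")
def tcell_latent(default_panel):
    return simulate_expression(
        default_panel, tcell_groups(), DriftParams(), seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_counts(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "amplicon_id", "mouse_reads", "rat_reads"]
    )
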