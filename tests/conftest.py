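import numpy as np
import pytest

from paleoproj.panel import FrequencyPanel, GenotypeMatrix, Marker
from paleoproj.projection import ProjectionOptions
from paleoproj.simulate import SimulationConfig, simulate_individuals, simulate_panel


@pytest.fixture
def toy_opts():
    """Projection options permissive enough for hand-sized instances."""
    return ProjectionOptions(min_markers=1)


@pytest.fixture
def tiny_panel():
    """Two ancestries, four well-separated non-ambiguous markers."""
    markers = [
        Marker("m1", "1", 100, "A", "G"),
        Marker("m2", "1", 200, "C", "T"),
        Marker("m3", "2", 50, "G", "A"),
        Marker("m4", "2", 150, "T", "C"),
    ]
    freqs = np.array([
        [0.9, 0.8, 0.7, 0.6],
        [0.1, 0.2, 0.3, 0.4],
    ])
    return FrequencyPanel(markers=markers, ancestries=["anc1", "anc2"], freqs=freqs)


@pytest.fixture
def tiny_genotypes(tiny_panel):
    dosages = np.array([
        [2.0, 1.0, 0.0, np.nan],
        [0.0, 2.0, 2.0, 1.0],
    ])
    return GenotypeMatrix(
        individuals=["indA", "indB"],
        markers=list(tiny_panel.markers),
        dosages=dosages,
    )


@pytest.fixture(scope="session")
def sim_truth_small():
    """A moderately sized simulated cohort reused across tests (K=3)."""
    panel = simulate_panel(K=3, M=3000, fst=0.1, seed=41)
    cfg = SimulationConfig(K=3, M=3000, fst=0.1, n_individuals=6,
                           dirichlet_alpha=5.0, missing_rate=0.1, seed=42)
    return simulate_individuals(panel, cfg)
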