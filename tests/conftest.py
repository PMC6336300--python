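import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stemscan as ss

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def coarse_config():
    """Fast lattice for simulation-backed tests (0.25 deg steps)."""
    return ss.ScannerConfig(delta_theta=0.25, delta_phi=0.25, range_accuracy_sigma=0.0)


@pytest.fixture(scope="session")
def single_stem_scene(coarse_config):
    """One bare vertical stem (no taper, no crown) on flat ground, noiseless."""
    stem = ss.StemModel(x=5.0, y=0.0, dbh=0.12, height=8.0, taper=0.0)
    plot = ss.SyntheticPlot(extent=14.0, stems=[stem], ground=ss.GroundModel())
    records, truth = ss.simulate_scan(
        plot, scanner_pos=(0.0, 0.0, 1.5), config=coarse_config, seed=0
    )
    return plot, records, truth


def circle_points(xc, yc, r, n=24, arc=(0.0, 2 * np.pi)):
    t = np.linspace(arc[0], arc[1], n, endpoint=abs(arc[1] - arc[0]) < 2 * np.pi)
    return np.column_stack([xc + r * np.cos(t), yc + r * np.sin(t)])
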