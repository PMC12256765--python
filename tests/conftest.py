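import numpy as np
import pytest

from hnbseq import ParamSet, SimDesign, simulate_gene


@pytest.fixture(scope="session")
def three_level_est() -> ParamSet:
    """Three-level estimates for the worked single-gene example."""
    return ParamSet(
        beta=[-15.4384, 0.7496, 0.5154, 0.3257],
        phi=0.5112,
        sigma_s=0.2236,
        sigma_i=0.2321,
    )


@pytest.fixture(scope="session")
def two_level_est() -> ParamSet:
    """Two-level estimates for the worked single-gene example."""
    return ParamSet(
        beta=[-15.4349, 0.7468, 0.4985, 0.3245], phi=0.5108, sigma_s=0.3154
    )


@pytest.fixture(scope="session")
def control_x() -> np.ndarray:
    """Covariate vector of a control sample (all visit indicators 0)."""
    return np.array([1.0, 0.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def small_gene():
    """A small two-level gene: 4 patients x 3 visits + 3 controls, 5 exons."""
    params = ParamSet(beta=[-15.0, 0.6, 0.3, 0.1], phi=0.8, sigma_s=0.35)
    design = SimDesign(
        params=params, levels="two", n_patients=4, n_controls=3, n_exons=5, seed=123
    )
    return simulate_gene(design)


@pytest.fixture(scope="session")
def study_design_gene():
    """One gene at the full study layout (29 patients x 3 + 13 controls)."""
    params = ParamSet(beta=[-15.4, 0.75, 0.50, 0.32], phi=0.51, sigma_s=0.32)
    return simulate_gene(SimDesign(params=params, levels="two", seed=321))
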