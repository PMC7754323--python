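import pytest

from pseudoipd.datasets import load_hypertension
from pseudoipd.generate import generate_dataset
from pseudoipd.simulate import SimScenario, simulate_ipd, summarize_to_ad


@pytest.fixture(scope="session")
def hyp_balanced():
    return load_hypertension()


@pytest.fixture(scope="session")
def hyp_imbalanced():
    return load_hypertension(imbalanced=True)


@pytest.fixture(scope="session")
def hyp_ipd(hyp_balanced):
    return generate_dataset(hyp_balanced, seed=1)


@pytest.fixture(scope="session")
def hyp_ipd_imbalanced(hyp_imbalanced):
    return generate_dataset(hyp_imbalanced, seed=1)


@pytest.fixture(scope="session")
def small_scenario():
    """A modest 4-study scenario with interaction and free residuals."""
    return SimScenario(
        n_studies=4,
        n_per_arm=[40, 60, 35, 80],
        mu_baseline=[150, 160, 155, 170],
        sigma_baseline=[12, 15, 10, 9],
        beta0=[140, 150, 148, 158],
        beta1=-8.0,
        beta2=[0.5, 0.6, 0.4, 0.55],
        beta3=-0.1,
        beta4=0.05,
        tau1_sq=4.0,
        tau3_sq=0.01,
        interaction=True,
        residual_structure="by_study_arm",
        residuals=[(14, 12), (16, 15), (13, 12), (15, 14)],
        seed=42,
    )


@pytest.fixture(scope="session")
def small_true_ipd(small_scenario):
    return simulate_ipd(small_scenario)


@pytest.fixture(scope="session")
def small_pseudo_ipd(small_true_ipd):
    return generate_dataset(summarize_to_ad(small_true_ipd), seed=7)
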