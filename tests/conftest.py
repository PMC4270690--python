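import numpy as np
import pytest

from mhcfinemap.encoding import encode_cohort
from mhcfinemap.simulate import simulate_cohort, study_preset


@pytest.fixture(scope="session")
def study_sim():
    """One simulated study cohort (365 cases / 368 controls), shared."""
    return simulate_cohort(study_preset(seed=11))


@pytest.fixture(scope="session")
def study_manifest(study_sim):
    """Encoded manifest (SNPs + HLA-derived variables) of the shared cohort."""
    matrix, descriptors, summary = encode_cohort(
        study_sim.records, (study_sim.snp_matrix, study_sim.snp_descriptors)
    )
    return matrix, descriptors, summary


def newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                    tol: float = 1e-12) -> np.ndarray:
    """Independent Newton-Raphson logistic MLE used as a test oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta
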