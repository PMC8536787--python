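import numpy as np
import pytest

from nbdeconv import ReferencePanel, build_reference, generate_synthetic_reference


@pytest.fixture(scope="session")
def small_ref():
    """Synthetic 4-type reference with recorded truth, shared across tests."""
    return generate_synthetic_reference(
        n_genes=300, n_types=4, cells_per_type=80, seed=11
    )


@pytest.fixture(scope="session")
def small_panel(small_ref):
    ref, _ = small_ref
    return build_reference(ref, top_n=80)


def make_panel(mu: np.ndarray) -> ReferencePanel:
    """Minimal valid panel with prescribed mean profiles (Poisson-flagged)."""
    mu = np.asarray(mu, dtype=float)
    I, K = mu.shape
    return ReferencePanel(
        selected_genes=[f"g{i}" for i in range(I)],
        cell_types=[f"t{k}" for k in range(K)],
        mu=mu,
        var=mu.copy(),
        dispersion=np.zeros_like(mu),
        success_prob=np.zeros_like(mu),
        specificity_weight=np.ones(I),
        fit_flag=np.full((I, K), "poisson_fallback", dtype=object),
        gene_mode="markers",
    )
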