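import numpy as np
import pandas as pd
import pytest

from longsig.datasets import fixture_tree
from longsig.normalization import ExpressionMatrix
from longsig.phylo import CovModel, covariance_matrix


@pytest.fixture(scope="session")
def tree14():
    return fixture_tree()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def simulate_stationary_ou(tree, alpha, sigma2, n_genes, rng):
    """Stationary-OU gene draws on a tree, as a standardized-stage matrix."""
    V = covariance_matrix(tree, CovModel("ou", sigma2=sigma2, alpha=alpha))
    L = np.linalg.cholesky(V)
    Z = (L @ rng.standard_normal((tree.n_taxa, n_genes))).T
    genes = [f"g{i:05d}" for i in range(n_genes)]
    return ExpressionMatrix(pd.DataFrame(Z, index=genes, columns=tree.taxa),
                            stage="standardized")


def simulate_bm(tree, sigma2, n_genes, rng):
    V = covariance_matrix(tree, CovModel("bm", sigma2=sigma2))
    L = np.linalg.cholesky(V)
    return (L @ rng.standard_normal((tree.n_taxa, n_genes))).T
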