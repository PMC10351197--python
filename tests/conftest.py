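import numpy as np
import pytest

import admixscan as ax


@pytest.fixture(scope="session")
def small_cohort():
    """400-sample cohort with one planted NAM ancestry effect at region 5."""
    cfg = ax.SimConfig(
        n_samples=400, n_regions=20, n_snvs=40, seed=11,
        sib_pair_fraction=0.2, ancestry_effects=[(5, "NAM", -0.6)],
    )
    return ax.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Null REML fit of the planted-signal metabolite (global-ancestry mode)."""
    c = small_cohort
    prepped, _ = ax.prepare_metabolites(c.phenotypes)
    design = ax.build_design(
        c.covariates, covariate_mode="global_ancestry",
        global_ancestry=ax.global_from_local(c.calls),
    )
    fit = ax.AncestryLMM(prepped.iloc[:, 0].to_numpy(), design,
                         c.structure).fit()
    assert fit.converged
    return fit


def dense_gls_oracle(structure, sigmas, X, W, y, extra=None):
    """Independent brute-force GLS Wald test with an explicit dense V."""
    n = structure.n_samples
    Zh = structure.cluster_indicator(structure.household).toarray()
    Zc = structure.cluster_indicator(structure.block).toarray()
    V = (sigmas[0] * 2 * structure.kinship.toarray()
         + sigmas[1] * Zh @ Zh.T + sigmas[2] * Zc @ Zc.T
         + sigmas[3] * np.eye(n))
    Vi = np.linalg.inv(V)
    cols = [X] if extra is None else [X, extra]
    A = np.column_stack(cols + [W])
    cov = np.linalg.inv(A.T @ Vi @ A)
    beta = cov @ A.T @ Vi @ y
    k = W.shape[1] if W.ndim == 2 else 1
    g = beta[-k:]
    cg = cov[-k:, -k:]
    stat = float(g @ np.linalg.solve(cg, g))
    return stat, g, cov
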