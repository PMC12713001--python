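import numpy as np
import pytest

import msrlearner as m


def simple_multistudy(n_k=(60, 80), p=3, seed=0, tau_consts=None, e_consts=None,
                      sigma=0.5):
    """Small synthetic multi-study dataset with linear baselines and constant CATEs."""
    rng = np.random.default_rng(seed)
    K = len(n_k)
    tau_consts = tau_consts if tau_consts is not None else np.linspace(1.0, -1.0, K)
    e_consts = e_consts if e_consts is not None else np.full(K, 0.5)
    alpha = rng.standard_normal(p) * 0.5
    Xs, Ss, As, Ys = [], [], [], []
    for k in range(K):
        X = rng.standard_normal((n_k[k], p)) + 0.3 * k
        A = (rng.random(n_k[k]) < e_consts[k]).astype(int)
        Y = X @ alpha + A * tau_consts[k] + rng.normal(0, sigma, n_k[k])
        Xs.append(X)
        Ss.append(np.full(n_k[k], k + 1))
        As.append(A)
        Ys.append(Y)
    return m.MultiStudyDataset(y=np.concatenate(Ys), a=np.concatenate(As),
                               s=np.concatenate(Ss), X=np.vstack(Xs))


@pytest.fixture
def two_study():
    return simple_multistudy()


@pytest.fixture
def ols_learner():
    return m.LearnerSpec("regression", "ols", "none")


@pytest.fixture
def logistic_learner():
    return m.LearnerSpec("binary-probability", "logistic", "none")


def manual_nuisances(dataset, m_k, e_k, p_k, membership=None):
    """Build a NuisanceSet directly from (n, K) arrays, bypassing clipping."""
    ns = m.NuisanceSet(
        m_k_cross=np.asarray(m_k, float),
        e_k_cross=np.asarray(e_k, float),
        p_cross=np.asarray(p_k, float),
        m_pooled=np.einsum("nk,nk->n", np.asarray(m_k, float), np.asarray(p_k, float)),
        membership=membership,
    )
    return ns
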