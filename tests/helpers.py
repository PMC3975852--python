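"""Independent oracles used by the tests: kept deliberately naive."""

import numpy as np


def tabular_a(sire, dam):
    """Dense numerator relationship matrix by the recursive tabular method.

    Requires parents (index -1 = unknown) to precede offspring.
    """
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a_js = A[j, s] if s >= 0 else 0.0
            a_jd = A[j, d] if d >= 0 else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jd)
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def gls_blup_st(K, rec_idx, y, sg2, se2):
    """Closed-form single-trait BLUP: GLS intercept, then conditional means."""
    rec_idx = np.asarray(rec_idx)
    V = K[np.ix_(rec_idx, rec_idx)] * sg2 + np.eye(rec_idx.size) * se2
    Vi = np.linalg.inv(V)
    one = np.ones(rec_idx.size)
    mu = (one @ Vi @ y) / (one @ Vi @ one)
    ghat = sg2 * K[:, rec_idx] @ Vi @ (y - mu)
    return mu, ghat


def gls_blup_mt(K, unit_animal, Y, H, R):
    """Closed-form two-trait BLUP with missing records, via the full
    multivariate-normal covariance of the observed stack."""
    n_k = K.shape[0]
    obs = [(u, t) for u in range(len(unit_animal)) for t in range(2)
           if not np.isnan(Y[u, t])]
    no = len(obs)
    V = np.zeros((no, no))
    X = np.zeros((no, 2))
    y = np.zeros(no)
    for i, (u, a) in enumerate(obs):
        X[i, a] = 1.0
        y[i] = Y[u, a]
        for j, (v, b) in enumerate(obs):
            V[i, j] = K[unit_animal[u], unit_animal[v]] * H[a, b] + (u == v) * R[a, b]
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    C = np.zeros((n_k * 2, no))
    for j, (v, b) in enumerate(obs):
        for i2 in range(n_k):
            for a in range(2):
                C[i2 * 2 + a, j] = K[i2, unit_animal[v]] * H[a, b]
    ghat = (C @ Vi @ resid).reshape(n_k, 2)
    return beta, ghat


def random_pedigree(n, rng, p_founder=0.15):
    """Random acyclic pedigree in parents-before-offspring order."""
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(2, n):
        if rng.random() > p_founder:
            sire[i] = rng.integers(0, i)
            dam[i] = rng.integers(0, i)
            if dam[i] == sire[i]:
                dam[i] = -1 if i < 3 else (sire[i] + 1) % i
    return sire, dam
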