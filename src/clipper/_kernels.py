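"""Compiled numerical kernels.

Everything the permutation loop touches lives here as numba ``@njit``
functions: shrinkage covariance estimation, iterative proportional scaling
(IPS) on clique blocks, Gaussian profile log-likelihoods and the per-split
test statistics. The public modules wrap these; there is exactly one
implementation of each primitive.

Cliques are passed as a padded int64 matrix ``cl_idx`` (one row per clique,
padded with -1) plus a length vector ``cl_len``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# flat layout of the statistic vector returned by _split_stats
CONC = 0
MEAN_HOMO = 1
MEAN_HETERO = 2
N_GLOBAL = 3  # per-clique stats follow: nc concentration then nc mean


@njit(cache=True)
def _center(X):
    n, p = X.shape
    mu = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j]
        mu[j] = s / n
    Xc = np.empty_like(X)
    for i in range(n):
        for j in range(p):
            Xc[i, j] = X[i, j] - mu[j]
    return Xc, mu


@njit(cache=True)
def _shrunk_from_centered(Xc):
    """James-Stein-type shrinkage toward the diagonal of S.

    Off-diagonal entries of the unbiased sample covariance are damped by the
    analytically estimated optimal intensity (sum of estimated variances of
    the off-diagonal entries over their sum of squares), clipped to [0, 1];
    variances are left untouched.
    """
    n, p = Xc.shape
    S = np.dot(Xc.T.copy(), Xc) / (n - 1.0)
    if p == 1:
        return S, 0.0
    num = 0.0
    den = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            wbar = S[i, j] * (n - 1.0) / n
            v = 0.0
            for k in range(n):
                w = Xc[k, i] * Xc[k, j]
                v += (w - wbar) ** 2
            num += v * n / ((n - 1.0) ** 3)
            den += S[i, j] * S[i, j]
    if den <= 1e-300:
        lam = 1.0
    else:
        lam = num / den
        if lam > 1.0:
            lam = 1.0
        elif lam < 0.0:
            lam = 0.0
    Sh = S * (1.0 - lam)
    for i in range(p):
        Sh[i, i] = S[i, i]
    return Sh, lam


@njit(cache=True)
def _ips(S, cl_idx, cl_len, tol, max_iter):
    """IPS for a graph-constrained Gaussian: match S on every clique block.

    Starts from the independence model K = diag(1/S_ii); each clique step
    adds inv(S_CC) - inv(Sigma_CC) to the K block, which makes the fitted
    covariance agree with S on that clique while keeping zeros elsewhere.
    Stops when the fitted covariance changes by less than ``tol`` (max abs
    entry) over a full sweep.
    """
    p = S.shape[0]
    K = np.zeros((p, p))
    for i in range(p):
        K[i, i] = 1.0 / S[i, i]
    Sigma = np.linalg.inv(K)
    nc = cl_idx.shape[0]
    conv = False
    it = 0
    delta = 1e300
    for sweep in range(max_iter):
        it = sweep + 1
        Sold = Sigma.copy()
        for c in range(nc):
            m = cl_len[c]
            Scc = np.empty((m, m))
            Gcc = np.empty((m, m))
            for a in range(m):
                ia = cl_idx[c, a]
                for b in range(m):
                    ib = cl_idx[c, b]
                    Scc[a, b] = S[ia, ib]
                    Gcc[a, b] = Sigma[ia, ib]
            D = np.linalg.inv(Scc) - np.linalg.inv(Gcc)
            for a in range(m):
                ia = cl_idx[c, a]
                for b in range(m):
                    K[ia, cl_idx[c, b]] += D[a, b]
            Sigma = np.linalg.inv(K)
        delta = 0.0
        for i in range(p):
            for j in range(p):
                dd = abs(Sigma[i, j] - Sold[i, j])
                if dd > delta:
                    delta = dd
        if delta < tol:
            conv = True
            break
    return Sigma, K, it, conv, delta


@njit(cache=True)
def _gauss_ll(K, S, n):
    """Profile log-likelihood (n/2)(log det K - tr(K S)), constant dropped."""
    sign, ld = np.linalg.slogdet(K)
    p = K.shape[0]
    tr = 0.0
    for i in range(p):
        for j in range(p):
            tr += K[i, j] * S[j, i]
    return 0.5 * n * (ld - tr)


@njit(cache=True)
def _gather_cols(X, idx, m):
    n = X.shape[0]
    out = np.empty((n, m))
    for i in range(n):
        for a in range(m):
            out[i, a] = X[i, idx[a]]
    return out


@njit(cache=True)
def _split_stats(X, idx1, idx2, cl_idx, cl_len, tol, max_iter):
    """All test statistics for one assignment of samples to the two classes.

    Returns a vector laid out as [concentration, mean_homo, mean_hetero,
    per-clique concentration stats, per-clique mean stats] and the number of
    IPS fits that failed to converge (out of 4).
    """
    n1 = idx1.shape[0]
    n2 = idx2.shape[0]
    n = n1 + n2
    p = X.shape[1]
    nc = cl_idx.shape[0]

    X1 = np.empty((n1, p))
    for i in range(n1):
        for j in range(p):
            X1[i, j] = X[idx1[i], j]
    X2 = np.empty((n2, p))
    for i in range(n2):
        for j in range(p):
            X2[i, j] = X[idx2[i], j]

    X1c, mu1 = _center(X1)
    X2c, mu2 = _center(X2)
    Xw = np.empty((n, p))
    for i in range(n1):
        for j in range(p):
            Xw[i, j] = X1c[i, j]
    for i in range(n2):
        for j in range(p):
            Xw[n1 + i, j] = X2c[i, j]
    X0c, _ = _center(X)

    S1, _ = _shrunk_from_centered(X1c)
    S2, _ = _shrunk_from_centered(X2c)
    Sw, _ = _shrunk_from_centered(Xw)
    S0, _ = _shrunk_from_centered(X0c)

    Sig1, K1, _, cv1, _ = _ips(S1, cl_idx, cl_len, tol, max_iter)
    Sig2, K2, _, cv2, _ = _ips(S2, cl_idx, cl_len, tol, max_iter)
    SigW, KW, _, cv3, _ = _ips(Sw, cl_idx, cl_len, tol, max_iter)
    Sig0, K0, _, cv4, _ = _ips(S0, cl_idx, cl_len, tol, max_iter)
    nonconv = (0 if cv1 else 1) + (0 if cv2 else 1) + (0 if cv3 else 1) + (0 if cv4 else 1)

    stats = np.empty(N_GLOBAL + 2 * nc)
    stats[CONC] = 2.0 * (
        _gauss_ll(K1, S1, n1)
        + _gauss_ll(K2, S2, n2)
        - (_gauss_ll(KW, S1, n1) + _gauss_ll(KW, S2, n2))
    )
    stats[MEAN_HOMO] = 2.0 * (_gauss_ll(KW, Sw, n) - _gauss_ll(K0, S0, n))

    d = mu1 - mu2
    M = Sig1 / n1 + Sig2 / n2
    stats[MEAN_HETERO] = np.dot(d, np.linalg.solve(M, d))

    # Per-clique tests: complete graph on the clique, shrunken covariances
    # of the clique's sub-data used directly (no IPS needed).
    for c in range(nc):
        m = cl_len[c]
        idx = cl_idx[c, :m]
        A1 = _gather_cols(X1c, idx, m)
        A2 = _gather_cols(X2c, idx, m)
        Aw = np.empty((n, m))
        for i in range(n1):
            for a in range(m):
                Aw[i, a] = A1[i, a]
        for i in range(n2):
            for a in range(m):
                Aw[n1 + i, a] = A2[i, a]
        S1c, _ = _shrunk_from_centered(A1)
        S2c, _ = _shrunk_from_centered(A2)
        Swc, _ = _shrunk_from_centered(Aw)
        K1c = np.linalg.inv(S1c)
        K2c = np.linalg.inv(S2c)
        KWc = np.linalg.inv(Swc)
        stats[N_GLOBAL + c] = 2.0 * (
            _gauss_ll(K1c, S1c, n1)
            + _gauss_ll(K2c, S2c, n2)
            - (_gauss_ll(KWc, S1c, n1) + _gauss_ll(KWc, S2c, n2))
        )
        dc = np.empty(m)
        for a in range(m):
            dc[a] = d[idx[a]]
        Mc = S1c / n1 + S2c / n2
        stats[N_GLOBAL + nc + c] = np.dot(dc, np.linalg.solve(Mc, dc))

    return stats, nonconv


@njit(cache=True)
def _permutation_pvalues(X, labels, B, seed, cl_idx, cl_len, tol, max_iter):
    """Observed statistics and add-one permutation counts for all tests.

    The same seeded permutation stream calibrates every statistic (common
    random numbers). Returns (observed stats vector, counts of permuted
    statistics >= observed, total non-converged IPS fits).
    """
    np.random.seed(seed)
    n = labels.shape[0]
    n1 = 0
    for i in range(n):
        if labels[i] == 0:
            n1 += 1
    idx1 = np.empty(n1, dtype=np.int64)
    idx2 = np.empty(n - n1, dtype=np.int64)
    a = 0
    b = 0
    for i in range(n):
        if labels[i] == 0:
            idx1[a] = i
            a += 1
        else:
            idx2[b] = i
            b += 1

    obs, nonconv = _split_stats(X, idx1, idx2, cl_idx, cl_len, tol, max_iter)
    counts = np.zeros(obs.shape[0], dtype=np.int64)
    perm = np.arange(n)
    for _ in range(B):
        np.random.shuffle(perm)
        p1 = perm[:n1].copy()
        p2 = perm[n1:].copy()
        st, nv = _split_stats(X, p1, p2, cl_idx, cl_len, tol, max_iter)
        nonconv += nv
        for k in range(obs.shape[0]):
            if st[k] >= obs[k]:
                counts[k] += 1
    return obs, counts, nonconv


def cliques_to_arrays(
    cliques: list[tuple[str, ...]], node_index: dict[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pack cliques of gene ids into the padded int64 layout kernels expect."""
    nc = len(cliques)
    width = max(len(c) for c in cliques)
    cl_idx = np.full((nc, width), -1, dtype=np.int64)
    cl_len = np.empty(nc, dtype=np.int64)
    for i, c in enumerate(cliques):
        cl_len[i] = len(c)
        for a, g in enumerate(c):
            cl_idx[i, a] = node_index[g]
    return cl_idx, cl_len
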