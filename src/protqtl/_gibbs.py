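"""Numba kernel for the grouped spike-and-slab Gibbs sampler.

One compiled function runs the whole chain.  Marker columns are visited in
a fresh random order each sweep; the residual vector and per-component
fitted vectors are maintained incrementally so a sweep costs O(n * m).
All randomness flows through numba's Mersenne-Twister state, seeded once,
which makes retained draws bit-reproducible for a fixed seed.

Layout conventions (all arrays are concatenated over groups):
  comp_off[g]:comp_off[g+1]  slab-component slots of group g
  pi_off[g]                  spike slot of group g in the pi vector,
                             followed by its slab components
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(
    X,  # (n, m) float64, Fortran order, standardised columns
    y,  # (n,) float64
    W,  # (n, q) float64 fixed-effect design; q may be 0
    WtWinv,  # (q, q)
    WtWinv_chol,  # (q, q) lower Cholesky of WtWinv
    group_of,  # (m,) int64 group index per marker
    comp_off,  # (G+1,) int64 slab-component offsets
    comp_var,  # (Ktot,) float64 slab variances (fractions of sigma2_g)
    dir_conc,  # (G+Ktot,) float64 Dirichlet concentration, spike first per group
    n_iter,
    burn,
    thin,
    seed,
    update_s2g,  # bool
    update_s2e,  # bool
    update_pi,  # bool
    s2g_init,  # (G,) float64
    s2e_init,  # float64
    nu0,
    s02,
):
    n, m = X.shape
    q = W.shape[1]
    G = comp_off.shape[0] - 1
    Ktot = comp_var.shape[0]
    np.random.seed(seed)

    # pi slot offsets: one spike slot per group followed by its components
    pi_off = np.zeros(G + 1, np.int64)
    for g in range(G):
        pi_off[g + 1] = pi_off[g] + 1 + (comp_off[g + 1] - comp_off[g])
    pi = np.zeros(G + Ktot)
    for g in range(G):
        kg = comp_off[g + 1] - comp_off[g]
        for k in range(kg + 1):
            pi[pi_off[g] + k] = 1.0 / (kg + 1)

    beta = np.zeros(m)
    comp = np.zeros(m, np.int64)  # 0 = spike, else slab index within group
    xx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xx[j] = s
    r = y.copy()
    alpha = np.zeros(q)
    u = np.zeros((Ktot, n))  # per slab-component fitted vectors
    s2g = s2g_init.copy()
    s2e = s2e_init

    my = 0.0
    for i in range(n):
        my += y[i]
    my /= n
    vary = 0.0
    for i in range(n):
        vary += (y[i] - my) ** 2
    vary /= n

    n_draws = 0
    for it in range(n_iter):
        if it >= burn and (it - burn) % thin == 0:
            n_draws += 1
    D = n_draws
    share_draws = np.zeros((D, G))
    comp_share_draws = np.zeros((D, Ktot))
    s2g_draws = np.zeros((D, G))
    s2e_draws = np.zeros(D)
    pi_draws = np.zeros((D, G + Ktot))
    beta_sum = np.zeros(m)
    beta_sq = np.zeros(m)
    pip_cnt = np.zeros(m)

    lw = np.zeros(17)
    d = 0
    for it in range(n_iter):
        # --- fixed effects ---------------------------------------------
        if q > 0:
            for i in range(n):
                acc = 0.0
                for c in range(q):
                    acc += W[i, c] * alpha[c]
                r[i] += acc
            wtr = np.zeros(q)
            for c in range(q):
                acc = 0.0
                for i in range(n):
                    acc += W[i, c] * r[i]
                wtr[c] = acc
            mu_a = WtWinv @ wtr
            z = np.empty(q)
            for c in range(q):
                z[c] = np.random.normal()
            alpha = mu_a + np.sqrt(s2e) * (WtWinv_chol @ z)
            for i in range(n):
                acc = 0.0
                for c in range(q):
                    acc += W[i, c] * alpha[c]
                r[i] -= acc

        # --- markers, randomized order ---------------------------------
        perm = np.random.permutation(m)
        for t in range(m):
            j = perm[t]
            g = group_of[j]
            kg = comp_off[g + 1] - comp_off[g]
            b_old = beta[j]
            k_old = comp[j]
            rhs = b_old * xx[j]
            for i in range(n):
                rhs += X[i, j] * r[i]
            lw[0] = np.log(pi[pi_off[g]] + 1e-300)
            best = lw[0]
            for k in range(kg):
                sk = comp_var[comp_off[g] + k] * s2g[g]
                lam = xx[j] / s2e + 1.0 / sk
                val = (
                    np.log(pi[pi_off[g] + 1 + k] + 1e-300)
                    - 0.5 * np.log(sk * lam)
                    + 0.5 * (rhs / s2e) ** 2 / lam
                )
                lw[k + 1] = val
                if val > best:
                    best = val
            tot = 0.0
            for k in range(kg + 1):
                lw[k] = np.exp(lw[k] - best)
                tot += lw[k]
            udraw = np.random.random() * tot
            k_new = kg
            acc = 0.0
            for k in range(kg + 1):
                acc += lw[k]
                if udraw <= acc:
                    k_new = k
                    break
            if k_new == 0:
                b_new = 0.0
            else:
                sk = comp_var[comp_off[g] + k_new - 1] * s2g[g]
                lam = xx[j] / s2e + 1.0 / sk
                mu_b = (rhs / s2e) / lam
                b_new = mu_b + np.random.normal() / np.sqrt(lam)
            if b_new != b_old or k_new != k_old:
                diff = b_old - b_new
                for i in range(n):
                    r[i] += X[i, j] * diff
                if k_old > 0:
                    row = comp_off[g] + k_old - 1
                    for i in range(n):
                        u[row, i] -= X[i, j] * b_old
                if k_new > 0:
                    row = comp_off[g] + k_new - 1
                    for i in range(n):
                        u[row, i] += X[i, j] * b_new
            beta[j] = b_new
            comp[j] = k_new

        # --- mixture proportions ---------------------------------------
        counts = np.zeros(G + Ktot)
        for j in range(m):
            counts[pi_off[group_of[j]] + comp[j]] += 1.0
        if update_pi:
            for g in range(G):
                kg = comp_off[g + 1] - comp_off[g]
                tot = 0.0
                for k in range(kg + 1):
                    a = counts[pi_off[g] + k] + dir_conc[pi_off[g] + k]
                    gd = np.random.gamma(a, 1.0)
                    if gd < 1e-300:
                        gd = 1e-300
                    pi[pi_off[g] + k] = gd
                    tot += gd
                for k in range(kg + 1):
                    pi[pi_off[g] + k] /= tot

        # --- variance hyperparameters ----------------------------------
        if update_s2g:
            for g in range(G):
                ssq = 0.0
                nnz = 0.0
                for j in range(m):
                    if group_of[j] == g and comp[j] > 0:
                        cv = comp_var[comp_off[g] + comp[j] - 1]
                        ssq += beta[j] * beta[j] / cv
                        nnz += 1.0
                chi = np.random.chisquare(nu0 + nnz)
                if chi < 1e-12:
                    chi = 1e-12
                val = (nu0 * s02 + ssq) / chi
                if val > 1e8:
                    val = 1e8
                if val < 1e-12:
                    val = 1e-12
                s2g[g] = val
        if update_s2e:
            rss = 0.0
            for i in range(n):
                rss += r[i] * r[i]
            chi = np.random.chisquare(nu0 + n)
            if chi < 1e-12:
                chi = 1e-12
            s2e = (nu0 * s02 + rss) / chi

        # --- record ------------------------------------------------------
        if it >= burn and (it - burn) % thin == 0:
            for g in range(G):
                k0 = comp_off[g]
                k1 = comp_off[g + 1]
                ut_mean = 0.0
                for i in range(n):
                    acc = 0.0
                    for row in range(k0, k1):
                        acc += u[row, i]
                    ut_mean += acc
                ut_mean /= n
                var_ut = 0.0
                for i in range(n):
                    acc = 0.0
                    for row in range(k0, k1):
                        acc += u[row, i]
                    var_ut += (acc - ut_mean) ** 2
                var_ut /= n
                share_draws[d, g] = var_ut / vary
                for row in range(k0, k1):
                    um = 0.0
                    for i in range(n):
                        um += u[row, i]
                    um /= n
                    cov = 0.0
                    for i in range(n):
                        acc = 0.0
                        for rr in range(k0, k1):
                            acc += u[rr, i]
                        cov += (u[row, i] - um) * (acc - ut_mean)
                    cov /= n
                    comp_share_draws[d, row] = cov / vary
                s2g_draws[d, g] = s2g[g]
            s2e_draws[d] = s2e
            for k in range(G + Ktot):
                pi_draws[d, k] = pi[k]
            for j in range(m):
                beta_sum[j] += beta[j]
                beta_sq[j] += beta[j] * beta[j]
                if comp[j] > 0:
                    pip_cnt[j] += 1.0
            d += 1

    return (
        share_draws,
        comp_share_draws,
        s2g_draws,
        s2e_draws,
        pi_draws,
        beta_sum,
        beta_sq,
        pip_cnt,
    )
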